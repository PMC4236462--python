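"""Glacial-refugium delimitation from ensembles of binary suitability maps.

A refugium is an area continuously suitable across all modeled time
slices. Two orders of operation are supported over a GCM x time-slice grid
of binary maps:

* **M1** (consensus then intersection): per slice, keep cells where at
  least k of the available GCMs agree on suitability; intersect the slice
  consensus maps.
* **M2** (intersection then consensus): per GCM, intersect its slices;
  then keep cells where at least k GCMs retain suitability.

M2(k) is always a subset of M1(k); both shrink as k grows. Agreement
thresholds can be given as fractions of the model count, rounded up per
slice against the *available* models (some GCMs lack certain paleo
slices), so fractions {1/G, 1/2, 3/4, 1} reproduce counts {1, G/2, 3G/4,
G} when all models are present.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .rasters import Raster

__all__ = ["BinaryEnsemble", "RefugiaScenario", "consensus_map",
           "delimit_refugia", "label_components", "refugia_sweep"]


@dataclass
class BinaryEnsemble:
    """Binary suitability maps indexed by (gcm, slice) on a common grid."""

    maps: dict[tuple[str, str], Raster]

    def __post_init__(self) -> None:
        rasters = list(self.maps.values())
        if not rasters:
            raise ValueError("empty ensemble")
        first = rasters[0]
        for r in rasters[1:]:
            if not first.same_grid(r):
                raise ValueError("ensemble maps are not conformable")
        for key, r in self.maps.items():
            vals = r.values
            ok = np.isnan(vals) | (vals == 0) | (vals == 1)
            if not ok.all():
                raise ValueError(f"map {key} contains non-binary values")

    @property
    def gcms(self) -> list[str]:
        return sorted({g for g, _ in self.maps})

    @property
    def slices(self) -> list[str]:
        seen = []
        for _, s in self.maps:
            if s not in seen:
                seen.append(s)
        return seen

    def grid(self) -> Raster:
        return next(iter(self.maps.values()))

    def slice_maps(self, sl: str) -> list[Raster]:
        return [r for (g, s), r in sorted(self.maps.items()) if s == sl]

    def gcm_maps(self, gcm: str) -> list[Raster]:
        return [r for (g, s), r in sorted(self.maps.items()) if g == gcm]


def consensus_map(maps: list[Raster], k: int) -> Raster:
    """Cell-wise agreement: 1 where at least k maps (with data) are
    suitable; nodata where fewer than k maps have data."""
    if not maps:
        raise ValueError("no maps")
    if not (1 <= k <= len(maps)):
        raise ValueError(f"k={k} out of range 1..{len(maps)}")
    stack = np.stack([m.values for m in maps])
    has = np.isfinite(stack)
    votes = np.nansum(np.where(has, stack, 0.0), axis=0)
    n_data = has.sum(axis=0)
    out = np.where(n_data >= k, (votes >= k).astype(float), np.nan)
    return maps[0].copy_with(out)


def _intersection(maps: list[Raster]) -> Raster:
    stack = np.stack([m.values for m in maps])
    anynan = np.isnan(stack).any(axis=0)
    out = np.where(anynan, np.nan, stack.min(axis=0))
    return maps[0].copy_with(out)


@dataclass
class RefugiaScenario:
    method: str
    k: int
    fraction: float | None
    result: Raster
    components: pd.DataFrame = field(default=None, repr=False)
    adjacency: str = "queen"


def _resolve_k(k: int | None, fraction: float | None, available: int) -> int:
    if (k is None) == (fraction is None):
        raise ValueError("give exactly one of k or fraction")
    if fraction is not None:
        k = max(1, math.ceil(fraction * available))
    return k


def delimit_refugia(ens: BinaryEnsemble, method: str = "M1",
                    k: int | None = None, fraction: float | None = None,
                    adjacency: str = "queen",
                    label: bool = True) -> RefugiaScenario:
    """Delimit refugia by consensus-then-intersection (M1) or
    intersection-then-consensus (M2) at agreement level k (count) or
    ``fraction`` of the available models (rounded up per slice for M1, of
    the full model list for M2)."""
    method = method.upper()
    if method not in {"M1", "M2"}:
        raise ValueError("method must be M1 or M2")
    gcms = ens.gcms
    G = len(gcms)
    if method == "M1":
        per_slice = []
        ks = []
        for sl in ens.slices:
            maps = ens.slice_maps(sl)
            ksl = _resolve_k(k, fraction, len(maps))
            if ksl > len(maps):
                raise ValueError(
                    f"k={ksl} exceeds the {len(maps)} models available for "
                    f"slice {sl!r}")
            ks.append(ksl)
            per_slice.append(consensus_map(maps, ksl))
        result = _intersection(per_slice)
        k_used = max(ks)
    else:
        per_gcm = [_intersection(ens.gcm_maps(g)) for g in gcms]
        k_used = _resolve_k(k, fraction, G)
        if k_used > G:
            raise ValueError(f"k={k_used} exceeds the {G} models available")
        result = consensus_map(per_gcm, k_used)
    comps = label_components(result, adjacency=adjacency) if label else None
    return RefugiaScenario(method=method, k=k_used, fraction=fraction,
                           result=result, components=comps,
                           adjacency=adjacency)


def label_components(binary: Raster, adjacency: str = "queen") -> pd.DataFrame:
    """Connected components of a binary map with latitude-corrected areas.

    Returns one row per component: label, cell count, area (km^2) and
    centroid. Queen adjacency (default) joins diagonal neighbours; rook
    does not.
    """
    if adjacency == "queen":
        structure = np.ones((3, 3), dtype=int)
    elif adjacency == "rook":
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    else:
        raise ValueError("adjacency must be 'queen' or 'rook'")
    mask = binary.values == 1
    labels, n = ndimage.label(mask, structure=structure)
    areas = binary.cell_areas_km2()
    lon = binary.lon_centers()
    lat = binary.lat_centers()
    rows = []
    for lab in range(1, n + 1):
        sel = labels == lab
        rr, cc = np.nonzero(sel)
        rows.append({
            "label": lab,
            "n_cells": int(sel.sum()),
            "area_km2": float(areas[sel].sum()),
            "centroid_lat": float(lat[rr].mean()),
            "centroid_lon": float(lon[cc].mean()),
        })
    df = pd.DataFrame(rows, columns=["label", "n_cells", "area_km2",
                                     "centroid_lat", "centroid_lon"])
    return df.sort_values("area_km2", ascending=False).reset_index(drop=True)


def refugia_sweep(ens: BinaryEnsemble, method: str,
                  fractions: tuple[float, ...] = (None,),
                  adjacency: str = "queen") -> list[RefugiaScenario]:
    """Run a stringency sweep; infeasible or empty levels are reported as
    empty scenarios rather than errors (the strictest M2 level may leave no
    surviving cell)."""
    if fractions == (None,):
        G = len(ens.gcms)
        fractions = (1.0 / G, 0.5, 0.75, 1.0)
    out = []
    for f in fractions:
        out.append(delimit_refugia(ens, method=method, fraction=f,
                                   adjacency=adjacency))
    return out
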