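"""Bioclimatic variables, change-factor downscaling, and the PCA
environment space shared by the niche-modeling steps.

Temperatures are degrees Celsius, precipitation millimetres per month.
Quarters are the 12 wrap-around 3-month windows; ties between equally warm
or wet quarters break toward the earliest window. Standard deviations in
BIO4/BIO15 use the sample convention (n-1), matching the common bioclim
implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .rasters import Raster

__all__ = [
    "MonthlyClimatology", "BioclimStack", "EnvPCA",
    "compute_bioclim", "downscale_change_factor", "fit_env_pca",
    "project_env", "BIOCLIM_EXCLUDED", "BIOCLIM_RETAINED",
]

BIOCLIM_ALL = [f"BIO{i:02d}" for i in range(1, 20)]
#: mean temperature of wettest/driest quarter and precipitation of
#: warmest/coldest quarter are computed but excluded from modeling
#: (spatial artifacts).
BIOCLIM_EXCLUDED = ["BIO08", "BIO09", "BIO18", "BIO19"]
BIOCLIM_RETAINED = [b for b in BIOCLIM_ALL if b not in BIOCLIM_EXCLUDED]


@dataclass
class MonthlyClimatology:
    """12 monthly layers of tmean/tmax/tmin (degC) and prec (mm) on a grid."""

    grid: Raster                      # template carrying geometry
    tmean: np.ndarray                 # (12, nrows, ncols)
    tmax: np.ndarray
    tmin: np.ndarray
    prec: np.ndarray

    def __post_init__(self) -> None:
        shape = (12,) + self.grid.shape
        for name in ("tmean", "tmax", "tmin", "prec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            setattr(self, name, arr)

    def validate(self) -> int:
        """Count cells violating tmax >= tmean >= tmin or prec >= 0."""
        bad = ((self.tmax < self.tmean) | (self.tmean < self.tmin)
               | (self.prec < 0))
        n_bad = int(np.nansum(bad))
        if n_bad:
            warnings.warn(f"{n_bad} cell-months violate climate ordering "
                          "constraints")
        return n_bad


@dataclass
class BioclimStack:
    grid: Raster
    layers: dict[str, np.ndarray]
    excluded: list[str] = field(default_factory=lambda: list(BIOCLIM_EXCLUDED))

    def retained(self) -> dict[str, np.ndarray]:
        return {k: v for k, v in self.layers.items() if k not in self.excluded}

    def matrix(self, names: list[str]) -> np.ndarray:
        """(ncells, nvars) matrix in the given layer order."""
        return np.column_stack([self.layers[n].ravel() for n in names])


def _quarter_windows(arr: np.ndarray, reduce: str) -> np.ndarray:
    """(12, ...) -> (12, ...) per-window mean or sum over wrap-around
    3-month quarters starting at each month."""
    ext = np.concatenate([arr, arr[:2]], axis=0)
    win = np.stack([ext[i:i + 3] for i in range(12)], axis=0)
    return win.mean(axis=1) if reduce == "mean" else win.sum(axis=1)


def compute_bioclim(clim: MonthlyClimatology) -> BioclimStack:
    """The 19 standard bioclim layers from a monthly climatology.

    BIO08/BIO09/BIO18/BIO19 are computed but listed as excluded, leaving 15
    layers for modeling.
    """
    t, tx, tn, pr = clim.tmean, clim.tmax, clim.tmin, clim.prec
    if any(a.shape[0] != 12 for a in (t, tx, tn, pr)):
        raise ValueError("12 monthly layers required for every variable")
    L: dict[str, np.ndarray] = {}
    L["BIO01"] = t.mean(axis=0)
    L["BIO02"] = (tx - tn).mean(axis=0)
    L["BIO04"] = t.std(axis=0, ddof=1) * 100.0
    L["BIO05"] = tx.max(axis=0)
    L["BIO06"] = tn.min(axis=0)
    L["BIO07"] = L["BIO05"] - L["BIO06"]
    with np.errstate(divide="ignore", invalid="ignore"):
        L["BIO03"] = np.where(L["BIO07"] > 0,
                              100.0 * L["BIO02"] / L["BIO07"], np.nan)
    L["BIO12"] = pr.sum(axis=0)
    L["BIO13"] = pr.max(axis=0)
    L["BIO14"] = pr.min(axis=0)
    pmean = pr.mean(axis=0)
    L["BIO15"] = 100.0 * pr.std(axis=0, ddof=1) / (1.0 + pmean)
    qt = _quarter_windows(t, "mean")          # (12, r, c)
    qp = _quarter_windows(pr, "sum")
    wet = qp.argmax(axis=0)
    dry = qp.argmin(axis=0)
    warm = qt.argmax(axis=0)
    cold = qt.argmin(axis=0)
    take = np.take_along_axis
    L["BIO08"] = take(qt, wet[None], axis=0)[0]
    L["BIO09"] = take(qt, dry[None], axis=0)[0]
    L["BIO10"] = qt.max(axis=0)
    L["BIO11"] = qt.min(axis=0)
    L["BIO16"] = qp.max(axis=0)
    L["BIO17"] = qp.min(axis=0)
    L["BIO18"] = take(qp, warm[None], axis=0)[0]
    L["BIO19"] = take(qp, cold[None], axis=0)[0]
    return BioclimStack(grid=clim.grid, layers={k: L[k] for k in BIOCLIM_ALL})


# ---------------------------------------------------------------------------
# change-factor downscaling


def _interp_to(src_grid: Raster, values: np.ndarray, dst_grid: Raster,
               method: str = "bilinear") -> np.ndarray:
    """Interpolate a field from one grid's cell centers to another's."""
    lats = src_grid.lat_centers()[::-1]      # ascending for the interpolator
    lons = src_grid.lon_centers()
    vals = values[::-1, :]
    dlat = dst_grid.lat_centers()
    dlon = dst_grid.lon_centers()
    glat, glon = np.meshgrid(dlat, dlon, indexing="ij")
    pts = np.column_stack([glat.ravel(), glon.ravel()])
    if method in ("bilinear", "linear"):
        f = RegularGridInterpolator((lats, lons), vals, method="linear",
                                    bounds_error=False, fill_value=None)
        out = f(pts)
    elif method == "idw":
        slat, slon = np.meshgrid(lats, lons, indexing="ij")
        src = np.column_stack([slat.ravel(), slon.ravel()])
        from sklearn.neighbors import NearestNeighbors
        nn = NearestNeighbors(n_neighbors=min(4, len(src))).fit(src)
        dist, idx = nn.kneighbors(pts)
        w = 1.0 / np.maximum(dist, 1e-9) ** 2
        w /= w.sum(axis=1, keepdims=True)
        out = (vals.ravel()[idx] * w).sum(axis=1)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    return out.reshape(dst_grid.shape)


def downscale_change_factor(past_coarse: MonthlyClimatology,
                            current_coarse: MonthlyClimatology,
                            current_fine: MonthlyClimatology | None = None,
                            target_grid: Raster | None = None,
                            method: str = "bilinear",
                            eps_mm: float = 0.01) -> MonthlyClimatology:
    """Downscale a past climate by the change-factor (delta) method.

    The coarse past-minus-current anomaly is interpolated to the fine grid
    and applied to the fine current climatology: additively for
    temperatures, multiplicatively for precipitation (ratio guarded by
    ``eps_mm`` against division in arid cells). When no observed fine
    current climatology is supplied, the interpolated coarse current is
    used. Identity holds under zero anomaly.
    """
    if not past_coarse.grid.same_grid(current_coarse.grid):
        raise ValueError("past and current coarse grids do not match")
    if current_fine is None:
        if target_grid is None:
            raise ValueError("need either current_fine or target_grid")
        fine = {}
        for name in ("tmean", "tmax", "tmin", "prec"):
            arr = getattr(current_coarse, name)
            fine[name] = np.stack([_interp_to(current_coarse.grid, arr[m],
                                              target_grid, method)
                                   for m in range(12)])
        current_fine = MonthlyClimatology(grid=target_grid, **fine)
    dst = current_fine.grid
    if (dst.cellsize > current_coarse.grid.cellsize + 1e-12):
        raise ValueError("target resolution must be finer than the source")
    out = {}
    for name in ("tmean", "tmax", "tmin"):
        anom = getattr(past_coarse, name) - getattr(current_coarse, name)
        fine_anom = np.stack([_interp_to(current_coarse.grid, anom[m], dst,
                                         method) for m in range(12)])
        out[name] = getattr(current_fine, name) + fine_anom
    ratio = (past_coarse.prec + eps_mm) / (current_coarse.prec + eps_mm)
    fine_ratio = np.stack([_interp_to(current_coarse.grid, ratio[m], dst,
                                      method) for m in range(12)])
    out["prec"] = np.maximum(current_fine.prec * fine_ratio, 0.0)
    return MonthlyClimatology(grid=dst, **out)


# ---------------------------------------------------------------------------
# environmental PCA


@dataclass
class EnvPCA:
    variables: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray        # (nvars, nvars), columns = components
    variance_fractions: np.ndarray
    k: int
    variance_target: float


def fit_env_pca(bioclim: BioclimStack, region_mask: np.ndarray | None = None,
                variance_target: float = 0.99) -> EnvPCA:
    """PCA of the retained bioclim layers over the calibration region.

    Variables are standardized over masked cells (correlation-matrix PCA —
    the layers mix degC, mm and dimensionless indices), zero-variance
    variables are dropped with a warning, and the number of retained
    components is the smallest k whose cumulative explained variance
    reaches ``variance_target``. Component signs follow a deterministic
    convention: the largest-magnitude loading of each component is
    positive.
    """
    names = [n for n in BIOCLIM_RETAINED if n in bioclim.layers]
    X = bioclim.matrix(names)
    mask = np.ones(X.shape[0], bool) if region_mask is None \
        else np.asarray(region_mask, bool).ravel()
    ok = mask & np.isfinite(X).all(axis=1)
    Xm = X[ok]
    keep = []
    for i, n in enumerate(names):
        if np.std(Xm[:, i]) > 0:
            keep.append(i)
        else:
            warnings.warn(f"dropping zero-variance variable {n}")
    names = [names[i] for i in keep]
    Xm = Xm[:, keep]
    if Xm.shape[0] < Xm.shape[1]:
        raise ValueError("fewer complete cells than variables; refusing PCA")
    means = Xm.mean(axis=0)
    sds = Xm.std(axis=0, ddof=1)
    Z = (Xm - means) / sds
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for c in range(evecs.shape[1]):
        j = np.argmax(np.abs(evecs[:, c]))
        if evecs[j, c] < 0:
            evecs[:, c] = -evecs[:, c]
    fracs = evals / evals.sum()
    cum = np.cumsum(fracs)
    k = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    k = min(k, len(fracs))
    return EnvPCA(variables=names, means=means, sds=sds, loadings=evecs,
                  variance_fractions=fracs, k=k,
                  variance_target=variance_target)


def project_env(pca: EnvPCA, bioclim: BioclimStack) -> np.ndarray:
    """Project a bioclim stack into the fitted PCA space.

    Layers are centered and scaled with the *calibration* means/SDs and
    multiplied by the stored loadings — the structure is enforced, never
    refit. Returns a (k, nrows, ncols) score stack with NaN where any
    input layer is missing.
    """
    missing = [n for n in pca.variables if n not in bioclim.layers]
    if missing:
        raise ValueError(f"missing variables for projection: {missing}")
    X = bioclim.matrix(pca.variables)
    Z = (X - pca.means) / pca.sds
    scores = Z @ pca.loadings[:, : pca.k]
    bad = ~np.isfinite(X).all(axis=1)
    scores[bad] = np.nan
    shape = (pca.k,) + bioclim.grid.shape
    return scores.T.reshape(shape)
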