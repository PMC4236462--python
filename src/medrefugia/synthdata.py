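"""Synthetic inputs with known truth for every stage of the pipeline.

Two families of generators:

* **Geo-referenced haplotype data** — several independently simulated
  mitochondrial lineages (standard n-coalescent genealogies, infinite-sites
  mutations) placed on a map so as to emulate the two phylogeographic
  patterns seen in Mediterranean synanthropic taxa: spatially structured
  lineages whose members cluster around a lineage center (distance-decay
  kernel, scale ``ibd_scale`` km), versus fully mixed lineages whose
  members are scattered uniformly over the localities (human-transport
  emulation via ``mixing_fraction``).

* **Multi-GCM climate suites** — smooth monthly temperature/precipitation
  fields (latitudinal gradient plus fixed coastal/mountain bumps) over
  three time slices; past slices are uniformly cooler so the climatically
  suitable band shifts southward at the glacial maximum; pseudo-GCMs are
  coherent smooth perturbations of the shared field. The true suitability
  is a logistic bell in annual mean temperature (BIO1) and annual
  precipitation (BIO12), so the niche-modeling arm can recover it with
  linear+quadratic features; true refugia are the cells suitable in every
  slice above a stated cutoff.

Everything is driven by one integer seed and is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .climate import MonthlyClimatology
from .coalescent import Genealogy, place_mutations, simulate_genealogy_arrays
from .enm import OccurrenceSet
from .popgen import GeoAlignment, Sample
from .rasters import Raster, write_ascii_grid

__all__ = ["SimConfig", "SyntheticTruth", "ClimateSuite",
           "simulate_genealogy", "simulate_alignment", "Alignment",
           "simulate_geo_dataset", "simulate_climate_suite",
           "sample_occurrences", "write_geo_dataset"]

SLICE_COOLING = {"present": 0.0, "midHolocene": 1.0, "LGM": 5.0}


@dataclass
class SimConfig:
    """Study conditions for the synthetic generators.

    Defaults describe a Mediterranean-scale setting: a ~1 kb mitochondrial
    fragment, a few dozen sampling localities in a lon/lat box spanning
    the basin, four divergent lineages, an isolation-by-distance kernel of
    a few hundred km, and four pseudo-GCMs over three time slices on a
    0.5-degree grid.
    """

    seed: int = 0
    n_samples: int = 60
    seq_length: int = 1016
    theta: float | None = 6.0
    s_fixed: int | None = None
    n_lineages: int = 4
    n_localities: int = 15
    ibd_scale: float = 300.0          # km
    mixing_fraction: float = 0.0
    grid_shape: tuple[int, int] = (60, 60)
    cellsize: float = 0.5             # degrees
    n_gcms: int = 4
    slices: tuple[str, ...] = ("LGM", "midHolocene", "present")
    gcm_noise_sd: float = 0.5         # degC-scale perturbation
    suitability_cutoff: float = 0.5
    lon_min: float = -10.0
    lat_max: float = 45.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mixing_fraction <= 1.0):
            raise ValueError("mixing_fraction must be in [0, 1]")
        if self.seq_length <= 0:
            raise ValueError("seq_length must be positive")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if (self.theta is None) == (self.s_fixed is None):
            raise ValueError("specify exactly one of theta or s_fixed")
        if min(self.grid_shape) < 10:
            raise ValueError("grid_shape must be at least 10x10")


@dataclass
class SyntheticTruth:
    genealogies: dict[str, str] = field(default_factory=dict)   # newick
    lineage_of_sample: dict[str, str] = field(default_factory=dict)
    locality_of_sample: dict[str, str] = field(default_factory=dict)
    mixed_samples: list[str] = field(default_factory=list)
    true_suitability: dict[str, Raster] = field(default_factory=dict)
    true_refugia: Raster | None = None
    suitability_cutoff: float = 0.5


@dataclass
class ClimateSuite:
    """Per-GCM, per-slice monthly climatologies on a common grid."""

    climatologies: dict[tuple[str, str], MonthlyClimatology]
    gcms: list[str]
    slices: list[str]

    def get(self, gcm: str, sl: str) -> MonthlyClimatology:
        return self.climatologies[(gcm, sl)]


# ---------------------------------------------------------------------------
# genealogies and alignments


def simulate_genealogy(n: int, seed: int = 0) -> dendropy.Tree:
    """One standard-coalescent genealogy as an ultrametric dendropy tree."""
    rng = np.random.default_rng(seed)
    gen = simulate_genealogy_arrays(n, rng)
    return dendropy.Tree.get(data=gen.newick(), schema="newick")


@dataclass
class Alignment:
    ids: list[str]
    sequences: list[str]
    L: int

    def __len__(self) -> int:
        return len(self.ids)


_BASES = "ACGT"


def _sequences_from_mutations(gen: Genealogy, mut_nodes: np.ndarray,
                              L: int, rng: np.random.Generator,
                              ancestral: np.ndarray | None = None
                              ) -> list[str]:
    n_mut = len(mut_nodes)
    if n_mut > L:
        raise ValueError(f"{n_mut} mutations exceed {L} sites "
                         "(infinite-sites violation)")
    sites = rng.choice(L, size=n_mut, replace=False)
    if ancestral is None:
        ancestral = rng.integers(0, 4, size=L)
    seqs = np.tile(ancestral, (gen.n, 1))
    below = gen.tips_below()
    for m in range(n_mut):
        anc = ancestral[sites[m]]
        derived = (anc + rng.integers(1, 4)) % 4
        seqs[below[mut_nodes[m]], sites[m]] = derived
    return ["".join(_BASES[b] for b in row) for row in seqs]


def simulate_alignment(genealogy, L: int = 1016,
                       theta: float | None = None,
                       s_fixed: int | None = None,
                       seed: int = 0,
                       labels: list[str] | None = None,
                       ancestral: np.ndarray | None = None) -> Alignment:
    """Infinite-sites sequences on a genealogy.

    ``genealogy`` is either the array form or a dendropy ultrametric tree.
    Mutations arrive on branches at rate theta/2 per unit length (Poisson)
    or exactly ``s_fixed`` are placed multinomially proportional to branch
    lengths; each mutation hits a distinct site; the derived base is drawn
    uniformly from the three non-ancestral bases.
    """
    if s_fixed is not None and s_fixed > L:
        raise ValueError("s_fixed cannot exceed the sequence length")
    rng = np.random.default_rng(seed)
    if isinstance(genealogy, Genealogy):
        gen = genealogy
        if labels is None:
            labels = [f"t{i}" for i in range(gen.n)]
    else:
        gen, labels = _genealogy_from_dendropy(genealogy)
    muts = place_mutations(gen, rng, theta=theta, s_fixed=s_fixed)
    seqs = _sequences_from_mutations(gen, muts, L, rng, ancestral=ancestral)
    return Alignment(ids=list(labels), sequences=seqs, L=L)


def _genealogy_from_dendropy(tree: dendropy.Tree):
    leaves = list(tree.leaf_node_iter())
    internals = list(tree.preorder_internal_node_iter())
    n = len(leaves)
    index = {id(nd): i for i, nd in enumerate(leaves)}
    # order internals by creation: children-before-parents via postorder
    post_internals = [nd for nd in tree.postorder_internal_node_iter()]
    for j, nd in enumerate(post_internals):
        index[id(nd)] = n + j
    total = n + len(post_internals)
    parent = np.full(total, -1, dtype=int)
    depth = np.zeros(total)
    for nd in tree.preorder_node_iter():
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            depth[i] = depth[index[id(nd.parent_node)]] + (nd.edge.length or 0.0)
    maxdepth = depth[:n].max() if n else 0.0
    age = maxdepth - depth
    labels = [lf.taxon.label if lf.taxon else f"t{i}"
              for i, lf in enumerate(leaves)]
    return Genealogy(n=n, parent=parent, age=age), labels


# ---------------------------------------------------------------------------
# geo-referenced haplotype datasets


def _locality_layout(cfg: SimConfig, rng: np.random.Generator
                     ) -> pd.DataFrame:
    """Fixed pseudo-random localities in the simulation's lon/lat box."""
    rows, cols = cfg.grid_shape
    lat_min = cfg.lat_max - rows * cfg.cellsize
    lon_max = cfg.lon_min + cols * cfg.cellsize
    lats = rng.uniform(lat_min + 0.5, cfg.lat_max - 0.5, cfg.n_localities)
    lons = rng.uniform(cfg.lon_min + 0.5, lon_max - 0.5, cfg.n_localities)
    return pd.DataFrame({
        "locality": [f"L{i:02d}" for i in range(cfg.n_localities)],
        "lat": lats, "lon": lons})


def simulate_geo_dataset(cfg: SimConfig
                         ) -> tuple[GeoAlignment, SyntheticTruth]:
    """Simulate a geo-referenced multi-lineage haplotype dataset.

    Lineages are simulated independently (own genealogy and mutations,
    plus a block of lineage-diagnostic substitutions emulating deep
    divergence). Each lineage is anchored at a center locality and its
    samples pick localities with probability proportional to
    exp(-d/ibd_scale); afterwards a fraction ``mixing_fraction`` of all
    samples has its locality resampled uniformly, which is the
    human-transport emulation and the knob that erases spatial structure.
    """
    from .popgen import haversine_km

    rng = np.random.default_rng(cfg.seed)
    locs = _locality_layout(cfg, rng)
    n_lin = max(1, cfg.n_lineages)
    sizes = np.full(n_lin, cfg.n_samples // n_lin)
    sizes[: cfg.n_samples % n_lin] += 1
    diag_block = 25
    if n_lin * diag_block >= cfg.seq_length:
        raise ValueError("sequence too short for lineage-diagnostic blocks")
    samples: list[Sample] = []
    truth = SyntheticTruth()
    centers = rng.choice(cfg.n_localities, size=n_lin,
                         replace=n_lin > cfg.n_localities)
    lat = locs["lat"].to_numpy()
    lon = locs["lon"].to_numpy()
    # one ancestral background for the whole dataset, so between-lineage
    # divergence is the diagnostic blocks plus private mutations (a few
    # percent), not two unrelated random sequences
    ancestral = rng.integers(0, 4, size=cfg.seq_length)
    for li, size in enumerate(sizes):
        if size < 2:
            size = 2
        name = f"A{li + 1}"
        sub_rng = np.random.default_rng(rng.integers(2 ** 31))
        gen = simulate_genealogy_arrays(int(size), sub_rng)
        truth.genealogies[name] = gen.newick(
            labels=[f"{name}_s{i:03d}" for i in range(size)])
        aln = simulate_alignment(
            gen, L=cfg.seq_length, theta=cfg.theta, s_fixed=cfg.s_fixed,
            seed=int(sub_rng.integers(2 ** 31)),
            labels=[f"{name}_s{i:03d}" for i in range(size)],
            ancestral=ancestral)
        # lineage-diagnostic block: sites set to a fixed base per lineage
        lo = li * diag_block
        seqs = []
        for s in aln.sequences:
            block = _BASES[li % 4] * diag_block
            seqs.append(s[:lo] + block + s[lo + diag_block:])
        # spatial placement: distance-decay kernel around the lineage
        # center, so members of a lineage (related haplotypes) sit at
        # proximate localities
        d = haversine_km(lat[centers[li]], lon[centers[li]], lat, lon)
        w = np.exp(-d / cfg.ibd_scale)
        w /= w.sum()
        loc_idx = sub_rng.choice(cfg.n_localities, size=size, p=w)
        for i in range(size):
            sid = f"{name}_s{i:03d}"
            j = int(loc_idx[i])
            samples.append(Sample(
                id=sid, sequence=seqs[i], locality=locs["locality"][j],
                lat=float(lat[j]), lon=float(lon[j]), lineage=name))
            truth.lineage_of_sample[sid] = name
            truth.locality_of_sample[sid] = locs["locality"][j]
    # human-transport mixing: uniform locality reassignment
    n_mix = int(round(cfg.mixing_fraction * len(samples)))
    if n_mix:
        mix_idx = rng.choice(len(samples), size=n_mix, replace=False)
        for i in mix_idx:
            j = int(rng.integers(cfg.n_localities))
            s = samples[i]
            samples[i] = Sample(id=s.id, sequence=s.sequence,
                                locality=locs["locality"][j],
                                lat=float(lat[j]), lon=float(lon[j]),
                                lineage=s.lineage)
            truth.locality_of_sample[s.id] = locs["locality"][j]
            truth.mixed_samples.append(s.id)
    return GeoAlignment(samples, L=cfg.seq_length), truth


# ---------------------------------------------------------------------------
# climate suites


def _smooth_field(rng: np.random.Generator, lat_g: np.ndarray,
                  lon_g: np.ndarray, sd: float) -> np.ndarray:
    """Coherent smooth random field: a few random low-frequency harmonics."""
    if sd <= 0:
        return np.zeros_like(lat_g)
    f = np.zeros_like(lat_g)
    lat0 = (lat_g - lat_g.mean()) / max(np.ptp(lat_g), 1e-9)
    lon0 = (lon_g - lon_g.mean()) / max(np.ptp(lon_g), 1e-9)
    for _ in range(4):
        a, b = rng.normal(size=2)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        f += a * np.cos(2 * np.pi * lat0 + ph1) + \
            b * np.cos(2 * np.pi * lon0 + ph2)
    f *= sd / max(f.std(), 1e-9)
    return f


def _base_monthly(cfg: SimConfig, lat_g: np.ndarray, lon_g: np.ndarray,
                  cooling: float):
    """Deterministic shared climate: gradient + fixed bumps, 12 months."""
    months = np.arange(12)
    seasonal = np.cos(2 * np.pi * (months - 6) / 12.0)   # July warm
    t_ann = 38.0 - 0.65 * lat_g - cooling
    bumps = (3.0 * np.exp(-(((lat_g - 36.0) / 2.5) ** 2
                            + ((lon_g - 5.0) / 4.0) ** 2))
             - 4.0 * np.exp(-(((lat_g - 32.0) / 2.0) ** 2
                              + ((lon_g + 6.0) / 3.0) ** 2)))
    # seasonal amplitude and diurnal spread vary with longitude (and the
    # fixed bumps), not latitude: a uniform cooling then translates the
    # whole climate envelope southward rather than creating conditions
    # with no present-day analogue
    amp = 8.0 + 0.6 * np.cos(np.pi * (lon_g - 5.0) / 15.0)
    tmean = np.stack([t_ann + bumps + amp * s for s in seasonal])
    spread = 5.0 + 0.3 * np.sin(np.pi * (lon_g + 2.0) / 12.0)
    tmax = tmean + spread
    tmin = tmean - spread
    # the moisture gradient shifts south together with the thermal one
    # (storm tracks follow the cooling), so past climates are southward
    # translations of the present envelope rather than no-analogue states
    lat_eff = lat_g + cooling / 0.65
    p_ann = np.clip(20.0 + 2.6 * (lat_eff - 25.0), 5.0, None) \
        + 30.0 * np.exp(-(((lon_g - 12.0) / 5.0) ** 2))
    wet_season = -np.cos(2 * np.pi * (months - 0.5) / 12.0)  # winter wet
    prec = np.stack([np.clip(p_ann * (1.0 + 0.6 * s), 0.0, None)
                     for s in wet_season])
    return tmean, tmax, tmin, prec


def true_suitability_fn(bio1: np.ndarray, bio12: np.ndarray) -> np.ndarray:
    """Logistic bell in annual mean temperature and annual precipitation.

    The factor 8 makes the transition sharp, so the species has a
    well-defined climatic envelope (suitability near 0 or 1 except in a
    narrow edge zone and occurrences drawn proportional to suitability
    almost never fall outside it); the 0.5 contour is the ellipse where
    the quadratic form equals 5.
    """
    z = 8.0 * (5.0 - ((bio1 - 17.0) / 2.5) ** 2
               - ((bio12 - 650.0) / 220.0) ** 2)
    return 1.0 / (1.0 + np.exp(-z))


def simulate_climate_suite(cfg: SimConfig
                           ) -> tuple[ClimateSuite, SyntheticTruth]:
    """Simulate the multi-GCM, multi-slice monthly climate suite.

    All GCMs share the deterministic gradient+bump climate of each slice;
    each GCM adds its own coherent smooth perturbation (additive for
    temperatures — the same field for tmean/tmax/tmin, preserving their
    ordering — and multiplicative for precipitation, preserving
    non-negativity). Truth (suitability per slice, refugia) is evaluated
    on the shared unperturbed climate.
    """
    rows, cols = cfg.grid_shape
    lat_min = cfg.lat_max - rows * cfg.cellsize
    grid = Raster(np.zeros((rows, cols)), xll=cfg.lon_min, yll=lat_min,
                  cellsize=cfg.cellsize)
    lon_g, lat_g = np.meshgrid(grid.lon_centers(), grid.lat_centers())
    rng = np.random.default_rng(cfg.seed + 1)
    gcm_fields = []
    for g in range(cfg.n_gcms):
        t_pert = _smooth_field(rng, lat_g, lon_g, cfg.gcm_noise_sd)
        p_pert = _smooth_field(rng, lat_g, lon_g, 0.1 * cfg.gcm_noise_sd)
        gcm_fields.append((t_pert, p_pert))
    suite: dict[tuple[str, str], MonthlyClimatology] = {}
    truth = SyntheticTruth(suitability_cutoff=cfg.suitability_cutoff)
    gcm_names = [f"GCM{g + 1}" for g in range(cfg.n_gcms)]
    refugia_mask = None
    for sl in cfg.slices:
        cooling = SLICE_COOLING.get(sl, 0.0)
        tmean, tmax, tmin, prec = _base_monthly(cfg, lat_g, lon_g, cooling)
        bio1 = tmean.mean(axis=0)
        bio12 = prec.sum(axis=0)
        suit = true_suitability_fn(bio1, bio12)
        truth.true_suitability[sl] = grid.copy_with(suit)
        ok = suit >= cfg.suitability_cutoff
        refugia_mask = ok if refugia_mask is None else (refugia_mask & ok)
        for g, name in enumerate(gcm_names):
            t_pert, p_pert = gcm_fields[g]
            suite[(name, sl)] = MonthlyClimatology(
                grid=grid,
                tmean=tmean + t_pert,
                tmax=tmax + t_pert,
                tmin=tmin + t_pert,
                prec=prec * np.exp(p_pert))
    truth.true_refugia = grid.copy_with(refugia_mask.astype(float))
    return (ClimateSuite(climatologies=suite, gcms=gcm_names,
                         slices=list(cfg.slices)), truth)


def sample_occurrences(true_suitability: Raster, n: int, seed: int = 0
                       ) -> OccurrenceSet:
    """Draw occurrence points with cell probability proportional to
    suitability, jittered uniformly within the cell."""
    if n < 1:
        raise ValueError("n must be >= 1")
    vals = np.where(np.isfinite(true_suitability.values),
                    true_suitability.values, 0.0)
    total = vals.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample")
    rng = np.random.default_rng(seed)
    flat = vals.ravel() / total
    idx = rng.choice(len(flat), size=n, p=flat)
    rr, cc = np.unravel_index(idx, vals.shape)
    cs = true_suitability.cellsize
    lat = true_suitability.lat_centers()[rr] + rng.uniform(-cs / 2, cs / 2, n)
    lon = true_suitability.lon_centers()[cc] + rng.uniform(-cs / 2, cs / 2, n)
    pts = pd.DataFrame({"id": [f"occ{i:03d}" for i in range(n)],
                        "lat": lat, "lon": lon})
    return OccurrenceSet(points=pts, note=f"synthetic, seed={seed}")


# ---------------------------------------------------------------------------
# writers


def write_geo_dataset(aln: GeoAlignment, truth: SyntheticTruth,
                      outdir: str | Path, cfg: SimConfig | None = None
                      ) -> dict[str, str]:
    """Write FASTA + sample CSV + newick genealogies + truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "sequences.fasta"
    with open(fasta, "w") as fh:
        for s in aln.samples:
            fh.write(f">{s.id}\n{s.sequence}\n")
    table = pd.DataFrame([{
        "id": s.id, "locality": s.locality, "lat": s.lat, "lon": s.lon,
        "lineage": s.lineage or ""} for s in aln.samples])
    csv = outdir / "samples.csv"
    table.to_csv(csv, index=False)
    trees = outdir / "genealogies.nwk"
    with open(trees, "w") as fh:
        for name, nwk in truth.genealogies.items():
            fh.write(nwk + "\n")
    manifest = {
        "lineage_of_sample": truth.lineage_of_sample,
        "mixed_samples": truth.mixed_samples,
        "config": asdict(cfg) if cfg else None,
    }
    man = outdir / "truth.json"
    with open(man, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return {"fasta": str(fasta), "samples": str(csv), "trees": str(trees),
            "truth": str(man)}


def write_climate_suite(suite: ClimateSuite, truth: SyntheticTruth,
                        outdir: str | Path) -> None:
    """Write the suite as ESRI ASCII grids: <gcm>/<slice>/<var><mm>.asc."""
    outdir = Path(outdir)
    for (gcm, sl), clim in suite.climatologies.items():
        d = outdir / gcm / sl
        d.mkdir(parents=True, exist_ok=True)
        for var in ("tmean", "tmax", "tmin", "prec"):
            arr = getattr(clim, var)
            for m in range(12):
                write_ascii_grid(clim.grid.copy_with(arr[m]),
                                 d / f"{var}{m + 1:02d}.asc")
    td = outdir / "truth"
    td.mkdir(exist_ok=True)
    for sl, r in truth.true_suitability.items():
        write_ascii_grid(r, td / f"suitability_{sl}.asc")
    if truth.true_refugia is not None:
        write_ascii_grid(truth.true_refugia, td / "refugia.asc")
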