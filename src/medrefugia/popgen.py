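"""Haplotype handling, diversity and neutrality statistics, and spatial
patterns of mitochondrial diversity.

The module operates on a :class:`GeoAlignment` — aligned sequences joined to
sampling localities — and provides the statistics used in single-locus
phylogeography: haplotype collapsing, p-distances, haplotype and nucleotide
diversity, Fu's Fs and Ramos-Onsins & Rozas' R2 with coalescent-simulation
significance, Mantel tests of isolation by distance, and a grid-based
bootstrap map of haplotype diversity, richness and rarity.

Conventions
-----------
* Any base other than A/C/G/T (IUPAC ambiguity, N, gap) is *unresolved*.
* Nucleotide diversity uses complete deletion by default (sites resolved in
  every sequence), p-distance matrices use pairwise deletion; both
  switchable. These mirror the defaults of the classic programs in which
  the two families of statistics are usually computed.
* Probabilities from permutation / simulation nulls use the add-one rule
  (1 + hits) / (1 + trials).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import mutation_stats, place_mutations, simulate_genealogy_arrays

__all__ = [
    "GeoAlignment", "Sample", "HaplotypeTable", "DistanceMatrix",
    "SummaryStats", "NeutralityResult", "MantelResult", "DiversityGrid",
    "UndefinedStatisticError",
    "collapse_haplotypes", "p_distance_matrix", "alignment_summary",
    "fu_fs", "r2_stat", "neutrality_significance",
    "great_circle_matrix", "haversine_km", "mantel_ibd", "diversity_grid",
]

EARTH_RADIUS_KM = 6371.0
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. S = 0)."""


@dataclass
class Sample:
    id: str
    sequence: str
    locality: str
    lat: float
    lon: float
    lineage: str | None = None


@dataclass
class GeoAlignment:
    """Aligned sequences with per-sample locality and coordinates."""

    samples: list[Sample]
    L: int = 0

    def __post_init__(self) -> None:
        if self.samples:
            if not self.L:
                self.L = len(self.samples[0].sequence)
            for s in self.samples:
                if len(s.sequence) != self.L:
                    raise ValueError(
                        f"sample {s.id}: sequence length {len(s.sequence)}"
                        f" != alignment length {self.L}")
                if not (-90.0 <= s.lat <= 90.0 and -180.0 <= s.lon <= 180.0):
                    raise ValueError(f"sample {s.id}: invalid coordinates")

    def __len__(self) -> int:
        return len(self.samples)

    def encoded(self) -> np.ndarray:
        """(n, L) int8 matrix; A,C,G,T -> 0..3, anything else -> -1."""
        n = len(self.samples)
        out = np.full((n, self.L), -1, dtype=np.int8)
        for i, s in enumerate(self.samples):
            seq = s.sequence.upper()
            for j, b in enumerate(seq):
                out[i, j] = _BASE_CODE.get(b, -1)
        return out

    def subset(self, ids: list[str]) -> "GeoAlignment":
        keep = set(ids)
        return GeoAlignment([s for s in self.samples if s.id in keep], self.L)

    def localities(self) -> pd.DataFrame:
        """One row per locality with its coordinates."""
        rows = {}
        for s in self.samples:
            rows.setdefault(s.locality, (s.lat, s.lon))
        return pd.DataFrame(
            [(k, v[0], v[1]) for k, v in rows.items()],
            columns=["locality", "lat", "lon"])


@dataclass
class HaplotypeTable:
    """Partition of samples into identical-sequence classes."""

    representatives: list[str]
    members: list[list[str]]
    unassigned: list[str] = field(default_factory=list)

    @property
    def H(self) -> int:
        return len(self.representatives)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.members], dtype=int)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def haplotype_of(self) -> dict[str, int]:
        return {sid: h for h, mem in enumerate(self.members) for sid in mem}


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def upper(self) -> np.ndarray:
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


@dataclass
class SummaryStats:
    n: int
    L_eff: int
    S: int
    H: int
    Hd: float
    pi: float
    kbar: float
    U: np.ndarray


@dataclass
class NeutralityResult:
    statistic: str
    value: float
    p: float
    p_upper: float
    ci95: tuple[float, float]
    n_sims: int
    seed: int


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int


@dataclass
class DiversityGrid:
    points: pd.DataFrame  # lat, lon, n_available, HT_mean, HR_mean, R_mean, missing
    spacing_km: float
    radius_km: float
    m: int
    B: int
    seed: int


# ---------------------------------------------------------------------------
# haplotypes and distances


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    both = (a >= 0) & (b >= 0)
    return bool(np.all(a[both] == b[both]))


def collapse_haplotypes(aln: GeoAlignment,
                        ambiguous_policy: str = "strict") -> HaplotypeTable:
    """Group samples into haplotypes (identical resolved sequences).

    ``strict`` (default): fully resolved sequences seed the groups; a
    sequence with unresolved sites joins a group only if it is compatible
    (equal at all mutually resolved sites) with exactly one group — if it is
    compatible with several, the merge is ambiguous and the sample is set
    aside as unassignable (with a warning), as is an all-unresolved
    sequence. ``exact``: byte-for-byte equality only.
    """
    if not aln.samples:
        raise ValueError("empty alignment")
    if ambiguous_policy not in {"strict", "exact"}:
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    enc = aln.encoded()
    ids = [s.id for s in aln.samples]

    if ambiguous_policy == "exact":
        groups: dict[str, list[str]] = {}
        for sid, s in zip(ids, aln.samples):
            groups.setdefault(s.sequence.upper(), []).append(sid)
        reps = list(groups)
        return HaplotypeTable(representatives=reps,
                              members=[groups[r] for r in reps])

    resolved = enc >= 0
    full = resolved.all(axis=1)
    reps_idx: list[int] = []
    members: list[list[str]] = []
    # pass 1: fully resolved sequences, grouped by identity
    seen: dict[bytes, int] = {}
    for i in np.flatnonzero(full):
        key = enc[i].tobytes()
        if key in seen:
            members[seen[key]].append(ids[i])
        else:
            seen[key] = len(reps_idx)
            reps_idx.append(i)
            members.append([ids[i]])
    unassigned: list[str] = []
    # pass 2: partially resolved sequences
    for i in np.flatnonzero(~full):
        if not resolved[i].any():
            warnings.warn(f"sample {ids[i]} has no resolved sites; excluded")
            unassigned.append(ids[i])
            continue
        hits = [g for g, r in enumerate(reps_idx) if _compatible(enc[i], enc[r])]
        if len(hits) == 1:
            members[hits[0]].append(ids[i])
        elif len(hits) == 0:
            # becomes its own (partially resolved) haplotype
            reps_idx.append(i)
            members.append([ids[i]])
        else:
            warnings.warn(
                f"sample {ids[i]} is compatible with {len(hits)} haplotypes; "
                "ambiguous merge, excluded")
            unassigned.append(ids[i])
    reps = [aln.samples[i].sequence.upper() for i in reps_idx]
    return HaplotypeTable(representatives=reps, members=members,
                          unassigned=unassigned)


def p_distance_matrix(aln: GeoAlignment, groups: dict[str, str] | None = None
                      ) -> tuple[DistanceMatrix, pd.DataFrame | None]:
    """Pairwise p-distances with pairwise deletion of unresolved sites.

    Returns the matrix and, when ``groups`` maps sample id -> group label,
    a table of mean between/within-group distances. A pair with zero
    comparable sites gets NaN.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    enc = aln.encoded()
    ok = enc >= 0
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n - 1):
        both = ok[i] & ok[i + 1:]
        diff = both & (enc[i] != enc[i + 1:])
        comp = both.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(comp > 0, diff.sum(axis=1) / comp, np.nan)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    labels = [s.id for s in aln.samples]
    dm = DistanceMatrix(labels, d)
    if groups is None:
        return dm, None
    glab = sorted(set(groups.values()))
    rows = []
    idx = {g: [k for k, s in enumerate(labels) if groups.get(s) == g]
           for g in glab}
    for a, b in itertools.combinations_with_replacement(glab, 2):
        if a == b:
            pairs = [(i, j) for i, j in itertools.combinations(idx[a], 2)]
        else:
            pairs = [(i, j) for i in idx[a] for j in idx[b]]
        vals = [d[i, j] for i, j in pairs]
        vals = [v for v in vals if np.isfinite(v)]
        rows.append((a, b, float(np.mean(vals)) if vals else np.nan, len(vals)))
    table = pd.DataFrame(rows, columns=["group1", "group2", "mean_p", "n_pairs"])
    return dm, table


# ---------------------------------------------------------------------------
# summary statistics and neutrality tests


def alignment_summary(aln: GeoAlignment, deletion: str = "complete"
                      ) -> SummaryStats:
    """Nucleotide/haplotype diversity summary of an alignment.

    Hd uses the small-sample correction n(1 - sum p_i^2)/(n-1) on haplotype
    frequencies; pi is mean per-site pairwise difference over the analyzed
    sites (complete deletion by default); kbar = pi * L_eff; U_i counts
    folded singleton sites attributed to the sequence carrying the minority
    base.
    """
    n = len(aln)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    enc = aln.encoded()
    if deletion == "complete":
        cols = (enc >= 0).all(axis=0)
    elif deletion == "none":
        cols = np.ones(aln.L, dtype=bool)
    else:
        raise ValueError(f"unknown deletion mode {deletion!r}")
    sub = enc[:, cols]
    L_eff = int(cols.sum())
    # pairwise differences (complete columns are fully resolved)
    total_diff = 0
    for i in range(n - 1):
        total_diff += (sub[i] != sub[i + 1:]).sum()
    n_pairs = n * (n - 1) // 2
    kbar = total_diff / n_pairs if n_pairs else 0.0
    pi = kbar / L_eff if L_eff else 0.0
    # segregating sites and singletons
    S = 0
    U = np.zeros(n)
    for j in range(L_eff):
        col = sub[:, j]
        vals, counts = np.unique(col, return_counts=True)
        if len(vals) > 1:
            S += 1
            for v, c in zip(vals, counts):
                if c == 1:
                    U[np.flatnonzero(col == v)[0]] += 1
    haps = collapse_haplotypes(aln)
    freqs = haps.counts / haps.n
    Hd = haps.n * (1.0 - float((freqs ** 2).sum())) / (haps.n - 1) \
        if haps.n > 1 else 0.0
    return SummaryStats(n=n, L_eff=L_eff, S=int(S), H=haps.H, Hd=float(Hd),
                        pi=float(pi), kbar=float(kbar), U=U)


def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling, first kind)."""
    row = np.full(n + 1, -np.inf)
    row[0] = -np.inf
    row[1] = 0.0  # |s(1,1)| = 1
    if n == 1:
        return row
    cur = row[: 2].copy()
    for m in range(1, n):
        nxt = np.full(m + 2, -np.inf)
        # |s(m+1,k)| = m |s(m,k)| + |s(m,k-1)|
        with np.errstate(divide="ignore"):
            a = np.log(m) + cur  # k = 0..m
        nxt[: m + 1] = a
        nxt[1: m + 2] = np.logaddexp(nxt[1: m + 2], cur)
        cur = nxt
    out = np.full(n + 1, -np.inf)
    out[: len(cur)] = cur
    return out


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k = 0..n under the Ewens sampling formula (log-space)."""
    if theta <= 0:
        p = np.zeros(n + 1)
        p[1] = 1.0
        return p
    ls = _log_stirling_row(n)
    lognum = ls + np.arange(n + 1) * np.log(theta)
    logden = np.sum(np.log(theta + np.arange(n)))
    logp = lognum - logden
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return p


def fu_fs(stats: SummaryStats) -> float:
    """Fu's Fs from the Ewens sampling formula.

    theta is estimated by the mean pairwise difference kbar; S' = P(K >=
    H_obs | theta, n); Fs = ln(S'/(1 - S')). Stirling numbers are handled in
    log space so n of several hundred poses no overflow problem. Returns
    signed infinity when S' is numerically 0 or 1.
    """
    if stats.S == 0:
        raise UndefinedStatisticError("Fs undefined when S = 0")
    n, H, theta = stats.n, stats.H, stats.kbar
    if H <= 1 or theta <= 0:
        return float("inf")
    p = ewens_k_distribution(n, theta)
    s_prime = float(p[H:].sum())
    if s_prime >= 1.0 - 1e-14:
        return float("inf")
    if s_prime <= 1e-300:
        return float("-inf")
    return float(np.log(s_prime / (1.0 - s_prime)))


def r2_stat(stats: SummaryStats) -> float:
    """Ramos-Onsins & Rozas R2: sqrt(mean (U_i - kbar/2)^2) / S."""
    if stats.S == 0:
        raise UndefinedStatisticError("R2 undefined when S = 0")
    dev = stats.U - stats.kbar / 2.0
    return float(np.sqrt(np.mean(dev ** 2)) / stats.S)


def _simulated_stat(statistic: str, n: int, S: int,
                    rng: np.random.Generator) -> float:
    gen = simulate_genealogy_arrays(n, rng)
    muts = place_mutations(gen, rng, s_fixed=S)
    ms = mutation_stats(gen, muts)
    st = SummaryStats(n=n, L_eff=S, S=ms["S"], H=ms["H"], Hd=0.0,
                      pi=0.0, kbar=ms["kbar"], U=ms["U"])
    if statistic == "Fs":
        return fu_fs(st)
    if statistic == "R2":
        return r2_stat(st)
    raise ValueError(f"unknown statistic {statistic!r}")


def neutrality_significance(observed: float, statistic: str, n: int, S: int,
                            n_sims: int = 1000, seed: int = 0
                            ) -> NeutralityResult:
    """Left-tail significance of Fs or R2 under the fixed-S neutral null.

    Simulates standard-coalescent genealogies with exactly S mutations
    (multinomial on branch lengths) and recomputes the statistic on every
    replicate. p = (1 + #{sim <= obs}) / (n_sims + 1); the upper-tail
    probability is exposed too because the conventional 5% call for Fs uses
    the 2% left tail.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if S < 1:
        raise ValueError("need S >= 1")
    rng = np.random.default_rng(seed)
    sims = np.array([_simulated_stat(statistic, n, S, rng)
                     for _ in range(n_sims)])
    finite = sims[np.isfinite(sims)]
    p_low = (1 + int((sims <= observed).sum())) / (n_sims + 1)
    p_high = (1 + int((sims >= observed).sum())) / (n_sims + 1)
    lo, hi = np.percentile(finite, [2.5, 97.5])
    return NeutralityResult(statistic=statistic, value=float(observed),
                            p=float(p_low), p_upper=float(p_high),
                            ci95=(float(lo), float(hi)),
                            n_sims=n_sims, seed=seed)


def null_distribution(statistic: str, n: int, S: int, n_sims: int,
                      seed: int = 0) -> np.ndarray:
    """Simulated fixed-S null sample of a neutrality statistic."""
    rng = np.random.default_rng(seed)
    return np.array([_simulated_stat(statistic, n, S, rng)
                     for _ in range(n_sims)])


# ---------------------------------------------------------------------------
# geography


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance on the 6371-km sphere (array-friendly)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (np.asarray(lat1, float),
                                              np.asarray(lon1, float),
                                              np.asarray(lat2, float),
                                              np.asarray(lon2, float)))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def great_circle_matrix(points: pd.DataFrame) -> DistanceMatrix:
    """Haversine distance matrix (km) from a table with lat/lon columns.

    The first column is used as the label when present, otherwise the index.
    """
    if not {"lat", "lon"}.issubset(points.columns):
        raise ValueError("points need 'lat' and 'lon' columns")
    lat = points["lat"].to_numpy(float)
    lon = points["lon"].to_numpy(float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("invalid coordinates")
    labels = [str(x) for x in (points.iloc[:, 0] if points.columns[0] not in
                               ("lat", "lon") else points.index)]
    d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(labels, d)


def mantel_ibd(genetic: DistanceMatrix, geographic: DistanceMatrix,
               n_perm: int = 999, seed: int = 0, log_geo: bool = True
               ) -> MantelResult:
    """Mantel correlation between genetic and (log) geographic distances.

    One-tailed (r >= observed) permutation p-value with simultaneous
    row/column permutation. Zero geographic distances are replaced by half
    the smallest positive distance before the log transform. Refuses fewer
    than five localities, the exclusion rule used for sparse lineages.
    """
    n = len(genetic.labels)
    if n < 5:
        raise ValueError("Mantel test refused: fewer than 5 localities")
    if len(geographic.labels) != n:
        raise ValueError("matrices are not conformable")
    g = genetic.values.copy()
    e = geographic.values.copy()
    if log_geo:
        off = e[np.triu_indices(n, k=1)]
        pos = off[off > 0]
        if len(pos) == 0:
            raise ValueError("geographic distances are all zero (degenerate)")
        fill = pos.min() / 2.0
        e = np.where(e <= 0, fill, e)
        e = np.log(e)
        np.fill_diagonal(e, 0.0)
    iu = np.triu_indices(n, k=1)
    x = g[iu]
    y = e[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = g[np.ix_(perm, perm)][iu]
        if np.std(xp) == 0:
            continue
        if np.corrcoef(xp, y)[0, 1] >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm)


def locality_matrices(aln: GeoAlignment
                      ) -> tuple[DistanceMatrix, DistanceMatrix]:
    """Locality-level genetic and geographic distance matrices for IBD.

    Genetic distance between two localities is the mean pairwise p-distance
    across their samples (pairwise deletion); within-locality diagonal is
    zero. Localities are ordered as first encountered.
    """
    dm, _ = p_distance_matrix(aln)
    locs = aln.localities()
    names = list(locs["locality"])
    idx = {name: [i for i, s in enumerate(aln.samples) if s.locality == name]
           for name in names}
    n = len(names)
    g = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            vals = dm.values[np.ix_(idx[names[a]], idx[names[b]])]
            vals = vals[np.isfinite(vals)]
            g[a, b] = g[b, a] = float(vals.mean()) if vals.size else np.nan
    genetic = DistanceMatrix(names, g)
    geographic = great_circle_matrix(locs)
    return genetic, geographic


# ---------------------------------------------------------------------------
# gridded diversity / rarity


def _unbiased_hd(counts: np.ndarray) -> float:
    m = counts.sum()
    if m < 2:
        return 0.0
    p = counts / m
    return float(m * (1.0 - (p ** 2).sum()) / (m - 1))


def diversity_grid(aln: GeoAlignment, spacing_km: float = 100.0,
                   radius_km: float | None = None, m: int = 5,
                   B: int = 1000, seed: int = 0) -> DiversityGrid:
    """Bootstrap maps of haplotype diversity (H_T), richness (H_R) and
    rarity (R) on a regular grid of points.

    Grid points are laid every ``spacing_km`` in latitude and longitude
    over the sampled extent. At each point, samples within ``radius_km``
    (default = spacing) form the local pool; if at least ``m`` are
    available, ``B`` subsamples of size ``m`` are drawn without replacement
    and the three indices averaged over draws. Rarity of a haplotype is the
    inverse of the number of distinct localities where it occurs
    dataset-wide; R of a draw is the mean rarity over drawn individuals.
    Points with fewer than ``m`` available samples are flagged missing.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    if radius_km is None:
        radius_km = spacing_km
    haps = collapse_haplotypes(aln)
    hap_of = haps.haplotype_of()
    keep = [s for s in aln.samples if s.id in hap_of]
    hap_ids = np.array([hap_of[s.id] for s in keep])
    lats = np.array([s.lat for s in keep])
    lons = np.array([s.lon for s in keep])
    # dataset-wide rarity: 1 / number of occupied localities per haplotype
    occ: dict[int, set[str]] = {}
    for s in keep:
        occ.setdefault(hap_of[s.id], set()).add(s.locality)
    rarity = {h: 1.0 / len(v) for h, v in occ.items()}
    rar = np.array([rarity[h] for h in hap_ids])

    deg_per_km = 1.0 / (np.pi / 180.0 * EARTH_RADIUS_KM)
    dlat = spacing_km * deg_per_km
    lat_pts = np.arange(lats.min(), lats.max() + dlat / 2, dlat)
    rng = np.random.default_rng(seed)
    rows = []
    for glat in lat_pts:
        coslat = max(np.cos(np.radians(glat)), 1e-6)
        dlon = spacing_km * deg_per_km / coslat
        lon_pts = np.arange(lons.min(), lons.max() + dlon / 2, dlon)
        for glon in lon_pts:
            d = haversine_km(glat, glon, lats, lons)
            idx = np.flatnonzero(d <= radius_km)
            n_avail = len(idx)
            if n_avail < m:
                rows.append((glat, glon, n_avail, np.nan, np.nan, np.nan, True))
                continue
            # vectorized sampling without replacement: argpartition of
            # uniform keys per draw
            keys = rng.random((B, n_avail))
            draws = idx[np.argpartition(keys, m - 1, axis=1)[:, :m]]
            ht = np.empty(B)
            hr = np.empty(B)
            for b in range(B):
                _, counts = np.unique(hap_ids[draws[b]], return_counts=True)
                hr[b] = len(counts)
                ht[b] = _unbiased_hd(counts)
            rmean = rar[draws].mean(axis=1)
            rows.append((glat, glon, n_avail, ht.mean(), hr.mean(),
                         rmean.mean(), False))
    pts = pd.DataFrame(rows, columns=["lat", "lon", "n_available", "HT_mean",
                                      "HR_mean", "R_mean", "missing"])
    return DiversityGrid(points=pts, spacing_km=spacing_km,
                         radius_km=radius_km, m=m, B=B, seed=seed)
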