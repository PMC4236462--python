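"""Ecological niche modeling: occurrence thinning, a regularized
maximum-entropy model on environmental-PCA features, aggregation of
replicate predictions, minimum-training-presence binarization, partial-ROC
evaluation, and MOP extrapolation masking.

The maxent model here maximizes

    (1/m) sum_i eta . f(x_i)  -  log Z(eta)  -  sum_j beta_j |eta_j|

over presence samples x_i, with Z = sum_bg exp(eta . f) over background
cells, features f = linear + quadratic terms of the PCA scores
(standardized over the background), and per-feature L1 weights
beta_j = reg_multiplier * s_j / sqrt(m) (s_j the feature SD over
presences). The objective is concave; it is solved by bounded L-BFGS-B on
the positive/negative split eta = a - b (an exact reformulation of the L1
penalty), to gradient tolerance 1e-6. The raw output exp(eta.f)/Z sums to
one over the background by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.neighbors import NearestNeighbors

from .popgen import haversine_km
from .rasters import Raster

__all__ = [
    "OccurrenceSet", "CalibrationRegion", "MaxentModel", "MopMap",
    "PartialRocResult",
    "build_calibration_region", "thin_occurrences", "build_features",
    "fit_maxent_single", "fit_maxent", "predict_raw",
    "aggregate_replicates", "aggregate_subsets", "predict_and_aggregate",
    "mtp_binarize", "partial_roc", "mop_mask",
]


@dataclass
class OccurrenceSet:
    points: pd.DataFrame          # columns id, lat, lon
    note: str = ""

    def __post_init__(self) -> None:
        need = {"id", "lat", "lon"}
        if not need.issubset(self.points.columns):
            raise ValueError("occurrence table needs id/lat/lon columns")
        lat = self.points["lat"].to_numpy(float)
        lon = self.points["lon"].to_numpy(float)
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
            raise ValueError("invalid occurrence coordinates")
        dup = self.points.duplicated(subset=["lat", "lon"]).sum()
        if dup:
            warnings.warn(f"{dup} duplicate occurrence coordinates")

    def __len__(self) -> int:
        return len(self.points)

    def latlon(self) -> np.ndarray:
        return self.points[["lat", "lon"]].to_numpy(float)


@dataclass
class CalibrationRegion:
    mask: Raster                  # 1 inside M, NaN outside
    buffer_km: float
    exclusions: list = field(default_factory=list)

    def contains(self, lat: float, lon: float) -> bool:
        try:
            r, c = self.mask.cell_of(lat, lon)
        except ValueError:
            return False
        return bool(np.isfinite(self.mask.values[r, c]))


def build_calibration_region(occ: OccurrenceSet, grid: Raster,
                             buffer_km: float = 350.0,
                             exclusions: list | None = None
                             ) -> CalibrationRegion:
    """Union of great-circle buffers around occurrences, minus exclusion
    polygons, rasterized to the working grid (the accessible area M)."""
    if len(occ) < 1:
        raise ValueError("need at least one occurrence")
    exclusions = list(exclusions or [])
    lon_c = grid.lon_centers()
    lat_c = grid.lat_centers()
    glon, glat = np.meshgrid(lon_c, lat_c)
    pts = occ.latlon()
    inside = np.zeros(grid.shape, dtype=bool)
    for lat, lon in pts:
        inside |= haversine_km(lat, lon, glat, glon) <= buffer_km
    if exclusions:
        from shapely.geometry import Point
        flat = inside.ravel()
        cand = np.flatnonzero(flat)
        for i in cand:
            p = Point(glon.ravel()[i], glat.ravel()[i])
            if any(poly.contains(p) for poly in exclusions):
                flat[i] = False
        inside = flat.reshape(grid.shape)
    if not inside.any():
        raise ValueError("calibration region is empty after exclusions")
    vals = np.where(inside, 1.0, np.nan)
    region = CalibrationRegion(mask=grid.copy_with(vals),
                               buffer_km=buffer_km, exclusions=exclusions)
    outside = [str(occ.points["id"].iloc[i]) for i, (lat, lon) in
               enumerate(pts) if not region.contains(lat, lon)]
    if outside:
        raise ValueError(
            f"occurrences fall outside the calibration region: {outside}")
    return region


def thin_occurrences(occ: OccurrenceSet, min_km: float = 50.0,
                     n_replicates: int = 10, seed: int = 0
                     ) -> list[OccurrenceSet]:
    """Spatial thinning to a minimum inter-point distance, replicated.

    Each replicate greedily accepts points in a random order, keeping a
    point only when it is at least ``min_km`` from every accepted one; the
    result is maximal (every rejected point is within ``min_km`` of an
    accepted point).
    """
    if min_km <= 0:
        raise ValueError("min_km must be positive")
    pts = occ.latlon()
    n = len(pts)
    d = haversine_km(pts[:, 0][:, None], pts[:, 1][:, None],
                     pts[:, 0][None, :], pts[:, 1][None, :])
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_replicates):
        order = rng.permutation(n)
        accepted: list[int] = []
        for i in order:
            if all(d[i, j] >= min_km for j in accepted):
                accepted.append(int(i))
        accepted.sort()
        out.append(OccurrenceSet(points=occ.points.iloc[accepted]
                                 .reset_index(drop=True),
                                 note=f"{occ.note} thin>= {min_km}km rep{rep}"))
    return out


# ---------------------------------------------------------------------------
# maxent


@dataclass
class MaxentModel:
    eta: np.ndarray
    beta: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    log_z: float
    n_features: int
    converged: bool
    dropped: list[int] = field(default_factory=list)


def build_features(scores: np.ndarray, means: np.ndarray | None = None,
                   sds: np.ndarray | None = None):
    """Polynomial features of score vectors — linear, squares, pairwise
    products, cubes and fourth powers — standardized by the background
    statistics (returned for reuse on presences/projections).

    The products matter because a climatic envelope that is elliptical in
    the original variables is a *rotated* ellipse in PCA-score space, which
    an axis-aligned quadratic cannot represent; the even quartic terms let
    the exponential-family density take flat-topped, sharp-edged
    (super-Gaussian) shapes instead of being forced Gaussian.
    """
    scores = np.asarray(scores, float)
    k = scores.shape[1]
    cross = [scores[:, i] * scores[:, j]
             for i in range(k) for j in range(i + 1, k)]
    cols = [scores, scores ** 2] \
        + ([np.column_stack(cross)] if cross else []) \
        + [scores ** 3, scores ** 4]
    raw = np.column_stack(cols)
    if means is None:
        means = raw.mean(axis=0)
        sds = raw.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        feats = np.where(sds > 0, (raw - means) / np.where(sds > 0, sds, 1.0),
                         0.0)
    return feats, means, sds


def _maxent_objective(q, f_pres_mean, f_bg, beta):
    p = len(f_pres_mean)
    eta = q[:p] - q[p:]
    u = f_bg @ eta
    umax = u.max()
    log_z = umax + np.log(np.exp(u - umax).sum())
    nll = -(f_pres_mean @ eta) + log_z + beta @ (q[:p] + q[p:])
    w = np.exp(u - log_z)
    e_bg = f_bg.T @ w
    g_eta = -f_pres_mean + e_bg
    grad = np.concatenate([g_eta + beta, -g_eta + beta])
    return nll, grad


def fit_maxent_single(presence_scores: np.ndarray,
                      background_scores: np.ndarray,
                      reg_multiplier: float = 1.0,
                      tol: float = 1e-6) -> MaxentModel:
    """Fit one regularized maxent model (no bootstrap)."""
    m = len(presence_scores)
    if m < 5:
        raise ValueError("need at least 5 presences")
    if len(background_scores) < 10 * m:
        warnings.warn("background smaller than 10x presences")
    f_bg, means, sds = build_features(background_scores)
    dropped = [int(i) for i in np.flatnonzero(sds == 0)]
    if dropped:
        warnings.warn(f"dropping constant features {dropped}")
    f_pres, _, _ = build_features(presence_scores, means, sds)
    p = f_bg.shape[1]
    s_pres = f_pres.std(axis=0)
    beta = reg_multiplier * s_pres / np.sqrt(m)
    beta[dropped] = 1e6          # effectively pins dropped features at zero
    f_pres_mean = f_pres.mean(axis=0)
    res = optimize.minimize(
        _maxent_objective, x0=np.zeros(2 * p), jac=True, method="L-BFGS-B",
        bounds=[(0.0, 60.0)] * (2 * p),
        args=(f_pres_mean, f_bg, beta),
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": tol})
    eta = res.x[:p] - res.x[p:]
    converged = bool(res.success)
    if not converged:
        raise RuntimeError(
            f"maxent solver did not converge: {res.message} "
            f"(nit={res.nit}, final objective {res.fun:.6g})")
    u = f_bg @ eta
    umax = u.max()
    log_z = float(umax + np.log(np.exp(u - umax).sum()))
    return MaxentModel(eta=eta, beta=beta, feature_means=means,
                       feature_sds=sds, log_z=log_z, n_features=p,
                       converged=converged, dropped=dropped)


def fit_maxent(presence_scores: np.ndarray, background_scores: np.ndarray,
               reg_multiplier: float = 1.0, n_boot_reps: int = 100,
               seed: int = 0) -> list[MaxentModel]:
    """Bootstrap-replicated maxent fits (presences resampled with
    replacement, background fixed)."""
    rng = np.random.default_rng(seed)
    m = len(presence_scores)
    models = []
    for _ in range(n_boot_reps):
        idx = rng.integers(0, m, size=m)
        models.append(fit_maxent_single(presence_scores[idx],
                                        background_scores, reg_multiplier))
    return models


def predict_raw(model: MaxentModel, scores: np.ndarray) -> np.ndarray:
    """Raw maxent output exp(eta.f)/Z (Z from the training background)."""
    feats, _, _ = build_features(scores, model.feature_means,
                                 model.feature_sds)
    return np.exp(np.clip(feats @ model.eta - model.log_z, -700.0, 700.0))


# ---------------------------------------------------------------------------
# aggregation and thresholding


def aggregate_replicates(maps: list[np.ndarray],
                         scale: float = 1.0) -> np.ndarray:
    """Cell-wise median over bootstrap replicates, x1000, floored to int.

    The raw maxent output sums to one over the background, so its values
    are of order 1/ncells and a 0-1000 integer grid would collapse to
    zero; ``scale`` converts the raw density to a suitability scale first.
    Passing the background cell count gives the density ratio relative to
    a uniform distribution — a common scale across time slices, which a
    threshold learned on the training slice can be transferred across
    (per-map maximum rescaling would give every slice its own unit).
    """
    stack = np.stack(maps).astype(float) * scale
    med = np.median(stack, axis=0)
    return np.floor(med * 1000.0)


def aggregate_subsets(int_maps: list[np.ndarray]) -> np.ndarray:
    """Cell-wise median over occurrence-subset maps."""
    shapes = {m.shape for m in int_maps}
    if len(shapes) != 1:
        raise ValueError("subset maps are not conformable")
    return np.median(np.stack(int_maps), axis=0)


def predict_and_aggregate(models_per_subset: list[list[MaxentModel]],
                          scores: np.ndarray,
                          scale: float = 1.0) -> np.ndarray:
    """Median-of-replicates then median-of-subsets suitability surface.

    ``scores`` is an (ncells, k) score matrix for one GCM/time slice;
    ``scale`` is the density-to-suitability factor (see
    :func:`aggregate_replicates`), typically the background cell count.
    """
    subset_maps = []
    for models in models_per_subset:
        reps = [predict_raw(m, scores) for m in models]
        subset_maps.append(aggregate_replicates(reps, scale=scale))
    return aggregate_subsets(subset_maps)


def mtp_binarize(suit: Raster, occ: OccurrenceSet) -> tuple[Raster, float]:
    """Minimum-training-presence binarization.

    The threshold is the lowest suitability at any occurrence cell, so
    training omission is zero by construction. Occurrences on nodata cells
    raise with the offending ids listed.
    """
    bad, vals = [], []
    for _, row in occ.points.iterrows():
        try:
            r, c = suit.cell_of(row["lat"], row["lon"])
        except ValueError:
            bad.append(str(row["id"]))
            continue
        v = suit.values[r, c]
        if np.isfinite(v):
            vals.append(v)
        else:
            bad.append(str(row["id"]))
    if bad:
        raise ValueError(f"occurrences on nodata cells: {bad}")
    tau = float(min(vals))
    out = np.where(np.isfinite(suit.values),
                   (suit.values >= tau).astype(float), np.nan)
    return suit.copy_with(out), tau


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class PartialRocResult:
    E: float
    auc_ratio: float
    p: float
    n_boot: int
    resample_fraction: float
    ratios: np.ndarray = field(repr=False, default=None)


def _auc_ratio(cell_vals: np.ndarray, test_vals: np.ndarray,
               E: float) -> float:
    thresholds = np.unique(np.concatenate([cell_vals, test_vals]))
    # descending: x = proportional predicted area, y = sensitivity
    thr = thresholds[::-1]
    x = np.searchsorted(np.sort(cell_vals), thr, side="left")
    x = 1.0 - x / len(cell_vals)
    y = np.searchsorted(np.sort(test_vals), thr, side="left")
    y = 1.0 - y / len(test_vals)
    x = np.concatenate([[0.0], x, [1.0]])
    y = np.concatenate([[0.0], y, [1.0]])
    keep = y >= 1.0 - E
    if keep.sum() < 2:
        # degenerate: fall back to the full curve above the first kept point
        keep = np.ones_like(keep, bool)
    xs, ys = x[keep], y[keep]
    if xs[-1] - xs[0] < 1e-12:
        # zero-width strip: the ratio degenerates to sensitivity over area
        # at that single operating point (1.0 when both are 1)
        return float(ys.mean() / xs[-1]) if xs[-1] > 0 else np.nan
    pauc = np.trapezoid(ys, xs)
    null = (xs[-1] ** 2 - xs[0] ** 2) / 2.0
    return float(pauc / null)


def partial_roc(suit: Raster, test_points: np.ndarray, E: float = 0.01,
                n_boot: int = 1000, resample_frac: float = 0.5,
                seed: int = 0) -> PartialRocResult:
    """Partial-ROC AUC ratio restricted to omission <= E.

    ``test_points`` is an (n, 2) array of lat/lon. The curve plots
    sensitivity against the proportional area predicted present across all
    distinct thresholds; the partial area above sensitivity 1-E is divided
    by the corresponding area under the chance diagonal. Bootstrap
    resamples ``resample_frac`` of the test points with replacement; p is
    the proportion of bootstrap ratios <= 1.
    """
    test_points = np.asarray(test_points, float)
    if len(test_points) < 5:
        raise ValueError("need at least 5 test points")
    cells = suit.values[np.isfinite(suit.values)].ravel()
    if np.all(cells == cells[0]):
        raise ValueError("constant suitability surface: partial ROC undefined")
    tv = []
    for lat, lon in test_points:
        r, c = suit.cell_of(lat, lon)
        v = suit.values[r, c]
        if not np.isfinite(v):
            raise ValueError(f"test point ({lat}, {lon}) on nodata")
        tv.append(v)
    tv = np.asarray(tv)
    obs = _auc_ratio(cells, tv, E)
    rng = np.random.default_rng(seed)
    nsub = max(int(np.ceil(resample_frac * len(tv))), 1)
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, len(tv), size=nsub)
        ratios[b] = _auc_ratio(cells, tv[idx], E)
    p = float(np.mean(ratios <= 1.0))
    return PartialRocResult(E=E, auc_ratio=float(obs), p=p, n_boot=n_boot,
                            resample_fraction=resample_frac, ratios=ratios)


# ---------------------------------------------------------------------------
# MOP extrapolation masking


@dataclass
class MopMap:
    similarity: np.ndarray
    strict_extrapolation: np.ndarray
    alpha: float


def mop_mask(calibration_scores: np.ndarray, projection_scores: np.ndarray,
             alpha: float = 0.1, binary: Raster | None = None
             ) -> tuple[MopMap, Raster | None]:
    """Mobility-oriented parity of projection cells to the calibration cloud.

    Strict extrapolation flags cells with any dimension outside the
    calibration min-max range; elsewhere similarity is 1 minus the mean
    Euclidean distance to the nearest ceil(alpha*n) calibration points,
    normalized by the largest such mean among projection cells. Suitable
    cells under strict extrapolation are removed from the binary map.
    """
    calib = np.asarray(calibration_scores, float)
    proj = np.asarray(projection_scores, float)
    if calib.shape[1] != proj.shape[1]:
        raise ValueError("score dimensionality mismatch")
    if alpha * len(calib) < 1:
        raise ValueError("alpha * n must be at least 1")
    n_ref = int(np.ceil(alpha * len(calib)))
    ok_proj = np.isfinite(proj).all(axis=1)
    lo, hi = calib.min(axis=0), calib.max(axis=0)
    strict = np.zeros(len(proj), bool)
    strict[ok_proj] = ((proj[ok_proj] < lo) | (proj[ok_proj] > hi)).any(axis=1)
    mean_d = np.full(len(proj), np.nan)
    nn = NearestNeighbors(n_neighbors=n_ref).fit(calib)
    if ok_proj.any():
        dist, _ = nn.kneighbors(proj[ok_proj])
        mean_d[ok_proj] = dist.mean(axis=1)
    dmax = np.nanmax(mean_d) if np.isfinite(mean_d).any() else 1.0
    sim = np.where(np.isfinite(mean_d), 1.0 - mean_d / max(dmax, 1e-300),
                   np.nan)
    sim[strict] = 0.0
    sim[~ok_proj] = np.nan
    mop = MopMap(similarity=sim, strict_extrapolation=strict, alpha=alpha)
    masked = None
    if binary is not None:
        vals = binary.values.ravel().copy()
        vals[strict & (vals == 1)] = 0.0
        masked = binary.copy_with(vals.reshape(binary.shape))
    return mop, masked
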