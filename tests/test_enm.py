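"""Niche-modeling operations: thinning, maxent, aggregation, thresholds,
partial ROC, MOP."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from medrefugia.enm import (OccurrenceSet, aggregate_replicates,
                            aggregate_subsets, build_calibration_region,
                            build_features, fit_maxent, fit_maxent_single,
                            mop_mask, mtp_binarize, partial_roc, predict_raw,
                            predict_and_aggregate, thin_occurrences)
from medrefugia.popgen import haversine_km
from medrefugia.rasters import Raster


def occ_from(latlon, note="t"):
    pts = pd.DataFrame({"id": [f"o{i}" for i in range(len(latlon))],
                        "lat": [p[0] for p in latlon],
                        "lon": [p[1] for p in latlon]})
    return OccurrenceSet(points=pts, note=note)


# ---------------------------------------------------------------------------
# calibration region


def test_single_point_buffer_area():
    grid = Raster(np.zeros((80, 80)), -10.0, 30.0, 0.25)
    occ = occ_from([(40.0, 0.0)])
    region = build_calibration_region(occ, grid, buffer_km=350.0)
    area = np.nansum(region.mask.values * grid.cell_areas_km2())
    assert area == pytest.approx(np.pi * 350.0 ** 2, rel=0.05)
    assert region.contains(40.0, 0.0)


def test_region_refused_when_exclusion_covers_buffer():
    from shapely.geometry import box
    grid = Raster(np.zeros((40, 40)), -10.0, 30.0, 0.5)
    occ = occ_from([(40.0, 0.0)])
    with pytest.raises(ValueError):
        build_calibration_region(occ, grid, buffer_km=300.0,
                                 exclusions=[box(-15, 25, 15, 55)])


def test_region_two_distant_points_contains_both():
    grid = Raster(np.zeros((40, 80)), -10.0, 30.0, 0.5)
    occ = occ_from([(40.0, -5.0), (40.0, 20.0)])
    region = build_calibration_region(occ, grid, buffer_km=300.0)
    assert region.contains(40.0, -5.0) and region.contains(40.0, 20.0)
    # midway between the two buffers is outside
    assert not region.contains(40.0, 7.5)


# ---------------------------------------------------------------------------
# thinning


def test_thinning_keeps_all_points_when_already_sparse():
    occ = occ_from([(35.0, 0.0), (36.0, 2.0), (38.0, 5.0)])
    outs = thin_occurrences(occ, min_km=50.0, n_replicates=4, seed=1)
    assert all(len(o) == 3 for o in outs)


def test_thinning_two_close_points_keeps_exactly_one():
    occ = occ_from([(35.0, 0.0), (35.05, 0.05)])
    outs = thin_occurrences(occ, min_km=50.0, n_replicates=6, seed=2)
    assert all(len(o) == 1 for o in outs)


def test_thinning_min_distance_and_maximality():
    rng = np.random.default_rng(3)
    pts = [(lat, lon) for lat, lon in zip(rng.uniform(33, 42, 60),
                                          rng.uniform(-8, 20, 60))]
    occ = occ_from(pts)
    for rep in thin_occurrences(occ, min_km=100.0, n_replicates=3, seed=4):
        kept = rep.latlon()
        d = haversine_km(kept[:, 0][:, None], kept[:, 1][:, None],
                         kept[:, 0][None, :], kept[:, 1][None, :])
        off = d[~np.eye(len(kept), dtype=bool)]
        assert off.min() >= 100.0
        # maximality: every rejected point is within min_km of a kept one
        kept_ids = set(rep.points["id"])
        for _, row in occ.points.iterrows():
            if row["id"] not in kept_ids:
                dd = haversine_km(row["lat"], row["lon"], kept[:, 0],
                                  kept[:, 1])
                assert dd.min() < 100.0


# ---------------------------------------------------------------------------
# maxent


def test_uniform_presences_give_near_zero_coefficients():
    rng = np.random.default_rng(5)
    bg = rng.normal(size=(500, 2))
    pres = bg[rng.integers(0, 500, 200)]
    m = fit_maxent_single(pres, bg)
    assert np.abs(m.eta).max() < 0.3
    p = predict_raw(m, bg)
    assert p.sum() == pytest.approx(1.0, abs=1e-8)
    assert p.max() / p.min() < 3.0


def test_constrained_single_feature_closed_form():
    z = np.zeros((200, 1))
    z[:100] = 1.0
    pres = np.ones((20, 1))
    m = fit_maxent_single(pres, z, reg_multiplier=0.0)
    p = predict_raw(m, z)
    assert p[:100] == pytest.approx(2.0 / 200.0, abs=1e-6)
    assert p[100:].max() < 1e-6


def test_maxent_matches_independent_convex_optimizer():
    from scipy import optimize
    rng = np.random.default_rng(6)
    bg = rng.normal(size=(50, 1))
    pres = rng.normal(loc=1.0, scale=0.5, size=(8, 1))
    mine = fit_maxent_single(pres, bg)
    f_bg, means, sds = build_features(bg)
    f_pr, _, _ = build_features(pres, means, sds)
    beta = f_pr.std(axis=0) / np.sqrt(8)

    def obj(eta):
        u = f_bg @ eta
        lz = u.max() + np.log(np.exp(u - u.max()).sum())
        return -(f_pr.mean(axis=0) @ eta) + lz + beta @ np.abs(eta)

    best = None
    for s in range(4):
        res = optimize.minimize(
            obj, np.random.default_rng(s).normal(scale=0.5,
                                                 size=f_bg.shape[1]),
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 50000,
                     "maxfev": 50000})
        if best is None or res.fun < best.fun:
            best = res
    # collinear features make eta non-unique; the objective value and the
    # fitted distribution are unique
    assert obj(mine.eta) <= best.fun + 1e-8
    u = f_bg @ best.x
    p_oracle = np.exp(u - (u.max() + np.log(np.exp(u - u.max()).sum())))
    assert np.abs(predict_raw(mine, bg) - p_oracle).max() < 1e-4


def test_maxent_raw_output_sums_to_one_over_background():
    rng = np.random.default_rng(7)
    bg = rng.normal(size=(300, 3))
    pres = rng.normal(loc=0.5, size=(25, 3))
    for m in fit_maxent(pres, bg, n_boot_reps=3, seed=8):
        assert predict_raw(m, bg).sum() == pytest.approx(1.0, abs=1e-8)


def test_maxent_bootstrap_is_seeded():
    rng = np.random.default_rng(9)
    bg = rng.normal(size=(200, 2))
    pres = rng.normal(loc=0.8, size=(15, 2))
    a = fit_maxent(pres, bg, n_boot_reps=2, seed=3)
    b = fit_maxent(pres, bg, n_boot_reps=2, seed=3)
    for ma, mb in zip(a, b):
        assert np.array_equal(ma.eta, mb.eta)


def test_maxent_needs_minimum_presences():
    rng = np.random.default_rng(10)
    with pytest.raises(ValueError):
        fit_maxent_single(rng.normal(size=(3, 2)), rng.normal(size=(100, 2)))


# ---------------------------------------------------------------------------
# aggregation


def test_aggregate_identical_maps_is_scaled_floor():
    m = np.full((4, 4), 1e-3)
    out = aggregate_replicates([m, m, m], scale=500.0)
    assert np.all(out == np.floor(1e-3 * 500 * 1000))


def test_aggregate_median_rule():
    maps = [np.array([[v]]) for v in (0.001, 0.002, 0.009)]
    out = aggregate_replicates(maps, scale=1.0)
    assert out[0, 0] == 2.0


def test_aggregate_matches_per_cell_sort_oracle():
    rng = np.random.default_rng(11)
    reps = [rng.random((5, 5)) * 1e-3 for _ in range(7)]
    subsets = [aggregate_replicates(reps, scale=1000.0)]
    got = aggregate_subsets(subsets)
    stack = np.stack(reps)
    oracle = np.floor(np.sort(stack, axis=0)[3] * 1e6)
    assert np.array_equal(got, oracle)


def test_aggregate_subsets_rejects_mismatched_shapes():
    with pytest.raises(ValueError):
        aggregate_subsets([np.zeros((2, 2)), np.zeros((3, 3))])


# ---------------------------------------------------------------------------
# minimum training presence


def test_mtp_threshold_is_lowest_occurrence_value():
    vals = np.arange(25, dtype=float).reshape(5, 5)
    suit = Raster(vals, 0.0, 40.0, 1.0)
    lat, lon = suit.lat_centers(), suit.lon_centers()
    occ = occ_from([(lat[0], lon[4]), (lat[0], lon[3]), (lat[0], lon[2])])
    binary, tau = mtp_binarize(suit, occ)
    assert tau == 2.0                       # 3rd-highest of the top row 0
    assert np.nansum(binary.values) == 23.0
    # training omission is zero by construction
    for la, lo in occ.latlon():
        r, c = suit.cell_of(la, lo)
        assert binary.values[r, c] == 1


def test_mtp_hand_thresholded_toy_grid():
    rng = np.random.default_rng(12)
    vals = rng.integers(0, 100, (5, 5)).astype(float)
    suit = Raster(vals, 0.0, 40.0, 1.0)
    lat, lon = suit.lat_centers(), suit.lon_centers()
    occ = occ_from([(lat[1], lon[1]), (lat[3], lon[2])])
    binary, tau = mtp_binarize(suit, occ)
    assert tau == min(vals[1, 1], vals[3, 2])
    assert np.array_equal(binary.values, (vals >= tau).astype(float))


def test_mtp_occurrence_on_nodata_is_an_error():
    vals = np.arange(25, dtype=float).reshape(5, 5)
    vals[2, 2] = np.nan
    suit = Raster(vals, 0.0, 40.0, 1.0)
    occ = occ_from([(suit.lat_centers()[2], suit.lon_centers()[2])])
    with pytest.raises(ValueError, match="o0"):
        mtp_binarize(suit, occ)


# ---------------------------------------------------------------------------
# partial ROC


def test_partial_roc_perfect_ranking():
    vals = np.linspace(0.0, 1.0, 400).reshape(20, 20)
    suit = Raster(vals, 0.0, 30.0, 0.5)
    lat, lon = suit.lat_centers(), suit.lon_centers()
    pts = [(lat[19], lon[c]) for c in range(12, 20)]
    res = partial_roc(suit, np.array(pts), E=0.05, n_boot=300, seed=1)
    assert res.auc_ratio > 1.5
    assert res.p < 0.05


def test_partial_roc_toy_matches_hand_trapezoids():
    # 6 cells with values 1..6, test points at 5 and 6, E generous enough
    # to keep the whole curve
    vals = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
    suit = Raster(vals, 0.0, 40.0, 1.0)
    lat, lon = suit.lat_centers(), suit.lon_centers()
    pts = np.array([(lat[1], lon[1]), (lat[1], lon[2]),
                    (lat[1], lon[1]), (lat[1], lon[2]),
                    (lat[1], lon[2])])
    res = partial_roc(suit, pts, E=1.0, n_boot=10, seed=2)
    # hand curve over thresholds 6..1:
    # x = 1/6,2/6,...,1 ; y (5 pts: 3 at '6', 2 at '5') = 3/5,1,1,1,1,1
    xs = np.array([0, 1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6, 1.0])
    ys = np.array([0, 3 / 5, 1, 1, 1, 1, 1])
    pauc = np.trapezoid(ys, xs)
    assert res.auc_ratio == pytest.approx(pauc / 0.5, rel=1e-9)


def test_partial_roc_null_calibration():
    ratios = []
    for i in range(60):
        rng = np.random.default_rng(i)
        suit = Raster(rng.random((15, 15)), 0.0, 30.0, 1.0)
        rows = rng.integers(0, 15, 10)
        cols = rng.integers(0, 15, 10)
        pts = np.column_stack([suit.lat_centers()[rows],
                               suit.lon_centers()[cols]])
        ratios.append(partial_roc(suit, pts, E=0.05, n_boot=40,
                                  seed=i).auc_ratio)
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)


def test_partial_roc_refuses_constant_surface():
    suit = Raster(np.ones((10, 10)), 0.0, 30.0, 1.0)
    pts = np.column_stack([suit.lat_centers()[:5], suit.lon_centers()[:5]])
    with pytest.raises(ValueError):
        partial_roc(suit, pts)


# ---------------------------------------------------------------------------
# MOP


def test_mop_exact_match_has_similarity_one():
    # alpha*n = 1 -> similarity measured to the single nearest point
    rng = np.random.default_rng(13)
    calib = rng.normal(size=(100, 3))
    proj = np.vstack([calib[0], calib[0] + 50.0])
    mop, _ = mop_mask(calib, proj, alpha=0.01)
    assert mop.similarity[0] == pytest.approx(1.0, abs=1e-9)
    assert mop.strict_extrapolation[1]
    assert mop.similarity[1] == 0.0


def test_mop_strict_extrapolation_removed_from_binary():
    rng = np.random.default_rng(14)
    calib = rng.normal(size=(60, 2))
    proj = np.vstack([calib, calib[:4] + 100.0])
    binary = Raster(np.ones((8, 8)), 0.0, 30.0, 1.0)
    mop, masked = mop_mask(calib, proj, alpha=0.1, binary=binary)
    assert masked.values.ravel()[60:64].sum() == 0
    assert np.nansum(masked.values) <= np.nansum(binary.values)


def test_mop_similarity_matches_brute_force():
    rng = np.random.default_rng(15)
    calib = rng.normal(size=(20, 2))
    proj = rng.normal(scale=0.8, size=(12, 2))
    alpha = 0.25
    mop, _ = mop_mask(calib, proj, alpha=alpha)
    k = int(np.ceil(alpha * 20))
    means = []
    for p in proj:
        d = np.sort(np.linalg.norm(calib - p, axis=1))
        means.append(d[:k].mean())
    means = np.array(means)
    lo, hi = calib.min(0), calib.max(0)
    strict = ((proj < lo) | (proj > hi)).any(axis=1)
    expect = 1.0 - means / means.max()
    expect[strict] = 0.0
    assert np.allclose(mop.similarity, expect)


def test_mop_alpha_too_small_rejected():
    # alpha * n = 0.05 < 1
    with pytest.raises(ValueError):
        mop_mask(np.zeros((5, 2)), np.zeros((3, 2)), alpha=0.01)


@settings(max_examples=20, deadline=None)
@given(seed=st.integers(min_value=0, max_value=10 ** 6))
def test_masking_never_increases_suitable_area(seed):
    rng = np.random.default_rng(seed)
    calib = rng.normal(size=(40, 2))
    proj = rng.normal(scale=2.0, size=(36, 2))
    binary = Raster((rng.random((6, 6)) > 0.5).astype(float), 0.0, 30.0, 1.0)
    _, masked = mop_mask(calib, proj, alpha=0.2, binary=binary)
    assert np.nansum(masked.values) <= np.nansum(binary.values)
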