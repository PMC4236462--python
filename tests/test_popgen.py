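"""Population-genetic statistics against closed forms and brute-force
oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from medrefugia.popgen import (DistanceMatrix, GeoAlignment, Sample,
                               SummaryStats, UndefinedStatisticError,
                               alignment_summary, collapse_haplotypes,
                               diversity_grid, ewens_k_distribution, fu_fs,
                               great_circle_matrix, haversine_km,
                               locality_matrices, mantel_ibd,
                               neutrality_significance, p_distance_matrix,
                               r2_stat)
from conftest import make_geoalignment


# ---------------------------------------------------------------------------
# haplotypes


def test_collapse_groups_identical_sequences():
    aln = make_geoalignment(["AAAA", "AAAA", "AAAA", "AATA"])
    haps = collapse_haplotypes(aln)
    assert haps.H == 2
    assert sorted(haps.counts.tolist()) == [1, 3]


def test_collapse_excludes_all_missing_sequence():
    aln = make_geoalignment(["AAAA", "AATA", "NNNN"])
    with pytest.warns(UserWarning):
        haps = collapse_haplotypes(aln)
    assert haps.unassigned == ["s2"]
    assert haps.n == 2


def test_collapse_ambiguous_merge_is_surfaced_not_resolved():
    # sNN is compatible with both resolved haplotypes -> set aside
    aln = make_geoalignment(["AAAA", "AATA", "AANA"])
    with pytest.warns(UserWarning):
        haps = collapse_haplotypes(aln)
    assert haps.H == 2
    assert haps.unassigned == ["s2"]


def test_collapse_unique_partial_match_merges():
    aln = make_geoalignment(["AAAA", "CCTA", "AANA"])
    haps = collapse_haplotypes(aln)
    assert haps.H == 2
    assert {"s0", "s2"} in [set(m) for m in haps.members]


def test_collapse_empty_alignment_rejected():
    with pytest.raises(ValueError):
        collapse_haplotypes(GeoAlignment([], L=0))


# ---------------------------------------------------------------------------
# p-distances


def test_p_distance_identical_pair_is_zero(toy_alignment):
    dm, _ = p_distance_matrix(toy_alignment)
    i, j = dm.labels.index("s1"), dm.labels.index("s2")
    assert dm.values[i, j] == 0.0
    assert np.allclose(dm.values, dm.values.T)
    assert np.all(np.diag(dm.values) == 0.0)


def test_p_distance_pairwise_deletion_direct_count():
    # 10 sites, 2 unresolved in one sequence, 1 difference among the 8 left
    aln = make_geoalignment(["ACGTACGTAC", "ACGTACGTNN", "TCGTACGTNN"])
    dm, _ = p_distance_matrix(aln)
    assert dm.values[1, 2] == pytest.approx(1.0 / 8.0)


def test_p_distance_group_means():
    aln = make_geoalignment(["AAAA", "AAAT", "TTTA", "TTTT"])
    groups = {"s0": "X", "s1": "X", "s2": "Y", "s3": "Y"}
    _, table = p_distance_matrix(aln, groups)
    between = table.query("group1 == 'X' and group2 == 'Y'")["mean_p"].iloc[0]
    within_x = table.query("group1 == 'X' and group2 == 'X'")["mean_p"].iloc[0]
    assert within_x == pytest.approx(0.25)
    assert between == pytest.approx((0.75 + 1.0 + 1.0 + 0.75) / 4)


def test_p_distance_no_comparable_sites_is_missing():
    aln = make_geoalignment(["AANN", "NNAA"])
    dm, _ = p_distance_matrix(aln)
    assert np.isnan(dm.values[0, 1])


# ---------------------------------------------------------------------------
# summary statistics


def test_summary_all_identical():
    aln = make_geoalignment(["ACGT"] * 4)
    st = alignment_summary(aln)
    assert (st.Hd, st.pi, st.S) == (0.0, 0.0, 0)


def test_summary_haplotype_diversity_closed_form():
    # haplotype counts {3,1}: Hd = (4/3)(1 - 10/16) = 0.5
    aln = make_geoalignment(["AAAA", "AAAA", "AAAA", "AATA"])
    st = alignment_summary(aln)
    assert st.Hd == pytest.approx(0.5)
    assert st.H == 2 and st.S == 1


def test_summary_invariant_under_reordering():
    seqs = ["ACGTAC", "ACGTAT", "TCGTAC", "ACGTAC"]
    st1 = alignment_summary(make_geoalignment(seqs))
    st2 = alignment_summary(make_geoalignment(seqs[::-1]))
    assert st1.Hd == pytest.approx(st2.Hd)
    assert st1.pi == pytest.approx(st2.pi)
    assert st1.S == st2.S


def test_summary_pi_complete_deletion():
    aln = make_geoalignment(["ACGT", "ACGA", "NCGA"])
    st = alignment_summary(aln)
    # complete deletion drops site 0; 3 sites left, pairs differ at site 3:
    # d(0,1)=1, d(0,2)=1, d(1,2)=0 -> kbar=2/3, pi=2/9
    assert st.L_eff == 3
    assert st.kbar == pytest.approx(2.0 / 3.0)
    assert st.pi == pytest.approx(2.0 / 9.0)


# ---------------------------------------------------------------------------
# Fu's Fs


def brute_force_ewens(n, theta):
    """P(K=k) via explicit unsigned Stirling numbers (independent path)."""
    from sympy.functions.combinatorial.numbers import stirling
    denom = np.prod([theta + i for i in range(n)])
    return np.array([0.0] + [
        float(stirling(n, k, kind=1, signed=False)) * theta ** k / denom
        for k in range(1, n + 1)])


@pytest.mark.parametrize("n,theta", [(4, 1.5), (7, 0.8), (12, 3.0)])
def test_ewens_distribution_matches_brute_force(n, theta):
    mine = ewens_k_distribution(n, theta)
    oracle = brute_force_ewens(n, theta)
    assert np.allclose(mine, oracle, atol=1e-12)


def test_fu_fs_against_brute_force_oracle():
    st = SummaryStats(n=4, L_eff=10, S=3, H=3, Hd=0.8, pi=0.15, kbar=1.5,
                      U=np.zeros(4))
    oracle = brute_force_ewens(4, 1.5)
    s_prime = oracle[3:].sum()
    expected = np.log(s_prime / (1 - s_prime))
    assert fu_fs(st) == pytest.approx(expected, rel=1e-10)


def test_fu_fs_boundary_single_haplotype_is_plus_infinity():
    st = SummaryStats(n=5, L_eff=10, S=1, H=1, Hd=0.0, pi=0.0, kbar=0.0,
                      U=np.zeros(5))
    assert fu_fs(st) == np.inf


def test_fu_fs_undefined_when_no_segregating_sites():
    st = SummaryStats(n=5, L_eff=10, S=0, H=1, Hd=0.0, pi=0.0, kbar=0.0,
                      U=np.zeros(5))
    with pytest.raises(UndefinedStatisticError):
        fu_fs(st)


def test_fu_fs_large_n_no_overflow():
    st = SummaryStats(n=300, L_eff=800, S=50, H=60, Hd=0.9, pi=0.01,
                      kbar=8.0, U=np.zeros(300))
    val = fu_fs(st)
    assert np.isfinite(val)


# ---------------------------------------------------------------------------
# R2


def test_r2_two_sequence_closed_form():
    st = SummaryStats(n=2, L_eff=10, S=1, H=2, Hd=1.0, pi=0.1, kbar=1.0,
                      U=np.array([1.0, 0.0]))
    assert r2_stat(st) == pytest.approx(0.5)


def test_r2_matches_textbook_recomputation_on_random_alignment():
    rng = np.random.default_rng(0)
    from medrefugia.synthdata import simulate_alignment, simulate_genealogy
    tree = simulate_genealogy(8, seed=3)
    aln = simulate_alignment(tree, L=60, s_fixed=9, seed=4)
    ga = make_geoalignment(aln.sequences)
    st = alignment_summary(ga)
    expected = np.sqrt(np.mean((st.U - st.kbar / 2) ** 2)) / st.S
    assert r2_stat(st) == pytest.approx(expected)


def test_r2_undefined_when_no_segregating_sites():
    st = SummaryStats(n=4, L_eff=10, S=0, H=1, Hd=0.0, pi=0.0, kbar=0.0,
                      U=np.zeros(4))
    with pytest.raises(UndefinedStatisticError):
        r2_stat(st)


# ---------------------------------------------------------------------------
# simulation significance


def test_neutrality_significance_is_seed_deterministic():
    a = neutrality_significance(-1.0, "Fs", n=12, S=8, n_sims=200, seed=5)
    b = neutrality_significance(-1.0, "Fs", n=12, S=8, n_sims=200, seed=5)
    assert (a.p, a.ci95) == (b.p, b.ci95)
    assert a.p + a.p_upper >= 1.0      # add-one rule on both tails


def test_neutrality_significance_median_observation_has_central_p():
    from medrefugia.popgen import null_distribution
    null = null_distribution("R2", 12, 8, 400, seed=6)
    med = float(np.median(null))
    res = neutrality_significance(med, "R2", n=12, S=8, n_sims=400, seed=7)
    assert 0.3 < res.p < 0.7


def test_neutrality_significance_preconditions():
    with pytest.raises(ValueError):
        neutrality_significance(0.0, "Fs", n=2, S=5)
    with pytest.raises(ValueError):
        neutrality_significance(0.0, "Fs", n=10, S=0)


# ---------------------------------------------------------------------------
# geography


def test_great_circle_identical_and_antipodal_points():
    pts = pd.DataFrame({"name": ["a", "b", "c"],
                        "lat": [0.0, 0.0, 0.0],
                        "lon": [0.0, 0.0, 180.0]})
    dm = great_circle_matrix(pts)
    assert dm.values[0, 1] == 0.0
    assert dm.values[0, 2] == pytest.approx(np.pi * 6371.0, rel=1e-9)


def test_great_circle_matches_spherical_law_of_cosines():
    rng = np.random.default_rng(8)
    lat = rng.uniform(-80, 80, 12)
    lon = rng.uniform(-179, 179, 12)
    dm = great_circle_matrix(pd.DataFrame({"n": range(12), "lat": lat,
                                           "lon": lon}))
    p1, p2 = np.radians(lat), np.radians(lon)
    for i in range(12):
        for j in range(i + 1, 12):
            cosd = (np.sin(p1[i]) * np.sin(p1[j])
                    + np.cos(p1[i]) * np.cos(p1[j]) * np.cos(p2[i] - p2[j]))
            d = 6371.0 * np.arccos(np.clip(cosd, -1, 1))
            assert dm.values[i, j] == pytest.approx(d, rel=5e-3, abs=1e-6)


def test_great_circle_invalid_coordinates_rejected():
    with pytest.raises(ValueError):
        great_circle_matrix(pd.DataFrame({"n": [1], "lat": [95.0],
                                          "lon": [0.0]}))


# ---------------------------------------------------------------------------
# Mantel


def _perfect_matrices(n=6):
    rng = np.random.default_rng(9)
    lat = rng.uniform(30, 45, n)
    lon = rng.uniform(-5, 20, n)
    geo = great_circle_matrix(pd.DataFrame({"n": range(n), "lat": lat,
                                            "lon": lon}))
    gen = DistanceMatrix(geo.labels, np.log1p(geo.values) / 10.0)
    return gen, geo


def test_mantel_perfect_monotone_association():
    gen, geo = _perfect_matrices()
    res = mantel_ibd(gen, geo, n_perm=199, seed=1)
    assert res.r > 0.99
    assert res.p == pytest.approx(1.0 / 200.0)


def test_mantel_refuses_fewer_than_five_localities():
    gen, geo = _perfect_matrices(4)
    with pytest.raises(ValueError):
        mantel_ibd(gen, geo, n_perm=99, seed=1)


def test_mantel_p_matches_exhaustive_enumeration():
    gen, geo = _perfect_matrices(5)
    rng = np.random.default_rng(10)
    noisy = gen.values + rng.normal(scale=0.05, size=(5, 5))
    noisy = (noisy + noisy.T) / 2
    np.fill_diagonal(noisy, 0.0)
    gen2 = DistanceMatrix(gen.labels, noisy)
    iu = np.triu_indices(5, 1)
    e = np.log(np.where(geo.values <= 0,
                        geo.values[geo.values > 0].min() / 2, geo.values))
    y = e[iu]
    r_obs = np.corrcoef(gen2.values[iu], y)[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(range(5)):
        xp = gen2.values[np.ix_(perm, perm)][iu]
        total += 1
        if np.corrcoef(xp, y)[0, 1] >= r_obs - 1e-12:
            count += 1
    exact_p = count / total
    res = mantel_ibd(gen2, geo, n_perm=4999, seed=2)
    # permutation p converges to the exhaustive value
    assert res.p == pytest.approx(exact_p, abs=4 * np.sqrt(exact_p / 5000))


def test_mantel_constant_matrix_rejected():
    gen, geo = _perfect_matrices(6)
    const = DistanceMatrix(gen.labels, np.ones((6, 6)) - np.eye(6))
    with pytest.raises(ValueError):
        mantel_ibd(const, geo, n_perm=99, seed=1)


def test_single_locality_dataset_is_refused(toy_alignment):
    aln = GeoAlignment([Sample(s.id, s.sequence, "L1", 36.0, 3.0)
                        for s in toy_alignment.samples])
    gen, geo = locality_matrices(aln)
    with pytest.raises(ValueError):
        mantel_ibd(gen, geo)


# ---------------------------------------------------------------------------
# diversity grid


def test_diversity_grid_monomorphic_pool():
    aln = make_geoalignment(["ACGT"] * 6, lats=[36.0] * 6, lons=[3.0] * 6,
                            locs=["L1"] * 6)
    dg = diversity_grid(aln, spacing_km=100, m=5, B=50, seed=1)
    row = dg.points[~dg.points.missing].iloc[0]
    assert row.HT_mean == 0.0
    assert row.HR_mean == 1.0
    assert row.R_mean == 1.0


def test_diversity_grid_all_unique_haplotypes():
    seqs = ["AAAA", "AAAT", "AATA", "ATAA", "TAAA"]
    aln = make_geoalignment(seqs, lats=[36.0] * 5, lons=[3.0] * 5,
                            locs=[f"L{i}" for i in range(5)])
    dg = diversity_grid(aln, spacing_km=100, radius_km=500, m=5, B=20, seed=1)
    row = dg.points[~dg.points.missing].iloc[0]
    assert row.HT_mean == pytest.approx(1.0)
    assert row.HR_mean == pytest.approx(5.0)


def test_diversity_grid_bootstrap_matches_exhaustive_enumeration():
    seqs = ["AAAA", "AAAA", "AAAT", "AAAT", "AATA", "ATAA"]
    locs = ["L1", "L1", "L2", "L2", "L1", "L3"]
    aln = make_geoalignment(seqs, lats=[36.0] * 6, lons=[3.0] * 6, locs=locs)
    B = 4000
    dg = diversity_grid(aln, spacing_km=100, radius_km=500, m=5, B=B, seed=3)
    row = dg.points[~dg.points.missing].iloc[0]
    # exhaustive over all C(6,5) draws
    hap = [0, 0, 1, 1, 2, 3]
    n_loc = {0: 1, 1: 1, 2: 1, 3: 1}   # localities per haplotype
    ht, hr, rr = [], [], []
    for combo in itertools.combinations(range(6), 5):
        counts = np.bincount([hap[i] for i in combo])
        counts = counts[counts > 0]
        p = counts / 5
        ht.append(5 / 4 * (1 - (p ** 2).sum()))
        hr.append(len(counts))
        rr.append(np.mean([1.0 / n_loc[hap[i]] for i in combo]))
    for got, pop in ((row.HT_mean, ht), (row.HR_mean, hr), (row.R_mean, rr)):
        se = np.std(pop) / np.sqrt(B)
        assert got == pytest.approx(np.mean(pop), abs=max(3 * se, 1e-12))


def test_diversity_grid_flags_undersampled_points():
    aln = make_geoalignment(["ACGT"] * 3, lats=[36.0] * 3, lons=[3.0] * 3,
                            locs=["L1"] * 3)
    dg = diversity_grid(aln, spacing_km=100, m=5, B=10, seed=1)
    assert dg.points.missing.all()
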