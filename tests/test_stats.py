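import itertools
import math

import numpy as np
import pytest
from scipy.special import comb

from methkit.calls import MethylationDataset
from methkit.stats import (cooccurrence, correspondence_analysis,
                           fisher_all_sites, fisher_site_test,
                           hamming_bicluster, hamming_distance_matrix,
                           mannwhitney_set_test, methylation_summary)


def make_ds(matrix, positions=None, ids=None):
    matrix = np.asarray(matrix, dtype=float)
    n, m = matrix.shape
    positions = positions or [10 * (k + 1) for k in range(m)]
    return MethylationDataset(
        clone_ids=ids or [f"c{i}" for i in range(n)],
        cpg_positions=list(positions),
        calls=matrix,
        spans=[(1, 100)] * n,
    )


# ------------------------------------------------------------------ oracles

def fisher_oracle(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def point(x):  # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return (comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True)
                / comb(n, c1, exact=True))

    p_obs = point(a)
    return sum(point(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if point(x) <= p_obs * (1 + 1e-9))


def mw_u(a, b):
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


def mw_permutation_oracle(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating group assignments."""
    pooled = list(a) + list(b)
    n_a = len(a)
    obs = min(mw_u(a, b), mw_u(b, a))
    hits = total = 0
    for comb_idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in comb_idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in comb_idx]
        if min(mw_u(ga, gb), mw_u(gb, ga)) <= obs + 1e-9:
            hits += 1
        total += 1
    return hits / total


def chi2_over_n(X) -> float:
    X = np.asarray(X, float)
    n = X.sum()
    E = np.outer(X.sum(1), X.sum(0)) / n
    return float(((X - E) ** 2 / E).sum() / n)


# ---------------------------------------------------------------- summaries

class TestMethylationSummary:
    def test_toy_percentages(self, toy_dataset):
        s = methylation_summary(toy_dataset)
        assert s["percent_methylated"].tolist() == [50.0, 50.0, 50.0,
                                                    50.0, 25.0]

    def test_missing_excluded_from_denominator(self):
        ds = make_ds([[1, 0], [np.nan, 0], [np.nan, 1], [np.nan, np.nan]])
        s = methylation_summary(ds)
        assert s["percent_methylated"].iloc[0] == 100.0
        assert s["n_missing"].iloc[0] == 3

    def test_all_missing_site_flagged(self):
        ds = make_ds([[np.nan, 1], [np.nan, 0]])
        assert math.isnan(methylation_summary(ds)["percent_methylated"].iloc[0])


# ------------------------------------------------------------ co-occurrence

class TestCooccurrence:
    def test_toy_perfect_correlations(self, toy_dataset):
        m = cooccurrence(toy_dataset, mode="correlation")
        assert m.values[0, 1] == 1.0    # sites 1,2 perfectly correlated
        assert m.values[1, 2] == -1.0   # sites 2,3 perfectly anti-correlated
        assert np.allclose(np.diag(m.values), 1.0)

    def test_symmetry_and_range(self, toy_dataset):
        m = cooccurrence(toy_dataset)
        np.testing.assert_array_equal(m.values, m.values.T)
        ok = ~np.isnan(m.values)
        assert (np.abs(m.values[ok]) <= 1.0 + 1e-12).all()

    def test_shared_fraction_is_one_minus_hamming(self, toy_dataset):
        m = cooccurrence(toy_dataset, mode="shared_fraction")
        d = hamming_distance_matrix(toy_dataset.calls.T)
        np.testing.assert_allclose(m.values, 1.0 - d)

    def test_correlation_matches_generic_oracle(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 2, (12, 6)).astype(float)
        calls[rng.random((12, 6)) < 0.2] = np.nan
        m = cooccurrence(make_ds(calls))
        for i in range(6):
            for j in range(i + 1, 6):
                ok = ~np.isnan(calls[:, i]) & ~np.isnan(calls[:, j])
                x, y = calls[ok, i], calls[ok, j]
                if ok.sum() < 2 or x.std() == 0 or y.std() == 0:
                    assert np.isnan(m.values[i, j])
                else:
                    assert m.values[i, j] == pytest.approx(
                        np.corrcoef(x, y)[0, 1])

    def test_constant_column_flagged_not_nan_propagated(self):
        ds = make_ds([[1, 1], [1, 0], [1, 1]])
        m = cooccurrence(ds)
        assert np.isnan(m.values[0, 1])
        assert m.values[0, 0] == 1.0  # diagonal still defined

    def test_neighbours_only_masks_distant_pairs(self, toy_dataset):
        m = cooccurrence(toy_dataset, neighbours_only=True)
        assert np.isnan(m.values[0, 2])
        assert not np.isnan(m.values[0, 1])
        assert len(m.neighbour_pairs()) == 4

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence(make_ds([[1], [0]]))


# ------------------------------------------------------------- Fisher test

class TestFisherSiteTest:
    @pytest.mark.parametrize("table,expected", [
        ([[3, 0], [0, 3]], 0.10),
        ([[2, 2], [2, 2]], 1.0),
        ([[5, 0], [0, 5]], 2 / 252),
    ])
    def test_known_tables(self, table, expected):
        # build a dataset realising the table at one site
        (a, b), (c, d) = table
        calls = [[1]] * a + [[0]] * b + [[1]] * c + [[0]] * d
        calls = np.hstack([np.array(calls, float),
                           np.zeros((len(calls), 1))])
        ids = [f"c{i}" for i in range(len(calls))]
        ds = make_ds(calls, ids=ids)
        groups = {cid: ("A" if i < a + b else "B")
                  for i, cid in enumerate(ids)}
        res = fisher_site_test(ds, groups, ds.cpg_positions[0])
        assert res.p_value == pytest.approx(expected, rel=1e-9)

    def test_matches_enumeration_oracle_small_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            table = rng.integers(0, 8, (2, 2))
            if table.sum() == 0 or table.sum() > 30:
                continue
            if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            (a, b), (c, d) = table
            calls = np.array([[1]] * a + [[0]] * b + [[1]] * c + [[0]] * d,
                             float)
            calls = np.hstack([calls, np.zeros((len(calls), 1))])
            ids = [f"c{i}" for i in range(len(calls))]
            ds = make_ds(calls, ids=ids)
            groups = {cid: ("A" if i < a + b else "B")
                      for i, cid in enumerate(ids)}
            res = fisher_site_test(ds, groups, ds.cpg_positions[0])
            assert res.p_value == pytest.approx(
                fisher_oracle(table.tolist()), rel=1e-9)

    def test_degenerate_table_flagged(self):
        ds = make_ds([[1, 0], [1, 0], [1, 1], [1, 1]])
        groups = {"c0": "A", "c1": "A", "c2": "B", "c3": "B"}
        res = fisher_site_test(ds, groups, ds.cpg_positions[0])
        assert res.degenerate and res.p_value == 1.0

    def test_bh_adjustment_monotone(self):
        ds = make_ds(np.array([[1, 1, 0], [1, 0, 0], [0, 1, 1],
                               [0, 0, 1]], float))
        groups = {"c0": "A", "c1": "A", "c2": "B", "c3": "B"}
        df = fisher_all_sites(ds, groups, bh_correct=True)
        assert (df["p_bh"] >= df["p_value"] - 1e-12).all()
        assert (df["p_bh"] <= 1.0).all()


# -------------------------------------------------------------- Mann-Whitney

class TestMannWhitney:
    def test_complete_separation(self):
        # group percentages (10,20,30) vs (70,80,90): U=0, two-sided p=0.10
        calls_a = np.zeros((10, 3))
        calls_a[:1, 0] = 1  # site percentages 10, 20, 30
        calls_a[:2, 1] = 1
        calls_a[:3, 2] = 1
        ds_a = make_ds(calls_a)
        ds_b = make_ds(1 - ds_a.calls)
        u, p = mannwhitney_set_test(ds_a, ds_b)
        assert u == 0.0
        assert p == pytest.approx(0.10)

    def test_identical_groups_p_one(self, toy_dataset):
        u, p = mannwhitney_set_test(toy_dataset, toy_dataset)
        assert p == 1.0

    def test_matches_permutation_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            a = rng.integers(0, 2, (4, 6)).astype(float)
            b = rng.integers(0, 2, (5, 6)).astype(float)
            ds_a, ds_b = make_ds(a), make_ds(b)
            pa = methylation_summary(ds_a)["percent_methylated"].to_numpy()
            pb = methylation_summary(ds_b)["percent_methylated"].to_numpy()
            _, p = mannwhitney_set_test(ds_a, ds_b)
            assert p == pytest.approx(mw_permutation_oracle(pa, pb))

    def test_all_ties_well_defined(self):
        ds_a = make_ds(np.ones((3, 4)))
        ds_b = make_ds(np.ones((3, 4)))
        u, p = mannwhitney_set_test(ds_a, ds_b)
        assert math.isfinite(u) and 0.0 <= p <= 1.0

    def test_mismatched_positions_rejected(self):
        ds_a = make_ds(np.ones((3, 3)), positions=[1, 5, 9])
        ds_b = make_ds(np.ones((3, 3)), positions=[2, 5, 9])
        with pytest.raises(ValueError):
            mannwhitney_set_test(ds_a, ds_b)


# ------------------------------------------------------------- biclustering

class TestHammingBicluster:
    def test_toy_merge_order(self, toy_dataset):
        res = hamming_bicluster(toy_dataset)
        # clones 1,2 identical: first merge at distance 0
        first = res.row_linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == 0.0
        # clones 3,4 (d=0.2) merge before joining the {1,2} cluster (d=0.8+)
        second = res.row_linkage[1]
        assert {int(second[0]), int(second[1])} == {2, 3}
        assert second[2] == pytest.approx(0.2)

    def test_distance_properties(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 2, (8, 10)).astype(float)
        d = hamming_distance_matrix(calls)
        np.testing.assert_array_equal(d, d.T)
        assert (np.diag(d) == 0).all()
        # triangle inequality on the unnormalised count (same denominator)
        counts = d * 10
        for i, j, k in itertools.permutations(range(8), 3):
            assert counts[i, k] <= counts[i, j] + counts[j, k] + 1e-9

    def test_duplicated_rows_zero_distance(self):
        ds = make_ds(np.tile([1.0, 0.0, 1.0], (4, 1)))
        d = hamming_distance_matrix(ds.calls)
        assert (d == 0).all()

    def test_opposite_clones_distance_one(self):
        ds = make_ds([[1, 1, 1], [0, 0, 0]])
        assert hamming_distance_matrix(ds.calls)[0, 1] == 1.0

    def test_undefined_pair_refused(self):
        ds = make_ds([[1, np.nan], [np.nan, 0], [1, 0]])
        with pytest.raises(ValueError):
            hamming_bicluster(ds)


# ---------------------------------------------------- correspondence analysis

class TestCorrespondenceAnalysis:
    def test_toy_percent_inertia(self, toy_dataset):
        ca = correspondence_analysis(toy_dataset)
        assert ca.percent_inertia[0] == pytest.approx(85.71, abs=0.01)
        assert ca.percent_inertia[1] == pytest.approx(14.29, abs=0.01)

    def test_toy_total_inertia(self, toy_dataset):
        ca = correspondence_analysis(toy_dataset)
        assert ca.total_inertia == pytest.approx(7 / 6)

    def test_total_inertia_equals_chi2_over_n_random(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            X = rng.integers(0, 6, (rng.integers(2, 9), rng.integers(2, 9)))
            if (X.sum(0) == 0).any() or (X.sum(1) == 0).any():
                continue
            ca = correspondence_analysis(X)
            assert ca.total_inertia == pytest.approx(chi2_over_n(X))
            assert ca.percent_inertia.sum() == pytest.approx(100.0, abs=1e-9)

    def test_rank_one_table_zero_inertia(self):
        X = np.outer([1, 2, 3], [4, 5, 6])
        ca = correspondence_analysis(X)
        assert ca.total_inertia == 0.0
        assert len(ca.principal_inertias) == 0

    def test_row_permutation_invariance(self, toy_dataset):
        ca = correspondence_analysis(toy_dataset)
        perm = [3, 1, 0, 2]
        ca_p = correspondence_analysis(toy_dataset.calls[perm],
                                       row_ids=perm)
        np.testing.assert_allclose(ca_p.principal_inertias,
                                   ca.principal_inertias)
        np.testing.assert_allclose(np.abs(ca_p.row_coords),
                                   np.abs(ca.row_coords[perm]), atol=1e-9)

    def test_duplicate_clones_coincide(self, toy_dataset):
        ca = correspondence_analysis(toy_dataset)
        np.testing.assert_allclose(ca.row_coords[0], ca.row_coords[1],
                                   atol=1e-12)

    def test_inertias_nonincreasing_and_dim_bound(self, toy_dataset):
        ca = correspondence_analysis(toy_dataset)
        lam = ca.principal_inertias
        assert (np.diff(lam) <= 1e-12).all()
        assert len(lam) <= min(4, 5) - 1

    def test_all_zero_row_dropped_with_warning(self):
        X = np.array([[1, 2], [0, 0], [3, 1]], float)
        with pytest.warns(UserWarning):
            ca = correspondence_analysis(X)
        assert len(ca.row_ids) == 2

    def test_zero_mass_rejected(self):
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            correspondence_analysis(np.zeros((3, 3)))
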