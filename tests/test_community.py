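"""Abundance accounting, Bray-Curtis, NMDS, PerMANOVA and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform

from cemag.community import (
    AbundanceTable, benjamini_hochberg, bray_curtis, bray_curtis_matrix,
    nmds, pairwise_permanova_bh, permanova, presence_and_filter,
)

from oracles import brute_force_bray_curtis


def _table(values, experiments):
    """Build an AbundanceTable from a genomes x samples array (percent)."""
    values = np.asarray(values, float)
    n_samples = values.shape[1]
    cols = [f"s{i + 1}" for i in range(n_samples)]
    abundance = pd.DataFrame(values, columns=cols,
                             index=[f"g{i + 1}" for i in range(values.shape[0])])
    residual = 100.0 - abundance.sum(axis=0)
    metadata = pd.DataFrame({"sample_id": cols, "experiment": experiments,
                             "timepoint": range(1, n_samples + 1)})
    return AbundanceTable(abundance, residual, metadata)


class TestPresenceAndFilter:
    @pytest.fixture()
    def fixture_table(self):
        #            s1    s2    s3    s4
        values = [[10.0,  0.0, 40.0, 30.0],   # g1: high everywhere it appears
                  [ 1.0,  0.5,  0.0,  0.0],   # g2: exactly 1% once
                  [ 0.0,  0.9,  0.0,  0.6],   # g3: present, never >=1%
                  [ 0.0,  0.0,  0.0,  0.0]]   # g4: absent
        return _table(values, ["e1", "e1", "e2", "e2"])

    def test_exact_one_percent_included(self, fixture_table):
        _, high, _ = presence_and_filter(fixture_table)
        assert "g2" in high

    def test_high_abundance_set_matches_hand_count(self, fixture_table):
        _, high, _ = presence_and_filter(fixture_table)
        assert high == {"g1", "g2"}

    def test_zero_abundance_not_present(self, fixture_table):
        present, _, _ = presence_and_filter(fixture_table)
        assert "g4" not in present["e1"] and "g4" not in present["e2"]
        assert present["e1"] == {"g1", "g2", "g3"}
        assert present["e2"] == {"g1", "g3"}

    def test_summary_matches_brute_force(self, fixture_table):
        _, _, summary = presence_and_filter(fixture_table)
        e1 = summary[summary.experiment == "e1"].iloc[0]
        # represented sums: s1 = 11.0, s2 = 1.4
        assert e1.min_represented == pytest.approx(1.4)
        assert e1.max_represented == pytest.approx(11.0)
        assert e1.median_represented == pytest.approx((1.4 + 11.0) / 2)

    def test_empty_table_rejected(self):
        t = _table([[50.0, 50.0]], ["e1", "e1"])
        t.abundance = t.abundance.iloc[:0]
        with pytest.raises(ValueError):
            presence_and_filter(t)


class TestBrayCurtis:
    def test_identical_vectors(self):
        assert bray_curtis([10, 20], [10, 20]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([10, 0], [0, 10]) == 1.0

    def test_hand_example(self):
        assert bray_curtis([60, 40], [20, 80]) == pytest.approx(0.4)

    @given(st.lists(st.floats(0.0, 100.0), min_size=2, max_size=8),
           st.lists(st.floats(0.0, 100.0), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_direct_formula(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if sum(x) + sum(y) == 0:
            return
        assert bray_curtis(x, y) == pytest.approx(brute_force_bray_curtis(x, y))


class TestNMDS:
    def test_planar_points_recovered_with_low_stress(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(12, 2))
        d = squareform(pdist(pts))
        res = nmds(d, seed=0, n_restarts=4)
        assert res.stress < 0.01

    def test_stress_non_increasing_within_restart(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        d = squareform(pdist(pts))
        res = nmds(d, seed=1, n_restarts=1)
        trace = np.array(res.stress_trace)
        assert np.all(np.diff(trace) <= 1e-8)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nmds(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_stress_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(9, 4))
        d = squareform(pdist(pts))
        perm = rng.permutation(9)
        s1 = nmds(d, seed=3, n_restarts=3).stress
        s2 = nmds(d[np.ix_(perm, perm)], seed=3, n_restarts=3).stress
        assert abs(s1 - s2) < 0.02

    def test_separable_experiments_separate_in_ordination(self):
        from cemag.simulate import SimConfig, TruthRecord, simulate_abundance

        truths = [TruthRecord(f"g{i}", "uninvolved") for i in range(15)]
        wins = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, abundance_experiments=2, samples_per_experiment=4)
            t = simulate_abundance(truths, cfg)
            bc = bray_curtis_matrix(t)
            res = nmds(bc, seed=seed, n_restarts=2)
            xy = res.coordinates.values
            exp = t.experiment_of().values
            d = squareform(pdist(xy))
            within, between = [], []
            for i in range(len(exp)):
                for j in range(i + 1, len(exp)):
                    (within if exp[i] == exp[j] else between).append(d[i, j])
            if np.mean(within) < np.mean(between):
                wins += 1
        assert wins >= 9


class TestPermanova:
    def test_floor_p_value(self):
        """Well-separated clouds: observed F beats all permutations, so
        p hits its floor 1/(n_perm+1)."""
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.1, size=(10, 3))
        b = rng.normal(5, 0.1, size=(10, 3))
        d = squareform(pdist(np.vstack([a, b])))
        labels = ["a"] * 10 + ["b"] * 10
        f, p = permanova(d, labels, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)
        assert f > 100

    def test_matches_scikit_bio(self):
        """Pseudo-F agrees with the independent scikit-bio implementation."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 4))
        d = squareform(pdist(pts))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        f, _ = permanova(d, labels, n_perm=99, seed=0)
        dm = skbio_stats.DistanceMatrix(d, ids=[str(i) for i in range(12)])
        ref = skbio_stats.permanova(dm, grouping=list(labels), permutations=99)
        assert f == pytest.approx(ref["test statistic"], rel=1e-9)

    def test_f_invariant_under_consistent_relabeling(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 3))
        d = squareform(pdist(pts))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        perm = rng.permutation(10)
        f1, _ = permanova(d, labels, n_perm=9, seed=0)
        f2, _ = permanova(d[np.ix_(perm, perm)], labels[perm], n_perm=9, seed=0)
        assert f1 == pytest.approx(f2)

    def test_singleton_group_rejected(self):
        d = squareform(pdist(np.random.default_rng(0).normal(size=(5, 2))))
        with pytest.raises(ValueError, match="fewer than 2"):
            permanova(d, ["a", "a", "a", "a", "b"], n_perm=9)


class TestBenjaminiHochberg:
    def test_single_test_unchanged(self):
        assert benjamini_hochberg([0.03])[0] == pytest.approx(0.03)

    def test_hand_example(self):
        adj = benjamini_hochberg([0.01, 0.02, 0.04])
        assert adj == pytest.approx([0.03, 0.03, 0.04])

    def test_monotone_in_raw_p(self):
        raw = np.array([0.001, 0.01, 0.02, 0.2, 0.6])
        adj = benjamini_hochberg(raw)
        assert np.all(np.diff(adj) >= -1e-12)

    def test_pairwise_table_flags_significance(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.2, size=(5, 3))
        b = rng.normal(4, 0.2, size=(5, 3))
        c = rng.normal(8, 0.2, size=(5, 3))
        d = squareform(pdist(np.vstack([a, b, c])))
        labels = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        out = pairwise_permanova_bh(d, labels, n_perm=199, seed=0)
        assert len(out) == 3
        assert out.significant.all()
        assert np.all(out.p_adjusted.values >= out.p_value.values - 1e-12)
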