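"""Stage-stratified correlation, FDR, hub summaries, trajectories and
clustering -- each checked against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ddrcoupling.coexpression import (
    bh_fdr,
    correlation_matrix,
    coupling_trajectory,
    divergence_ratio,
    hierarchical_cluster,
    hub_coupling_summary,
    pearson_r,
    stage_correlation_table,
)
from ddrcoupling.panel import STAGES, hub_targets
from ddrcoupling.synthetic import default_spec, generate_dataset


def _oracle_pearson(x, y):
    """Brute-force correlation sum and exact t-test p."""
    n = len(x)
    xm, ym = x - np.mean(x), y - np.mean(y)
    r = np.sum(xm * ym) / np.sqrt(np.sum(xm**2) * np.sum(ym**2))
    t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, p


def _oracle_bh(p):
    """Step-up q-values by hand: p*m/i with running tail minimum."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, p[idx] * m / rank_from_top)
        q[idx] = running
    return q


class TestPearson:
    def test_perfect_positive_and_negative(self):
        r, _ = pearson_r([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        r, _ = pearson_r([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, _ = pearson_r([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)

    def test_matches_bruteforce_oracle_on_random_panels(self, rng):
        X = rng.standard_normal((14, 50))
        for i, j in itertools.combinations(range(14), 2):
            r, p = pearson_r(X[i], X[j])
            r0, p0 = _oracle_pearson(X[i], X[j])
            assert abs(r - r0) < 1e-10
            assert abs(p - p0) < 1e-10

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            pearson_r([1, 2], [3, 4])


class TestBHFDR:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_stepup_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60)
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_oracle_and_monotone(self, p):
        q = bh_fdr(p)
        assert np.allclose(q, _oracle_bh(p), atol=1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all(q <= 1.0) and np.all(q >= p)


class TestStageCorrelationTable:
    def test_91_records_and_invariants(self, small_cohort):
        _, X, ann = small_cohort
        table = stage_correlation_table(X, ann, "carcinoma")
        assert len(table) == 91
        assert (table["q"] >= table["p"] - 1e-15).all()
        assert np.allclose(table["r2"], table["r"] ** 2, atol=1e-12)
        assert (table["r"].abs() <= 1).all()
        # each unordered pair exactly once, oriented by the panel order
        gene_pos = {g: i for i, g in enumerate(X.index)}
        assert all(gene_pos[a] < gene_pos[b] for a, b in zip(table.gene_a, table.gene_b))

    def test_sample_order_permutation_invariant(self, small_cohort):
        _, X, ann = small_cohort
        t1 = stage_correlation_table(X, ann, "normal")
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ann))
        t2 = stage_correlation_table(X.iloc[:, perm], ann.iloc[perm], "normal")
        assert np.allclose(t1["r"], t2["r"], atol=1e-12)

    def test_planted_strong_pair_attains_minimum_q(self):
        """When one pair's planted carcinoma R^2 (0.549) dominates every
        other coupling, that pair attains the minimum q in every draw."""
        from ddrcoupling.synthetic import unique_pair_spec

        for seed in range(10):
            spec = unique_pair_spec(seed=seed)
            X, ann = generate_dataset(spec)
            table = stage_correlation_table(X, ann, "carcinoma")
            top = table.loc[table["p"].idxmin()]
            assert {top["gene_a"], top["gene_b"]} == {"DDR2", "COL11A1"}

    def test_missing_stage_rejected(self, small_cohort):
        _, X, ann = small_cohort
        with pytest.raises(ValueError, match="absent"):
            stage_correlation_table(X, ann, "metastasis")


class TestHubSummary:
    def _records_from_planted(self, r2_by_target):
        rows = []
        for stage_i, stage in enumerate(STAGES):
            for target, r2s in r2_by_target.items():
                rows.append(("DDR2", target, stage, np.sqrt(r2s[stage_i]), r2s[stage_i], 0.001, 0.001, 100))
        return pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "stage", "r", "r2", "p", "q", "n"]
        )

    def test_reported_stage_means_give_reported_fold(self):
        """Stage means (0.147, 0.234, 0.380) imply a 2.59-fold overall
        coupling enhancement."""
        records = self._records_from_planted(
            {f"T{i}": (0.147, 0.234, 0.380) for i in range(12)}
        )
        s = hub_coupling_summary(records, "DDR2", tuple(f"T{i}" for i in range(12)))
        assert s.mean_r2_by_stage["normal"] == pytest.approx(0.147)
        assert round(s.overall_fold, 2) == 2.59
        assert round(s.per_transition_fold["normal->adenoma"], 2) == 1.59
        assert round(s.per_transition_fold["adenoma->carcinoma"], 2) == 1.62

    def test_zero_coupling_folds_are_nan(self):
        records = self._records_from_planted({f"T{i}": (0.0, 0.0, 0.0) for i in range(3)})
        s = hub_coupling_summary(records, "DDR2", ("T0", "T1", "T2"))
        assert s.mean_r2_by_stage["carcinoma"] == 0.0
        assert np.isnan(s.overall_fold)

    def test_divergence_ratio_of_reported_means(self):
        a = self._records_from_planted({f"T{i}": (0.147, 0.234, 0.380) for i in range(12)})
        sa = hub_coupling_summary(a, "DDR2", tuple(f"T{i}" for i in range(12)))
        b = self._records_from_planted({f"T{i}": (0.031, 0.021, 0.017) for i in range(12)})
        sb = hub_coupling_summary(b, "DDR2", tuple(f"T{i}" for i in range(12)))
        assert round(divergence_ratio(sa, sb, "carcinoma"), 1) == 22.4
        assert round(divergence_ratio(sa, sb, "normal"), 1) == 4.7

    def test_missing_pair_listed_in_error(self):
        records = self._records_from_planted({"T0": (0.1, 0.1, 0.1)})
        with pytest.raises(ValueError, match="T9"):
            hub_coupling_summary(records, "DDR2", ("T0", "T9"))


class TestCouplingTrajectory:
    def _records(self, r2s):
        rows = []
        for stage, r2 in zip(STAGES, r2s):
            rows.append(("DDR2", "COL11A1", stage, np.sqrt(r2), r2, 0.01, 0.01, 100))
        return pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "stage", "r", "r2", "p", "q", "n"]
        )

    @pytest.mark.parametrize(
        "r2s, expected_class, expected_delta",
        [
            ((0.006, 0.235, 0.549), "de_novo", 0.543),
            ((0.325, 0.384, 0.577), "progressive", 0.252),
            ((0.2, 0.2, 0.2), "flat", 0.0),
            ((0.4, 0.3, 0.2), "declining", -0.2),
        ],
    )
    def test_kinetic_classes_and_deltas(self, r2s, expected_class, expected_delta):
        t = coupling_trajectory(self._records(r2s), ("DDR2", "COL11A1"))
        assert t.kinetic_class == expected_class
        assert t.delta_r2["normal->carcinoma"] == pytest.approx(expected_delta, abs=1e-12)

    def test_transition_deltas_sum_to_overall(self):
        t = coupling_trajectory(self._records((0.05, 0.33, 0.41)), ("DDR2", "COL11A1"))
        total = t.delta_r2["normal->adenoma"] + t.delta_r2["adenoma->carcinoma"]
        assert total == pytest.approx(t.delta_r2["normal->carcinoma"], abs=1e-12)

    def test_fold_suppressed_below_floor(self):
        t = coupling_trajectory(self._records((0.0005, 0.2, 0.5)), ("DDR2", "COL11A1"))
        assert np.isnan(t.fold_r2["normal->adenoma"])
        assert np.isnan(t.fold_r2["normal->carcinoma"])
        assert t.delta_r2["normal->carcinoma"] == pytest.approx(0.4995)

    def test_missing_stage_rejected(self):
        records = self._records((0.1, 0.2, 0.3)).iloc[:2]
        with pytest.raises(ValueError, match="missing"):
            coupling_trajectory(records, ("DDR2", "COL11A1"))


def _oracle_average_linkage(dist):
    """Exhaustive agglomerative average linkage: cluster distance is the
    mean of all inter-cluster pairwise distances."""
    clusters = [[i] for i in range(len(dist))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return sorted(heights)


class TestHierarchicalCluster:
    def test_perfectly_correlated_pair_merges_at_zero(self):
        r = pd.DataFrame(
            [[1.0, 1.0, 0.2], [1.0, 1.0, 0.2], [0.2, 0.2, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        d = hierarchical_cluster(r)
        assert d.merge_heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_sign_symmetric_distance(self):
        r = pd.DataFrame(
            [[1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [0.0, 0.0, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        d = hierarchical_cluster(r)
        assert d.merge_heights[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_average_linkage_oracle(self, rng):
        for _ in range(5):
            raw = rng.standard_normal((6, 40))
            r = pd.DataFrame(np.corrcoef(raw), index=list("abcdef"), columns=list("abcdef"))
            d = hierarchical_cluster(r)
            dist = 1 - np.abs(r.to_numpy())
            np.fill_diagonal(dist, 0)
            assert np.allclose(
                sorted(d.merge_heights), _oracle_average_linkage(dist), atol=1e-10
            )

    def test_newick_round_trips_leaf_set(self, small_cohort, tmp_path):
        from io import StringIO

        from Bio import Phylo

        _, X, ann = small_cohort
        d = hierarchical_cluster(correlation_matrix(X, ann, "carcinoma"))
        tree = Phylo.read(StringIO(d.to_newick()), "newick")
        leaves = {leaf.name for leaf in tree.get_terminals()}
        assert leaves == set(X.index)

    def test_asymmetric_matrix_rejected(self):
        r = pd.DataFrame([[1.0, 0.5], [0.4, 1.0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(r)
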