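"""Stroke-adapted preprocessing: symmetrization, size correction,
right-hemisphere percentile thresholding, zero-degree pruning."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import lesionctl as lc
from lesionctl.prep import (
    correct_links,
    prep_connectome,
    regional_lesion_summary,
    remove_zero_degree,
    symmetrize_streamlines,
    threshold_spurious,
)

from conftest import make_connectome, random_symmetric


class TestSymmetrize:
    def test_averages_both_directions(self):
        a = np.zeros((3, 3))
        a[1, 2], a[2, 1] = 10.0, 6.0
        out = symmetrize_streamlines(a)
        assert out[1, 2] == out[2, 1] == 8.0

    def test_idempotent_on_symmetric_input(self, rng):
        a = random_symmetric(6, rng)
        out = symmetrize_streamlines(a)
        np.testing.assert_array_equal(np.triu(out, 1), np.triu(a, 1))

    def test_transpose_oracle(self, rng):
        a = rng.uniform(0, 5, (5, 5))
        expected = (a + a.T) / 2
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(symmetrize_streamlines(a), expected)

    def test_rejects_non_square(self):
        with pytest.raises(ValueError, match="square"):
            symmetrize_streamlines(np.ones((2, 3)))


class TestCorrectLinks:
    def test_hand_arithmetic(self):
        a = np.array([[0.0, 100.0], [100.0, 0.0]])
        out = correct_links(a, np.array([200.0, 300.0]))
        assert out[0, 1] == pytest.approx(0.4)

    def test_equal_volumes_uniform_rescale(self, rng):
        a = random_symmetric(5, rng)
        out = correct_links(a, np.full(5, 50.0))
        np.testing.assert_allclose(out, a / 50.0)

    def test_zero_weight_stays_zero_and_volume_validation(self):
        a = np.zeros((2, 2))
        assert correct_links(a, np.array([1.0, 2.0])).sum() == 0
        with pytest.raises(ValueError, match="positive"):
            correct_links(a, np.array([1.0, 0.0]))


class TestThresholdSpurious:
    def test_degenerate_equal_weights_nothing_removed(self):
        # all right-hemisphere links equal w: threshold = w, strict '<' keeps them
        a = np.zeros((4, 4))
        a[2, 3] = a[3, 2] = 5.0   # right-internal
        a[0, 1] = a[1, 0] = 5.0   # left-internal, equal weight
        conn = make_connectome(a, hemisphere=["L", "L", "R", "R"])
        out, report = threshold_spurious(conn)
        assert report.threshold_value == 5.0
        assert np.count_nonzero(np.triu(out.adjacency, 1)) == 2

    def test_six_node_toy_matches_brute_force(self):
        # right-internal nonzero weights {1..5}; brute-force percentile rule
        a = np.zeros((6, 6))
        rr_pairs = [(3, 4), (3, 5), (4, 5)]
        rr_weights = [1.0, 2.0, 3.0]
        for (i, j), w in zip(rr_pairs, rr_weights):
            a[i, j] = a[j, i] = w
        lr_pairs = [(0, 3), (1, 4)]
        lr_weights = [4.0, 5.0]
        for (i, j), w in zip(lr_pairs, lr_weights):
            a[i, j] = a[j, i] = w
        a[0, 1] = a[1, 0] = 0.5   # weak left link, should die
        conn = make_connectome(a, hemisphere=["L"] * 3 + ["R"] * 3)
        out, report = threshold_spurious(conn, percentile=20)
        expected_threshold = np.percentile(rr_weights, 20)
        assert report.threshold_value == pytest.approx(expected_threshold)
        all_weights = rr_weights + lr_weights + [0.5]
        expected_survivors = sum(w >= expected_threshold for w in all_weights)
        assert report.n_links_after == expected_survivors
        assert report.right_hemisphere_link_count == 3

    def test_raising_percentile_never_adds_links(self, rng):
        a = random_symmetric(10, rng, density=0.7)
        conn = make_connectome(a)
        counts = [
            threshold_spurious(conn, percentile=p)[1].n_links_after
            for p in (0, 20, 50, 80)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_no_right_links_rejected(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        conn = make_connectome(a, hemisphere=["L", "L", "R", "R"])
        with pytest.raises(ValueError, match="right-hemisphere"):
            threshold_spurious(conn)

    def test_symmetry_preserved(self, rng):
        a = random_symmetric(8, rng)
        out, _ = threshold_spurious(make_connectome(a))
        np.testing.assert_array_equal(out.adjacency, out.adjacency.T)


class TestRemoveZeroDegree:
    def test_complete_graph_untouched(self):
        a = np.ones((4, 4)) - np.eye(4)
        out, report = remove_zero_degree(make_connectome(a))
        assert out.n_nodes == 4 and report.removed_nodes == []

    def test_path_plus_isolate(self):
        a = np.zeros((6, 6))
        for i in range(4):
            a[i, i + 1] = a[i + 1, i] = 1.0
        conn = make_connectome(a)  # node 5 isolated
        out, report = remove_zero_degree(conn)
        assert report.removed_nodes == [("n5", 1)]
        assert out.node_ids == ["n0", "n1", "n2", "n3", "n4"]

    def test_all_isolated_rejected(self):
        with pytest.raises(ValueError, match="empty network"):
            remove_zero_degree(make_connectome(np.zeros((5, 5))))

    def test_one_by_one_ledger_order(self):
        # two isolates: lowest index removed first, rounds increase
        a = np.zeros((5, 5))
        a[2, 3] = a[3, 2] = 1.0
        out, report = remove_zero_degree(make_connectome(a))
        assert report.removed_nodes == [("n0", 1), ("n1", 2), ("n4", 3)]
        assert out.node_ids == ["n2", "n3"]


class TestPipelineProperties:
    def test_threshold_fixed_value_then_prune_idempotent(self, rng):
        # re-applying the recorded threshold and the pruning pass changes
        # nothing (the percentile itself shifts once weak links are gone,
        # so the *rule* is re-anchored to the recorded value)
        a = random_symmetric(12, rng, density=0.4)
        conn = make_connectome(a)
        once, rep1 = threshold_spurious(conn)
        once, _ = remove_zero_degree(once)
        again = once.adjacency.copy()
        again[(again < rep1.threshold_value) & (again > 0)] = 0.0
        np.testing.assert_array_equal(once.adjacency, again)
        twice, rep2 = remove_zero_degree(once)
        np.testing.assert_array_equal(once.adjacency, twice.adjacency)
        assert rep2.removed_nodes == []

    def test_stages_preserve_invariants(self, rng):
        raw = rng.uniform(0, 100, (10, 10))
        conn = make_connectome(symmetrize_streamlines(raw))
        prepped, _ = prep_connectome(conn)
        a = prepped.adjacency
        assert np.all(a >= 0)
        assert np.all(np.diag(a) == 0)
        np.testing.assert_allclose(a, a.T)
        assert np.all(prepped.degrees() > 0)

    def test_removals_track_lesion_severity(self):
        # more severe synthetic lesions -> at least as many zero-degree removals
        base = lc.generate_base_connectome(40, 0.15, 1e5, seed=2)
        removals = []
        for severity in (0.0, 0.3, 0.6, 0.9):
            if severity == 0:
                lesioned = base
            else:
                lesioned = lc.apply_synthetic_lesion(
                    base, severity, "L_region_000", seed=3
                )
            _, report = prep_connectome(lesioned)
            removals.append(len(report.removed_nodes))
        rho = spearmanr([0.0, 0.3, 0.6, 0.9], removals).statistic
        assert rho > 0


class TestRegionalSummary:
    def test_single_participant_identity(self, rng):
        conn = make_connectome(random_symmetric(6, rng))
        table = regional_lesion_summary([conn])
        np.testing.assert_allclose(
            table.loc[conn.node_ids, "mean_degree"], conn.degrees()
        )

    def test_mean_lesion_fraction(self, rng):
        a = random_symmetric(4, rng)
        c1 = make_connectome(a, lesion=[0.2, 0, 0, 0])
        c2 = make_connectome(a, lesion=[0.6, 0, 0, 0])
        table = regional_lesion_summary([c1, c2])
        assert table.loc["n0", "mean_lesion_fraction"] == pytest.approx(0.4)

    def test_matches_brute_force_on_cohort(self, rng):
        cohort = []
        for _ in range(10):
            n = int(rng.integers(4, 8))
            cohort.append(make_connectome(random_symmetric(n, rng)))
        table = regional_lesion_summary(cohort)
        # brute force: loop over participants possessing each region
        for label in table.index:
            degs = [
                c.degrees()[c.node_ids.index(label)]
                for c in cohort
                if label in c.node_ids
            ]
            assert table.loc[label, "mean_degree"] == pytest.approx(np.mean(degs))
            assert table.loc[label, "n_participants"] == len(degs)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            regional_lesion_summary([])
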