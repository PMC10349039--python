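"""Synthetic cohort generator: base connectomes, the lesion operator, and
the planted network-level mediation structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import lesionctl as lc
from lesionctl.cohort import COVARIATE_COLUMNS, SyntheticTruth
from lesionctl.stats import partial_correlation


class TestBaseConnectome:
    def test_complete_graph_case(self):
        conn = lc.generate_base_connectome(4, density=1.0, weight_scale=10.0,
                                           seed=1)
        off = conn.adjacency[np.triu_indices(4, 1)]
        assert (off > 0).all()

    def test_edge_count_within_binomial_band(self):
        conn = lc.generate_base_connectome(100, density=0.3, weight_scale=50.0,
                                           seed=7)
        n_edges = np.count_nonzero(np.triu(conn.adjacency, 1))
        mean = 0.3 * 4950
        sd = np.sqrt(4950 * 0.3 * 0.7)
        assert abs(n_edges - mean) < 3 * sd

    def test_determinism(self):
        a = lc.generate_base_connectome(30, 0.4, 5.0, seed=3)
        b = lc.generate_base_connectome(30, 0.4, 5.0, seed=3)
        np.testing.assert_array_equal(a.adjacency, b.adjacency)
        np.testing.assert_array_equal(a.region_volume, b.region_volume)

    def test_homotopic_mirror_blocks(self):
        conn = lc.generate_base_connectome(20, 0.5, 1.0, seed=2)
        half = 10
        np.testing.assert_array_equal(
            conn.adjacency[:half, :half],
            conn.adjacency[half:, half:],
        )
        np.testing.assert_array_equal(conn.region_volume[:half],
                                      conn.region_volume[half:])

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError, match="even"):
            lc.generate_base_connectome(5, 0.3, 1.0, seed=0)
        with pytest.raises(ValueError, match="density"):
            lc.generate_base_connectome(4, 1.5, 1.0, seed=0)


class TestLesionOperator:
    def test_zero_severity_is_identity(self):
        base = lc.generate_base_connectome(20, 0.5, 1.0, seed=4)
        out = lc.apply_synthetic_lesion(base, 0.0, "L_region_000", seed=1)
        np.testing.assert_array_equal(out.adjacency, base.adjacency)
        assert not out.region_lesion_fraction.any()

    def test_right_hemisphere_untouched_and_left_attenuated(self):
        base = lc.generate_base_connectome(40, 0.4, 1.0, seed=5)
        for severity in (0.2, 0.5, 0.8):
            out = lc.apply_synthetic_lesion(base, severity, "L_region_003",
                                            seed=9)
            right = ~base.left_mask()
            np.testing.assert_array_equal(
                out.adjacency[np.ix_(right, right)],
                base.adjacency[np.ix_(right, right)],
            )
            left = base.left_mask()
            assert (
                out.adjacency[left].sum() <= base.adjacency[left].sum()
            )
            assert (out.adjacency <= base.adjacency + 1e-12).all()

    def test_severe_lesion_isolates_a_left_node(self):
        base = lc.generate_base_connectome(100, 0.3, 50.0, seed=7)
        out = lc.apply_synthetic_lesion(base, 0.95, "L_rolandic_operculum",
                                        seed=4)
        left_deg = out.degrees()[out.left_mask()]
        assert (left_deg == 0).any()
        right = ~out.left_mask()
        np.testing.assert_array_equal(
            out.adjacency[np.ix_(right, right)],
            base.adjacency[np.ix_(right, right)],
        )

    def test_lesion_fractions_recorded_and_decay(self):
        base = lc.generate_base_connectome(20, 0.6, 1.0, seed=1)
        out = lc.apply_synthetic_lesion(base, 0.5, "L_region_002", seed=2)
        focus = out.index_of("L_region_002")
        assert out.region_lesion_fraction[focus] == pytest.approx(0.5)
        assert out.region_lesion_fraction.max() == pytest.approx(0.5)
        assert not out.region_lesion_fraction[~out.left_mask()].any()

    def test_unknown_and_right_focus_rejected(self):
        base = lc.generate_base_connectome(10, 0.5, 1.0, seed=1)
        with pytest.raises(KeyError):
            lc.apply_synthetic_lesion(base, 0.2, "nonexistent", seed=0)
        with pytest.raises(ValueError, match="left-hemisphere"):
            lc.apply_synthetic_lesion(base, 0.2, "R_region_000", seed=0)


class TestGenerateCohort:
    def test_cardinality_and_record_invariants(self):
        truth = SyntheticTruth(n_participants=93, seed=11)
        bundle = lc.generate_cohort(truth)
        assert len(bundle.connectomes) == 93
        assert len(bundle.table) == 93
        assert bundle.table["id"].is_unique
        gap = bundle.table["predicted_brain_age"] - bundle.table["chronological_age"]
        np.testing.assert_allclose(gap, bundle.table["brain_age_gap"],
                                   atol=1e-9)
        assert bundle.table["wab_aq"].between(0, 100).all()

    def test_determinism_under_fixed_seed(self):
        truth = SyntheticTruth(n_participants=10, seed=5)
        b1 = lc.generate_cohort(truth)
        b2 = lc.generate_cohort(truth)
        pd.testing.assert_frame_equal(b1.table, b2.table)
        np.testing.assert_array_equal(
            b1.connectomes[3].adjacency, b2.connectomes[3].adjacency
        )

    def test_zero_noise_recovers_direct_effect(self):
        """With noise off, the direct path comes back to three decimals."""
        truth = SyntheticTruth(
            n_participants=40, c_prime=-0.71, noise_sd_m=0.0, noise_sd_y=0.0,
            seed=17,
        )
        bundle = lc.generate_cohort(truth)
        assert bundle.diagnostics["n_clipped"] == 0
        t = bundle.table
        res = lc.mediate(
            t["brain_age_gap"].to_numpy(),
            t["mediator_controllability"].to_numpy(),
            t["wab_aq"].to_numpy(),
            covariates=t[COVARIATE_COLUMNS],
            n_boot=20,
            seed=1,
        )
        assert res.direct_effect.estimate == pytest.approx(-0.71, abs=5e-4)
        assert res.b_path.estimate == pytest.approx(truth.b_path, abs=1e-6)

    def test_null_truth_shows_no_mediator_outcome_association(self):
        """a = b = 0: partial correlation between computed mediator
        controllability and severity should rarely reach significance."""
        nonsig = 0
        n_rep = 10
        for rep in range(n_rep):
            truth = SyntheticTruth(
                n_participants=40, a_path=0.0, b_path=0.0, seed=300 + rep,
            )
            t = lc.generate_cohort(truth).table
            ok = np.isfinite(t["mediator_controllability"])
            _, p = partial_correlation(
                t.loc[ok, "mediator_controllability"],
                t.loc[ok, "wab_aq"],
                controls=t.loc[ok, COVARIATE_COLUMNS],
            )
            nonsig += p > 0.05
        assert nonsig / n_rep > 0.5

    def test_gap_couples_to_computed_mediator(self):
        """The planted a path must appear as a negative partial association
        between gap and the network-computed mediator controllability."""
        truth = SyntheticTruth(n_participants=93, a_path=-0.15, seed=23)
        t = lc.generate_cohort(truth).table
        ok = np.isfinite(t["mediator_controllability"])
        r, p = partial_correlation(
            t.loc[ok, "brain_age_gap"],
            t.loc[ok, "mediator_controllability"],
            controls=t.loc[ok, ["lesion_volume", "chronological_age"]],
        )
        assert r < 0 and p < 0.05

    def test_demographics_within_study_ranges(self):
        t = lc.generate_cohort(SyntheticTruth(n_participants=50, seed=2)).table
        assert t["chronological_age"].between(29, 80).all()
        assert t["education"].between(12, 20).all()
        assert t["months_post_stroke"].between(10, 241).all()
        assert set(t["sex"].unique()) <= {0.0, 1.0}
        assert t["lesion_volume"].between(2.4, 470).all()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SyntheticTruth(noise_sd_y=-1.0)
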