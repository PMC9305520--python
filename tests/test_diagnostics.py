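import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hdps import (
    CodeHierarchy,
    CohortTable,
    NearIVRule,
    ValidationError,
    asd_binary,
    association_scatter,
    balance_table,
    bias_distribution,
    concept_summary,
    flag_near_ivs,
    importance_weight,
    mean_asd,
    prevalence_scatter,
    ps_overlap_summary,
)
from hdps.diagnostics import NEAR_IV_RELAXED, NEAR_IV_STRICT
from hdps.estimation import PSResult


class TestASD:
    def test_equal_prevalence_is_zero(self):
        assert asd_binary(0.3, 0.3) == 0.0

    def test_hand_arithmetic(self):
        # 100*0.2/sqrt((0.21+0.09)/2) = 100*0.2/sqrt(0.15)
        assert asd_binary(0.3, 0.1) == pytest.approx(100 * 0.2 / math.sqrt(0.15))
        assert asd_binary(0.3, 0.1) == pytest.approx(51.64, abs=0.01)

    def test_degenerate_variance_zero_convention(self):
        assert asd_binary(1.0, 1.0) == 0.0
        assert asd_binary(0.0, 0.0) == 0.0

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_symmetry(self, p1, p0):
        assert asd_binary(p1, p0) == pytest.approx(asd_binary(p0, p1))


class TestBalanceTable:
    def _cohort(self, n=40):
        rng = np.random.default_rng(0)
        return CohortTable(
            pd.DataFrame(
                {
                    "patient_id": [f"p{i}" for i in range(n)],
                    "index_date": "2020-01-01",
                    "exposure": np.tile([0, 1], n // 2),
                    "event": rng.integers(0, 2, n),
                    "followup_time": 100.0,
                }
            ),
            predefined=[],
        )

    def test_unit_weights_reproduce_unweighted_asd(self):
        cohort = self._cohort()
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(
            {"b": rng.integers(0, 2, cohort.n), "cont": rng.standard_normal(cohort.n)},
            index=pd.Index(cohort.patient_ids.values, name="patient_id"),
        )
        ones = pd.Series(1.0, index=frame.index)
        out = balance_table(frame, cohort, {"w": ones})
        np.testing.assert_allclose(out["asd_w"], out["asd_unweighted"], atol=1e-12)

    def test_perfectly_balanced_covariate_is_zero_everywhere(self):
        cohort = self._cohort()
        frame = pd.DataFrame(
            {"bal": np.tile([1, 1, 0, 0], cohort.n // 4)},
            index=pd.Index(cohort.patient_ids.values, name="patient_id"),
        )
        ones = pd.Series(1.0, index=frame.index)
        out = balance_table(frame, cohort, {"w": ones})
        assert out.loc[0, "asd_unweighted"] == 0.0
        assert out.loc[0, "asd_w"] == 0.0

    def test_nonpositive_group_weight_total_rejected(self):
        cohort = self._cohort()
        frame = pd.DataFrame(
            {"b": np.tile([0, 1], cohort.n // 2)},
            index=pd.Index(cohort.patient_ids.values, name="patient_id"),
        )
        bad = pd.Series(
            np.where(cohort.exposure.to_numpy() == 1, -1.0, 1.0), index=frame.index
        )
        with pytest.raises(ValidationError, match="non-positive"):
            balance_table(frame, cohort, {"w": bad})


class TestImportanceWeight:
    def test_boundaries(self):
        assert importance_weight(1, 250) == 1.0
        assert importance_weight(250, 250) == pytest.approx(1 / 250)
        assert importance_weight(126, 250) == pytest.approx(0.5)

    def test_strictly_decreasing_in_rank(self):
        weights = [importance_weight(r, 50) for r in range(1, 51)]
        assert all(a > b for a, b in zip(weights, weights[1:]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            importance_weight(0, 10)
        with pytest.raises(ValidationError):
            importance_weight(11, 10)


class TestMeanASD:
    def test_single_covariate_either_way(self):
        assert mean_asd([7.2]) == 7.2
        assert mean_asd([7.2], importance=True, weights=[0.4]) == pytest.approx(7.2)

    def test_hand_weighted_mean(self):
        assert mean_asd([4, 2], importance=True, weights=[1.0, 0.5]) == pytest.approx(
            5 / 1.5
        )

    def test_vanishing_weight_limit(self):
        # second covariate's weight -> 0: importance mean -> first ASD
        assert mean_asd([10, 0], importance=True, weights=[1.0, 1e-12]) == pytest.approx(
            10.0
        )

    def test_ranks_with_predefined_weight_one(self):
        # ranks: predefined (None) -> 1.0; rank 1 of N=2 -> 1.0; rank 2 -> 0.5
        out = mean_asd([2, 4, 8], importance=True, ranks=[None, 1, 2], N=2)
        assert out == pytest.approx((2 * 1 + 4 * 1 + 8 * 0.5) / 2.5)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            mean_asd([])


class TestOverlap:
    def _cohort_scores(self, s1, s0):
        n1, n0 = len(s1), len(s0)
        cohort = CohortTable(
            pd.DataFrame(
                {
                    "patient_id": [f"p{i}" for i in range(n1 + n0)],
                    "index_date": "2020-01-01",
                    "exposure": [1] * n1 + [0] * n0,
                    "event": np.tile([0, 1], (n1 + n0) // 2),
                    "followup_time": 100.0,
                }
            ),
            predefined=[],
        )
        scores = pd.Series(
            np.r_[s1, s0], index=pd.Index(cohort.patient_ids.values, name="patient_id")
        )
        ps = PSResult("m", [], scores, True)
        return cohort, ps

    def test_identical_distributions_give_overlap_one(self):
        s = np.linspace(0.05, 0.95, 50)
        cohort, ps = self._cohort_scores(s, s)
        out = ps_overlap_summary(ps, ps, cohort)
        assert out["overlap"]["m"] == pytest.approx(1.0)

    def test_disjoint_supports_give_overlap_zero(self):
        cohort, ps = self._cohort_scores(
            np.linspace(0.7, 0.95, 50), np.linspace(0.05, 0.3, 50)
        )
        out = ps_overlap_summary(ps, ps, cohort)
        assert out["overlap"]["m"] == pytest.approx(0.0)

    def test_hdps_model_separates_groups_more(self, small_run):
        out = ps_overlap_summary(
            small_run.ps_predefined, small_run.ps_hdps, small_run.cohort
        )
        assert out["overlap"]["hdps"] < out["overlap"]["predefined"]


def _ptable(rows):
    return pd.DataFrame(
        rows, columns=["name", "dimension", "pc1", "pc0", "rr_ce", "rr_cd"]
    )


class TestPrevalenceScatter:
    def test_equal_prevalence_on_identity_unflagged(self):
        out = prevalence_scatter(_ptable([("a", "d", 0.2, 0.2, 1.0, 1.0)]))
        assert out.loc[0, "pr"] == 1.0
        assert not out.loc[0, "outside_band"]

    def test_pr_three_flagged(self):
        out = prevalence_scatter(_ptable([("a", "d", 0.3, 0.1, 3.0, 1.0)]))
        assert out.loc[0, "pr"] == pytest.approx(3.0)
        assert out.loc[0, "outside_band"]

    def test_zero_prevalence_uses_continuity_and_flags(self):
        out = prevalence_scatter(_ptable([("a", "d", 0.3, 0.0, 4.0, 1.0)]))
        assert np.isfinite(out.loc[0, "pr"])
        assert out.loc[0, "pr_corrected"]
        assert out.loc[0, "outside_band"]


class TestBiasDistribution:
    def test_sequence_non_increasing_and_counts_conserve(self, small_run):
        dist = bias_distribution(small_run.priority)
        vals = dist["abs_log_bias"].to_numpy()
        assert (np.diff(vals) <= 1e-12).all()
        assert sum(dist.attrs["dimension_counts"].values()) == len(dist)

    def test_unranked_input_rejected(self):
        with pytest.raises(ValidationError):
            bias_distribution(_ptable([("a", "d", 0.2, 0.1, 2.0, 1.0)]))


class TestAssociationScatter:
    def test_strength_arithmetic(self):
        out = association_scatter(
            _ptable(
                [
                    ("null", "d", 0.2, 0.2, 1.0, 1.0),
                    ("iv", "d", 0.4, 0.1, 2.0, 1.05),
                    ("protective", "d", 0.1, 0.2, 0.5, 1.0),
                ]
            )
        ).set_index("name")
        assert out.loc["null", "strength_exposure"] == 0.0
        assert out.loc["iv", "strength_exposure"] == pytest.approx(1.0)
        assert out.loc["iv", "strength_outcome"] == pytest.approx(0.05)
        assert out.loc["protective", "strength_exposure"] == pytest.approx(0.5)


class TestNearIVRule:
    def test_clear_iv_flagged_under_both_presets(self):
        t = _ptable([("iv", "d", 0.5, 0.05, math.exp(2.0), 1.0)])
        assert flag_near_ivs(t, NEAR_IV_STRICT) == ["iv"]
        assert flag_near_ivs(t, NEAR_IV_RELAXED) == ["iv"]

    def test_no_exposure_association_never_flagged(self):
        t = _ptable([("dull", "d", 0.2, 0.2, 1.0, 1.0)])
        for tau in (0.5, 1.1, 1.5):
            assert flag_near_ivs(t, NearIVRule(tau_exposure=tau)) == []

    def test_threshold_arithmetic_between_presets(self):
        t = _ptable([("mid", "d", 0.4, 0.1, math.exp(1.3), 1.1)])
        assert flag_near_ivs(t, NEAR_IV_RELAXED) == ["mid"]
        assert flag_near_ivs(t, NEAR_IV_STRICT) == []

    def test_strong_outcome_association_blocks_flag(self):
        t = _ptable([("conf", "d", 0.5, 0.05, math.exp(2.0), math.exp(0.8))])
        assert flag_near_ivs(t, NEAR_IV_RELAXED) == []

    @given(st.lists(st.tuples(st.floats(0.05, 20), st.floats(0.05, 20)), max_size=20))
    def test_relaxed_rule_flags_superset_of_strict(self, rrs):
        t = _ptable(
            [
                (f"c{i}", "d", 0.2, 0.1, rr_ce, rr_cd)
                for i, (rr_ce, rr_cd) in enumerate(rrs)
            ]
        )
        assert set(flag_near_ivs(t, NEAR_IV_STRICT)) <= set(
            flag_near_ivs(t, NEAR_IV_RELAXED)
        )

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValidationError):
            NearIVRule(tau_exposure=0.0)


class TestConceptSummary:
    def test_counts_conserve_and_unmapped_bucket(self):
        sel = pd.DataFrame(
            {
                "dimension": ["clinical", "clinical", "therapy"],
                "code": ["I21", "I22", "ZZZ"],
            }
        )
        h = CodeHierarchy({"I21": "IX", "I22": "IX"})
        out = concept_summary(sel, h)
        assert out["n"].sum() == 3
        assert out.set_index(["dimension", "chapter"]).loc[("clinical", "IX"), "n"] == 2
        assert out.set_index(["dimension", "chapter"]).loc[("therapy", "unmapped"), "n"] == 1

    def test_empty_selection(self):
        assert len(concept_summary(pd.DataFrame(columns=["dimension", "code"]),
                                   CodeHierarchy({}))) == 0
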