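import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hdps import (
    CohortTable,
    ValidationError,
    bross_bias,
    rank_covariates,
    select_top_k,
    univariate_associations,
)
from hdps.prioritise import CONTINUITY


def brute_force_associations(C, X, D):
    """Independent loop-based 2x2 tabulation with the same continuity rule.

    Used as the oracle against the vectorised implementation.
    """
    out = []
    for j in range(C.shape[1]):
        c = C[:, j]
        n11 = sum(1 for i in range(len(X)) if c[i] == 1 and X[i] == 1)
        n01 = sum(1 for i in range(len(X)) if c[i] == 1 and X[i] == 0)
        n1 = sum(X)
        n0 = len(X) - n1
        pc1, pc0 = n11 / n1, n01 / n0
        if min(n11, n1 - n11, n01, n0 - n01) == 0:
            rr_ce = ((n11 + CONTINUITY) / (n1 + 2 * CONTINUITY)) / (
                (n01 + CONTINUITY) / (n0 + 2 * CONTINUITY)
            )
        else:
            rr_ce = pc1 / pc0
        m1 = sum(c)
        m0 = len(c) - m1
        e1 = sum(1 for i in range(len(D)) if c[i] == 1 and D[i] == 1)
        e0 = sum(D) - e1
        if min(e1, m1 - e1, e0, m0 - e0) == 0:
            rr_cd = ((e1 + CONTINUITY) / (m1 + 2 * CONTINUITY)) / (
                (e0 + CONTINUITY) / (m0 + 2 * CONTINUITY)
            )
        else:
            rr_cd = (e1 / m1) / (e0 / m0)
        rr = max(rr_cd, 1 / rr_cd)
        bias = (pc1 * (rr - 1) + 1) / (pc0 * (rr - 1) + 1)
        out.append((pc1, pc0, rr_ce, rr_cd, bias))
    return out


def random_cohort_and_matrix(rng, n, p):
    X = rng.integers(0, 2, n)
    X[0], X[1] = 0, 1
    D = rng.integers(0, 2, n)
    cohort = CohortTable(
        pd.DataFrame(
            {
                "patient_id": [f"p{i}" for i in range(n)],
                "index_date": "2020-01-01",
                "exposure": X,
                "event": D,
                "followup_time": rng.uniform(10, 300, n),
            }
        ),
        predefined=[],
    )
    C = rng.integers(0, 2, (n, p))
    values = pd.DataFrame(
        C, index=pd.Index(cohort.patient_ids.values, name="patient_id"),
        columns=[f"cov{j}" for j in range(p)],
    )
    return cohort, values, C, X, D


class TestBrossBias:
    def test_direct_arithmetic(self):
        assert bross_bias(0.4, 0.2, 2.0) == pytest.approx(1.4 / 1.2)

    def test_equal_prevalence_gives_unity(self):
        for rr in (0.3, 1.0, 5.0):
            assert bross_bias(0.3, 0.3, rr) == pytest.approx(1.0)

    def test_null_outcome_association_gives_unity(self):
        assert bross_bias(0.7, 0.1, 1.0) == pytest.approx(1.0)

    @given(
        st.floats(0.0, 1.0),
        st.floats(0.0, 1.0),
        st.floats(0.05, 20.0),
    )
    def test_invariance_under_rr_inversion(self, pc1, pc0, rr):
        assert bross_bias(pc1, pc0, rr) == pytest.approx(
            bross_bias(pc1, pc0, 1.0 / rr)
        )

    def test_monotone_in_prevalences_for_harmful_rr(self):
        grid = np.linspace(0.05, 0.95, 10)
        for rr in (1.5, 3.0):
            vals = [bross_bias(p, 0.2, rr) for p in grid]
            assert all(a < b for a, b in zip(vals, vals[1:]))
            vals = [bross_bias(0.5, p, rr) for p in grid]
            assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            bross_bias(1.2, 0.2, 2.0)
        with pytest.raises(ValidationError):
            bross_bias(0.2, 0.2, 0.0)


class TestUnivariateAssociations:
    def test_hand_2x2(self):
        # 20 patients: covariate C splits them 10/10; events 4/10 vs 2/10
        C = np.repeat([1, 0], 10)
        D = np.r_[np.ones(4), np.zeros(6), np.ones(2), np.zeros(8)].astype(int)
        X = np.tile([0, 1], 10)
        cohort = CohortTable(
            pd.DataFrame(
                {
                    "patient_id": [f"p{i}" for i in range(20)],
                    "index_date": "2020-01-01",
                    "exposure": X,
                    "event": D,
                    "followup_time": 100.0,
                }
            ),
            predefined=[],
        )
        values = pd.DataFrame(
            {"c": C}, index=pd.Index(cohort.patient_ids.values, name="patient_id")
        )
        row = univariate_associations(values, cohort).iloc[0]
        assert row["rr_cd"] == pytest.approx((4 / 10) / (2 / 10))

    def test_equal_prevalence_gives_rr_ce_one(self):
        # prevalence exactly 0.2 in each exposure group of 10
        X = np.repeat([1, 0], 10)
        C = np.r_[1, 1, np.zeros(8), 1, 1, np.zeros(8)].astype(int)
        cohort = CohortTable(
            pd.DataFrame(
                {
                    "patient_id": [f"p{i}" for i in range(20)],
                    "index_date": "2020-01-01",
                    "exposure": X,
                    "event": np.tile([0, 1], 10),
                    "followup_time": 100.0,
                }
            ),
            predefined=[],
        )
        values = pd.DataFrame(
            {"c": C}, index=pd.Index(cohort.patient_ids.values, name="patient_id")
        )
        row = univariate_associations(values, cohort).iloc[0]
        assert row["pc1"] == row["pc0"] == 0.2
        assert row["rr_ce"] == pytest.approx(1.0)

    def test_zero_cell_yields_finite_ratios(self):
        n = 12
        X = np.tile([0, 1], 6)
        D = np.zeros(n, int)
        D[X == 1] = 1  # no events in the unexposed; C=0 cell empty for outcome
        C = X.copy()  # covariate equal to exposure: zero cells everywhere
        cohort = CohortTable(
            pd.DataFrame(
                {
                    "patient_id": [f"p{i}" for i in range(n)],
                    "index_date": "2020-01-01",
                    "exposure": X,
                    "event": D,
                    "followup_time": 50.0,
                }
            ),
            predefined=[],
        )
        values = pd.DataFrame(
            {"c": C}, index=pd.Index(cohort.patient_ids.values, name="patient_id")
        )
        table = univariate_associations(values, cohort)
        assert np.isfinite(table[["rr_ce", "rr_cd", "bias_m"]].to_numpy()).all()
        assert (table[["rr_ce", "rr_cd", "bias_m"]] > 0).all().all()

    def test_constant_covariate_excluded(self, rng=np.random.default_rng(1)):
        cohort, values, *_ = random_cohort_and_matrix(rng, 30, 2)
        values["always"] = 1
        table = univariate_associations(values, cohort)
        assert "always" not in set(table["name"])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(10, 50))
            p = int(rng.integers(1, 10))
            cohort, values, C, X, D = random_cohort_and_matrix(rng, n, p)
            table = univariate_associations(values, cohort).set_index("name")
            oracle = brute_force_associations(C, X, D)
            for j, (pc1, pc0, rr_ce, rr_cd, bias) in enumerate(oracle):
                name = f"cov{j}"
                if name not in table.index:  # constant covariate, excluded
                    assert C[:, j].min() == C[:, j].max()
                    continue
                row = table.loc[name]
                assert row["pc1"] == pc1
                assert row["pc0"] == pc0
                assert row["rr_ce"] == pytest.approx(rr_ce, abs=0, rel=1e-12)
                assert row["rr_cd"] == pytest.approx(rr_cd, abs=0, rel=1e-12)
                assert row["bias_m"] == pytest.approx(bias, abs=0, rel=1e-12)


def _table(names, abs_log_bias=None, rr_ce=None):
    df = pd.DataFrame({"name": names})
    df["abs_log_bias"] = abs_log_bias if abs_log_bias is not None else 0.0
    df["rr_ce"] = rr_ce if rr_ce is not None else 1.0
    df["rr_cd"] = 1.0
    return df


class TestRanking:
    def test_bross_ranks_by_descending_score(self):
        ranked = rank_covariates(_table(["a", "b"], abs_log_bias=[0.1, 0.3]))
        assert ranked.set_index("name")["rank"].to_dict() == {"b": 1, "a": 2}

    def test_all_tied_scores_follow_name_order(self):
        ranked = rank_covariates(_table(["c", "a", "b"], abs_log_bias=[0.2] * 3))
        assert ranked["name"].tolist() == ["a", "b", "c"]
        assert sorted(ranked["rank"]) == [1, 2, 3]

    def test_exposure_only_uses_abs_log_rr_ce(self):
        ranked = rank_covariates(
            _table(["x4", "x02", "x1"], rr_ce=[4.0, 0.2, 1.0]), method="exposure_only"
        )
        assert ranked["name"].tolist() == ["x02", "x4", "x1"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValidationError):
            rank_covariates(_table(["a"]), method="magic")

    def test_select_top_k(self):
        ranked = rank_covariates(_table(["a", "b", "c"], abs_log_bias=[3, 2, 1]))
        assert select_top_k(ranked, 0) == []
        assert select_top_k(ranked, 2) == ["a", "b"]
        assert select_top_k(ranked, 500) == ["a", "b", "c"]


def test_confounder_proxies_outrank_noise_codes():
    """Planted confounder proxies get systematically better Bross ranks than
    planted noise codes (Mann-Whitney across replicates, p < 0.01)."""
    from scipy.stats import mannwhitneyu

    from hdps import build_covariate_matrix, generate_study
    from hdps.simulate import small_config

    proxy_means, noise_means = [], []
    for s in range(30):
        cfg = small_config(n_patients=800, codes_per_dimension=10, n_iv_codes=2,
                           n_noise_codes=10, seed=400 + s)
        cohort, dims, truth = generate_study(cfg)
        cov = build_covariate_matrix(dims, cohort)
        ranked = rank_covariates(univariate_associations(cov, cohort))
        by_code = ranked.groupby("code")["rank"].mean()
        proxies = by_code.reindex(truth.codes_with_role("confounder_proxy")).dropna()
        noise = by_code.reindex(truth.codes_with_role("noise")).dropna()
        proxy_means.append(proxies.mean())
        noise_means.append(noise.mean())
    res = mannwhitneyu(proxy_means, noise_means, alternative="less")
    assert res.pvalue < 0.01
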