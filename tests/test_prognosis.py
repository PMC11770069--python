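import numpy as np
import pandas as pd
import pytest

from metastates import (
    RiskModel,
    concordance_index,
    cox_multivariate,
    lasso_stability_select,
    logrank_test,
    risk_score,
    simulate_survival_cohort,
    stepwise_cox,
)
from metastates.prognosis import read_risk_model, write_risk_model


def _survival(times, events, samples=None):
    samples = samples or [f"p{i}" for i in range(len(times))]
    return pd.DataFrame({"sample_id": samples, "time": times, "event": events})


class TestRiskScore:
    def _bulk(self, data):
        return pd.DataFrame(data)

    def test_linear_combination_arithmetic(self):
        bulk = self._bulk({"s1": [2.0, 3.0], "s2": [0.0, 0.0]})
        bulk.index = ["gA", "gB"]
        model = RiskModel(["gA", "gB"], pd.Series({"gA": 0.5, "gB": -1.0}), standardized=False)
        strat = risk_score(model, bulk, standardize=False)
        assert strat.scores["s1"] == pytest.approx(-2.0)
        assert strat.scores["s2"] == pytest.approx(0.0)

    def test_median_rule(self):
        bulk = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]], index=["g"], columns=list("abcd"))
        model = RiskModel(["g"], pd.Series({"g": 1.0}), standardized=False)
        strat = risk_score(model, bulk, standardize=False)
        assert set(strat.groups[strat.groups == "hi"].index) == {"c", "d"}

    def test_beta_scaling_preserves_partition(self):
        rng = np.random.default_rng(0)
        bulk = pd.DataFrame(
            rng.normal(size=(3, 20)), index=["g1", "g2", "g3"],
            columns=[f"p{i}" for i in range(20)],
        )
        betas = pd.Series({"g1": 0.4, "g2": -0.2, "g3": 1.1})
        m1 = RiskModel(list(betas.index), betas, standardized=False)
        m2 = RiskModel(list(betas.index), 3.0 * betas, standardized=False)
        s1 = risk_score(m1, bulk, standardize=False)
        s2 = risk_score(m2, bulk, standardize=False)
        np.testing.assert_allclose(s2.scores, 3.0 * s1.scores)
        pd.testing.assert_series_equal(s1.groups, s2.groups)

    def test_missing_genes_fatal(self):
        bulk = pd.DataFrame([[1.0]], index=["g1"], columns=["s1"])
        model = RiskModel(["g1", "g2"], pd.Series({"g1": 1.0, "g2": 2.0}))
        with pytest.raises(KeyError, match="g2"):
            risk_score(model, bulk)

    def test_round_trip_serialization(self, tmp_path):
        model = RiskModel(["gA", "gB"], pd.Series({"gA": 0.5, "gB": -1.0}))
        write_risk_model(model, tmp_path / "m.tsv")
        loaded = read_risk_model(tmp_path / "m.tsv")
        assert loaded.genes == model.genes
        np.testing.assert_allclose(loaded.betas, model.betas)


def logrank_oracle(times, events, group_a):
    """Observed-minus-expected log-rank statistic computed directly."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    a = np.asarray(group_a, bool)
    o_minus_e, var = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n_a = (at_risk & a).sum()
        d = ((times == t) & (events == 1)).sum()
        d_a = ((times == t) & (events == 1) & a).sum()
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_matches_oracle_on_ten_subject_toy(self):
        times = [2, 3, 3, 5, 7, 8, 9, 10, 12, 14]
        events = [1, 1, 0, 1, 1, 0, 1, 1, 0, 1]
        groups = pd.Series(
            ["hi"] * 5 + ["lo"] * 5, index=[f"p{i}" for i in range(10)]
        )
        sv = _survival(times, events)
        chi2, p = logrank_test(groups, sv)
        expected = logrank_oracle(times, events, np.arange(10) < 5)
        assert chi2 == pytest.approx(expected, rel=1e-6)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        times = np.concatenate([rng.exponential(0.5, 30), rng.exponential(5.0, 30)])
        groups = pd.Series(["hi"] * 30 + ["lo"] * 30, index=[f"p{i}" for i in range(60)])
        sv = _survival(times, np.ones(60, dtype=int))
        chi2, p = logrank_test(groups, sv)
        assert p < 0.001

    def test_empty_group_fatal(self):
        sv = _survival([1, 2], [1, 1])
        groups = pd.Series(["hi", "hi"], index=sv["sample_id"])
        with pytest.raises(ValueError):
            logrank_test(groups, sv)


def c_index_oracle(times, events, scores):
    """O(n^2) pair enumeration of Harrell's C with 0.5 for score ties."""
    num, den = 0.0, 0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] == times[j] or times[i] > times[j]:
                continue
            if not events[i]:
                continue  # earlier subject censored: not comparable
            den += 1
            if scores[i] > scores[j]:
                num += 1.0
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


class TestConcordance:
    def test_perfect_ordering_gives_one(self):
        n = 15
        scores = pd.Series(np.arange(n, dtype=float), index=[f"p{i}" for i in range(n)])
        times = n - np.arange(n, dtype=float)  # higher risk fails first
        sv = _survival(times, np.ones(n, dtype=int))
        assert concordance_index(scores, sv) == pytest.approx(1.0)

    def test_matches_brute_force_with_censoring(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = 20
            times = rng.exponential(1.0, n)  # continuous: no tied times
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            scores = pd.Series(
                rng.choice([0.1, 0.5, 0.9], n), index=[f"p{i}" for i in range(n)]
            )
            sv = _survival(times, events)
            assert concordance_index(scores, sv) == pytest.approx(
                c_index_oracle(times, events, scores.to_numpy())
            )

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(4)
        n = 30
        times = rng.exponential(1.0, n)
        events = rng.integers(0, 2, n)
        events[:5] = 1
        scores = pd.Series(rng.normal(size=n), index=[f"p{i}" for i in range(n)])
        sv = _survival(times, events)
        assert concordance_index(scores, sv) == pytest.approx(
            1.0 - concordance_index(-scores, sv)
        )

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(5)
        n = 400
        times = rng.exponential(1.0, n)
        scores = pd.Series(rng.normal(size=n), index=[f"p{i}" for i in range(n)])
        sv = _survival(times, np.ones(n, dtype=int))
        assert concordance_index(scores, sv) == pytest.approx(0.5, abs=0.06)


class TestStepwiseCox:
    def test_single_strong_gene_kept_with_correct_sign(self):
        bulk, sv, _ = simulate_survival_cohort(200, 5, {"B0000": 1.0}, seed=1)
        model = stepwise_cox(bulk, sv, list(bulk.index))
        assert "B0000" in model.genes
        assert model.betas["B0000"] > 0

    def test_collinear_copy_not_duplicated(self):
        bulk, sv, _ = simulate_survival_cohort(150, 4, {"B0000": 1.0}, seed=2)
        bulk.loc["copy"] = bulk.loc["B0000"]
        model = stepwise_cox(bulk, sv, list(bulk.index))
        assert not ({"B0000", "copy"} <= set(model.genes))

    def test_pure_noise_yields_sparse_model(self):
        bulk, sv, _ = simulate_survival_cohort(300, 8, {}, seed=3)
        model = stepwise_cox(bulk, sv, list(bulk.index))
        assert len(model.genes) <= 2


class TestStabilitySelection:
    def test_single_iteration_reduces_to_one_lasso_fit(self):
        bulk, sv, _ = simulate_survival_cohort(120, 20, {"B0000": 1.2}, seed=4)
        selected, freq = lasso_stability_select(
            bulk, sv, list(bulk.index), n_iter=1, min_freq=1, seed=4, cv_folds=4
        )
        assert freq.max() == 1
        assert "B0000" in selected

    def test_strong_gene_always_selected_nulls_rarely(self):
        bulk, sv, _ = simulate_survival_cohort(300, 51, {"B0000": 1.0}, seed=5)
        selected, freq = lasso_stability_select(
            bulk, sv, list(bulk.index), n_iter=20, min_freq=18, seed=5, cv_folds=5
        )
        assert freq["B0000"] >= 18
        assert (freq.drop("B0000") < 18).all()


class TestCoxMultivariate:
    def test_independent_covariate_leaves_hr_close_to_univariate(self):
        rng = np.random.default_rng(6)
        n = 250
        score = rng.normal(size=n)
        cov = rng.normal(size=n)
        haz = 0.1 * np.exp(0.8 * score)
        times = rng.exponential(1 / haz)
        sv = _survival(times, np.ones(n, dtype=int))
        s = pd.Series(score, index=sv["sample_id"])
        covs = pd.DataFrame({"age": cov}, index=sv["sample_id"])
        tab = cox_multivariate(s, covs, sv)
        assert tab.loc["risk_score", "HR"] == pytest.approx(np.exp(0.8), rel=0.2)
        assert tab.loc["risk_score", "p"] < 1e-6

    def test_exact_copy_covariate_flagged(self):
        rng = np.random.default_rng(7)
        n = 60
        score = rng.normal(size=n)
        times = rng.exponential(1.0, n)
        sv = _survival(times, np.ones(n, dtype=int))
        s = pd.Series(score, index=sv["sample_id"])
        covs = pd.DataFrame({"dup": score}, index=sv["sample_id"])
        tab = cox_multivariate(s, covs, sv)
        assert (tab["flag"] == "collinearity").all()

    def test_null_model_ci_coverage(self):
        # 95% CIs should cover HR=1 at roughly the nominal rate
        rng = np.random.default_rng(8)
        n, reps, covered = 120, 200, 0
        for _ in range(reps):
            score = rng.normal(size=n)
            times = rng.exponential(1.0, n)
            sv = _survival(times, np.ones(n, dtype=int))
            s = pd.Series(score, index=sv["sample_id"])
            covs = pd.DataFrame({"x": rng.normal(size=n)}, index=sv["sample_id"])
            tab = cox_multivariate(s, covs, sv)
            if tab.loc["risk_score", "HR_lower95"] <= 1.0 <= tab.loc["risk_score", "HR_upper95"]:
                covered += 1
        assert covered / reps == pytest.approx(0.95, abs=0.05)
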