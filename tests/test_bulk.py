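import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, rankdata

from metastates import (
    assoc_categorical,
    assoc_continuous,
    cox_univariate,
    liptak_combine,
    signed_mlog10p,
    ssgsea,
)


def ssgsea_oracle(expr: pd.Series, gene_set, alpha=0.25) -> float:
    """Literal running-sum evaluation, kept independent of the library
    implementation: walk genes in decreasing expression, step up by
    rank^alpha (normalized) for set members, step down uniformly for the
    rest, and integrate the running sum."""
    genes = list(expr.index)
    ranks = dict(zip(genes, rankdata(expr.to_numpy())))
    ordered = sorted(genes, key=lambda g: (-expr[g], g))
    in_set = set(gene_set)
    total_w = sum(ranks[g] ** alpha for g in ordered if g in in_set)
    n_out = len(genes) - len(in_set & set(genes))
    running, es = 0.0, 0.0
    for g in ordered:
        if g in in_set:
            running += ranks[g] ** alpha / total_w
        else:
            running -= 1.0 / n_out
        es += running
    return es


class TestSsgsea:
    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n_genes = rng.integers(6, 50)
            n_samples = rng.integers(1, 5)
            expr = pd.DataFrame(
                rng.normal(size=(n_genes, n_samples)) * 10,
                index=[f"g{i}" for i in range(n_genes)],
                columns=[f"s{j}" for j in range(n_samples)],
            )
            set_size = int(rng.integers(1, max(2, n_genes // 2)))
            gene_set = list(rng.choice(expr.index, size=set_size, replace=False))
            scores = ssgsea(expr, {"S": gene_set}, normalize=False)
            for s in expr.columns:
                assert scores.loc[s, "S"] == pytest.approx(
                    ssgsea_oracle(expr[s], gene_set), abs=1e-9
                )

    def test_six_gene_toy_against_oracle(self):
        expr = pd.Series([6.0, 5.0, 4.0, 3.0, 2.0, 1.0], index=list("abcdef"))
        df = expr.to_frame("s1")
        score = ssgsea(df, {"S": ["a", "b"]}, normalize=False).loc["s1", "S"]
        assert score == pytest.approx(ssgsea_oracle(expr, ["a", "b"]), abs=1e-12)

    def test_rank_monotonicity(self):
        # the set gene sits on top in sample A and at the bottom in B
        df = pd.DataFrame(
            {"A": [10.0, 5, 4, 3, 2, 1], "B": [0.5, 5, 4, 3, 2, 1]},
            index=[f"g{i}" for i in range(6)],
        )
        scores = ssgsea(df, {"S": ["g0"]}, normalize=False)
        assert scores.loc["A", "S"] > scores.loc["B", "S"]

    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(1)
        col = rng.random(30)
        df = pd.DataFrame({"A": col, "B": col}, index=[f"g{i}" for i in range(30)])
        scores = ssgsea(df, {"S": ["g1", "g5", "g9"]})
        assert scores.loc["A", "S"] == pytest.approx(scores.loc["B", "S"])

    def test_empty_intersection_fatal(self):
        df = pd.DataFrame({"A": [1.0, 2.0]}, index=["g0", "g1"])
        with pytest.raises(ValueError, match="no genes"):
            ssgsea(df, {"S": ["zz"]})


def _survival(times, events, samples=None):
    samples = samples or [f"p{i}" for i in range(len(times))]
    return pd.DataFrame({"sample_id": samples, "time": times, "event": events})


class TestCoxUnivariate:
    def test_risk_ordering_gives_positive_z(self):
        # higher score -> strictly earlier event, no censoring
        rng = np.random.default_rng(0)
        n = 40
        score = pd.Series(rng.normal(size=n), index=[f"p{i}" for i in range(n)])
        times = (-score).rank().to_numpy()  # highest score fails first
        sv = _survival(times, np.ones(n, dtype=int))
        res = cox_univariate(score, sv)
        assert res.statistic > 0
        assert res.p_value < 0.01
        assert res.signed_mlog10p > 2

    def test_null_scores_give_uniform_p(self):
        # repeated independent null scores: p values approximately uniform
        rng = np.random.default_rng(1)
        n = 60
        times = rng.exponential(1.0, n)
        events = np.ones(n, dtype=int)
        sv = _survival(times, events)
        ps = []
        for _ in range(200):
            score = pd.Series(rng.normal(size=n), index=sv["sample_id"])
            ps.append(cox_univariate(score, sv).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_constant_score_fatal(self):
        sv = _survival([1, 2, 3, 4], [1, 1, 1, 0])
        score = pd.Series(1.0, index=sv["sample_id"])
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(score, sv)


class TestRegressionAssociations:
    @staticmethod
    def _logistic_irls_z(x, y):
        """Independent IRLS Newton fit of logit(y) ~ 1 + x; Wald z for x."""
        X = np.column_stack([np.ones_like(x), x])
        beta = np.zeros(2)
        for _ in range(100):
            eta = X @ beta
            p = 1 / (1 + np.exp(-eta))
            W = p * (1 - p)
            grad = X.T @ (y - p)
            H = X.T @ (X * W[:, None])
            step = np.linalg.solve(H, grad)
            beta = beta + step
            if np.abs(step).max() < 1e-12:
                break
        se = np.sqrt(np.linalg.inv(H)[1, 1])
        return beta[1] / se

    def test_logistic_matches_irls_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = (rng.uniform(size=80) < 1 / (1 + np.exp(-(0.8 * x)))).astype(float)
        score = pd.Series(x, index=[f"p{i}" for i in range(80)])
        labels = pd.Series(y, index=score.index, name="grp")
        res = assoc_categorical(score, labels)
        assert res.statistic == pytest.approx(self._logistic_irls_z(x, y), rel=1e-6)

    def test_constant_score_statistic_near_zero(self):
        rng = np.random.default_rng(4)
        idx = [f"p{i}" for i in range(40)]
        score = pd.Series(rng.normal(size=40), index=idx)
        labels = pd.Series(rng.integers(0, 2, 40), index=idx, name="grp")
        values = pd.Series(rng.normal(size=40), index=idx, name="cont")
        # independent variable -> small statistics on average
        assert abs(assoc_continuous(score, values).statistic) < 4

    def test_perfect_linear_fit_flagged(self):
        idx = [f"p{i}" for i in range(10)]
        score = pd.Series(np.arange(10, dtype=float), index=idx)
        values = pd.Series(2.0 * score, index=idx, name="v")
        res = assoc_continuous(score, values)
        assert res.p_value <= np.finfo(float).tiny * 10 or res.flag is not None
        assert res.statistic > 1e3


class TestLiptak:
    def test_single_cohort_identity(self):
        assert liptak_combine([1.3], [50]) == pytest.approx(1.3)

    def test_equal_n_closed_form(self):
        assert liptak_combine([1.96, 1.96], [100, 100]) == pytest.approx(
            1.96 * np.sqrt(2), abs=1e-4
        )
        assert liptak_combine([1.96, 1.96], [100, 100]) == pytest.approx(2.7719, abs=1e-3)

    def test_antisymmetry(self):
        assert liptak_combine([2.0, -2.0], [80, 80]) == pytest.approx(0.0)

    def test_equal_weights_reduce_to_stouffer(self):
        z = [0.5, 1.5, -0.7]
        stouffer = sum(z) / np.sqrt(3)
        assert liptak_combine(z, [10, 10, 10]) == pytest.approx(stouffer)
        assert liptak_combine(z, [7, 7, 7], weights="equal") == pytest.approx(stouffer)

    def test_inverse_sqrt_weights_downweight_large_cohorts(self):
        # the larger cohort contributes less than under sqrt(n) weighting
        z_small_big = liptak_combine([3.0, 0.0], [10, 1000])
        z_conventional = liptak_combine([3.0, 0.0], [10, 1000], weights="sqrt_n")
        assert z_small_big > z_conventional

    def test_empty_fatal(self):
        with pytest.raises(ValueError):
            liptak_combine([], [])


class TestSignedMlog10p:
    @pytest.mark.parametrize(
        "stat,p,expected",
        [(2.5, 0.01, 2.0), (-1.1, 0.001, -3.0), (0.7, 1.0, 0.0)],
    )
    def test_values(self, stat, p, expected):
        assert signed_mlog10p(stat, p) == pytest.approx(expected)

    def test_invalid_p_fatal(self):
        with pytest.raises(ValueError):
            signed_mlog10p(1.0, 0.0)
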