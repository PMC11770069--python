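"""Ecosystem-derived prognostic risk model.

The gene-level model is built in two stages: (i) stability selection —
repeated leave-out-10% subsampling, each round fitting an L1-penalized
Cox model with an internally cross-validated penalty, keeping genes
selected in at least ``min_freq`` rounds; (ii) bidirectional stepwise
Cox regression by AIC over the stable genes. The resulting risk score is
score_s = sum_i Exp_is * beta_i, and samples are split at the median
(strictly above = high risk). The split is evaluated with the log-rank
test, multivariate Cox adjustment and Harrell's concordance index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_concordance
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "RiskModel",
    "RiskStratification",
    "lasso_stability_select",
    "stepwise_cox",
    "risk_score",
    "logrank_test",
    "cox_multivariate",
    "concordance_index",
    "read_risk_model",
    "write_risk_model",
]


@dataclass
class RiskModel:
    """Ordered gene list with Cox coefficients (log-hazard units)."""

    genes: list[str]
    betas: pd.Series
    selection_frequencies: pd.Series | None = None
    n_iterations: int | None = None
    standardized: bool = True

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.betas):
            raise ValueError("genes and betas differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in risk model")


@dataclass
class RiskStratification:
    scores: pd.Series  # sample -> risk score
    groups: pd.Series  # sample -> "hi" / "lo"; strictly above median = hi
    median: float


def _as_matrix(bulk) -> pd.DataFrame:
    """Accept an ExpressionMatrix or a genes x samples DataFrame."""
    if hasattr(bulk, "to_frame") and not isinstance(bulk, pd.DataFrame):
        return bulk.to_frame()
    return bulk


def _design(bulk, genes, survival, standardize=True):
    df = _as_matrix(bulk)
    missing = [g for g in genes if g not in df.index]
    if missing:
        raise KeyError(f"genes absent from bulk matrix: {missing}")
    sv = survival.set_index("sample_id")
    X = df.loc[genes, sv.index].T.astype(float)
    if standardize:
        sd = X.std(ddof=0).replace(0, 1.0)
        X = (X - X.mean()) / sd
    return X, sv


def _breslow_pll(X: np.ndarray, beta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Breslow partial log-likelihood for held-out penalty selection."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # descending time
    eta_o, t_o, e_o = eta[order], time[order], event[order]
    log_cum = np.logaddexp.accumulate(eta_o)
    # risk set of subject i = all with time >= t_i; with descending sort,
    # tied times need the full tie block included
    pll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j < n and t_o[j] == t_o[i]:
            j += 1
        denom = log_cum[j - 1]
        for k in range(i, j):
            if e_o[k]:
                pll += eta_o[k] - denom
        i = j
    return float(pll)


def _cv_coxnet(
    X, time, event, rng,
    n_folds=10, n_alphas=30, alpha_min_ratio=0.01, penalty_rule="1se",
):
    """Fit an L1 Cox path and choose the penalty by cross-validated
    held-out partial log-likelihood (deviance).

    ``penalty_rule="min"`` takes the deviance-minimizing penalty;
    ``"1se"`` (default) the strongest penalty whose mean held-out
    log-likelihood is within one standard error of the best, favouring
    parsimonious supports.
    """
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    base = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio,
        fit_baseline_model=False,
    )
    base.fit(X, y)
    alphas = np.asarray(base.alphas_)  # descending
    n = len(time)
    folds = np.resize(np.arange(n_folds), n)
    rng.shuffle(folds)
    pll = np.full((n_folds, len(alphas)), np.nan)
    for f in range(n_folds):
        tr, te = folds != f, folds == f
        if event[te].sum() == 0 or event[tr].sum() == 0:
            continue
        m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        try:
            m.fit(X[tr], Surv.from_arrays(event=event[tr].astype(bool), time=time[tr]))
        except Exception:
            continue
        fitted = {a: i for i, a in enumerate(np.asarray(m.alphas_))}
        for ai, a in enumerate(alphas):
            if a in fitted:
                beta = m.coef_[:, fitted[a]]
                pll[f, ai] = _breslow_pll(X[te], beta, time[te], event[te])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(pll, axis=0)
        folds_ok = np.sum(~np.isnan(pll), axis=0)
        se = np.nanstd(pll, axis=0, ddof=1) / np.sqrt(np.maximum(folds_ok, 1))
    if np.isnan(mean).all():
        best = len(alphas) - 1
    else:
        best = int(np.nanargmax(mean))
        if penalty_rule == "1se":
            thr = mean[best] - se[best]
            within = [i for i in range(len(alphas)) if not np.isnan(mean[i]) and mean[i] >= thr]
            best = min(within)  # alphas descend: smallest index = strongest penalty
        elif penalty_rule != "min":
            raise ValueError(f"unknown penalty rule {penalty_rule!r}")
    coef = base.coef_[:, best]
    return coef, float(alphas[best])


def lasso_stability_select(
    bulk,
    survival: pd.DataFrame,
    candidate_genes: Sequence[str],
    n_iter: int = 1000,
    holdout_frac: float = 0.10,
    min_freq: int = 900,
    seed: int = 0,
    cv_folds: int = 10,
    n_alphas: int = 30,
    penalty_rule: str = "1se",
) -> tuple[list[str], pd.Series]:
    """Stability selection by repeated leave-out-10% LASSO-Cox.

    Each iteration drops a seeded random ``holdout_frac`` of samples, fits
    an L1-penalized Cox model on the remainder with the penalty chosen by
    internal cross-validation (1-SE rule by default; ``penalty_rule="min"``
    for the deviance minimizer), and records the nonzero-coefficient
    genes. Returns (genes selected in >= ``min_freq`` iterations, full
    frequency table).
    """
    genes = [g for g in candidate_genes if g in _as_matrix(bulk).index]
    if not genes:
        raise ValueError("no candidate genes present in the bulk matrix")
    X_df, sv = _design(bulk, genes, survival, standardize=True)
    time = sv["time"].to_numpy(dtype=float)
    event = sv["event"].to_numpy(dtype=float)
    if event.sum() < 20:
        warnings.warn("fewer than 20 events; selection may be unstable", stacklevel=2)
    X = X_df.to_numpy()
    n = X.shape[0]
    n_drop = max(1, int(round(holdout_frac * n)))
    rng = np.random.default_rng(seed)
    freq = pd.Series(0, index=pd.Index(genes), dtype=int)
    for _ in range(n_iter):
        drop = rng.choice(n, size=n_drop, replace=False)
        keep = np.setdiff1d(np.arange(n), drop)
        coef, _alpha = _cv_coxnet(
            X[keep], time[keep], event[keep], rng,
            n_folds=cv_folds, n_alphas=n_alphas, penalty_rule=penalty_rule,
        )
        freq[np.abs(coef) > 0] += 1
    selected = freq.index[freq >= min_freq].tolist()
    if not selected:
        warnings.warn("no gene reached the selection-frequency cutoff", stacklevel=2)
    return selected, freq


def _fit_cox(frame: pd.DataFrame, covariates: Sequence[str]):
    cph = CoxPHFitter(penalizer=0.0)
    cph.fit(frame[["time", "event", *covariates]], duration_col="time", event_col="event")
    return cph


def stepwise_cox(
    bulk,
    survival: pd.DataFrame,
    genes: Sequence[str],
    standardize: bool = True,
) -> RiskModel:
    """Bidirectional stepwise Cox regression minimizing AIC.

    Starts from the empty model; at each step considers adding any
    excluded gene or dropping any included one, taking the move with the
    largest AIC improvement until none improves. Genes whose fit fails to
    converge are dropped with a warning.
    """
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise ValueError("no genes supplied")
    X, sv = _design(bulk, genes, survival, standardize=standardize)
    if sv["event"].sum() < len(genes):
        warnings.warn("fewer events than candidate genes", stacklevel=2)
    frame = pd.concat(
        [sv[["time", "event"]].reset_index(drop=True), X.reset_index(drop=True)], axis=1
    )

    def aic_of(cols):
        if not cols:
            # null model: AIC = -2 * log partial likelihood with no terms
            t = frame["time"].to_numpy()
            e = frame["event"].to_numpy()
            return -2.0 * _breslow_pll(np.zeros((len(t), 1)), np.zeros(1), t, e)
        cph = _fit_cox(frame, cols)
        return float(cph.AIC_partial_), cph

    current: list[str] = []
    current_aic = aic_of([])
    bad: set[str] = set()
    while True:
        moves = []
        for g in genes:
            if g in current or g in bad:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    aic, _ = aic_of(current + [g])
                moves.append((aic, "add", g))
            except Exception:
                warnings.warn(f"dropping {g}: Cox fit failed", stacklevel=2)
                bad.add(g)
        for g in current:
            cols = [c for c in current if c != g]
            if cols:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    aic, _ = aic_of(cols)
            else:
                aic = aic_of([])
            moves.append((aic, "drop", g))
        if not moves:
            break
        best_aic, action, g = min(moves, key=lambda m: m[0])
        if best_aic >= current_aic - 1e-9:
            break
        current_aic = best_aic
        if action == "add":
            current.append(g)
        else:
            current.remove(g)
    if current:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, cph = aic_of(current)
        betas = cph.params_.loc[current]
    else:
        betas = pd.Series(dtype=float)
    return RiskModel(
        genes=list(current),
        betas=betas,
        standardized=standardize,
    )


def risk_score(model: RiskModel, bulk, standardize: bool | None = None) -> RiskStratification:
    """Apply the linear risk model: score_s = sum_i Exp_is * beta_i with a
    strictly-above-median high-risk split. Missing genes are an error."""
    df = _as_matrix(bulk)
    missing = [g for g in model.genes if g not in df.index]
    if missing:
        raise KeyError(f"model genes missing from bulk matrix: {missing}")
    X = df.loc[model.genes].T.astype(float)
    if standardize is None:
        standardize = model.standardized
    if standardize and len(model.genes):
        sd = X.std(ddof=0).replace(0, 1.0)
        X = (X - X.mean()) / sd
    if model.genes:
        scores = X @ model.betas.loc[model.genes]
    else:
        scores = pd.Series(0.0, index=X.index)
    med = float(scores.median())
    if scores.nunique() <= 1 and len(model.genes):
        raise ValueError("constant risk scores; cannot form groups")
    groups = pd.Series(np.where(scores > med, "hi", "lo"), index=scores.index)
    return RiskStratification(scores=scores, groups=groups, median=med)


def logrank_test(groups: pd.Series, survival: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p value)."""
    sv = survival.set_index("sample_id").loc[groups.index]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {levels}")
    a = groups == levels[0]
    if a.all() or (~a).all():
        raise ValueError("one group is empty")
    res = _ll_logrank(
        sv.loc[a.values, "time"], sv.loc[~a.values, "time"],
        event_observed_A=sv.loc[a.values, "event"],
        event_observed_B=sv.loc[~a.values, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def cox_multivariate(
    score: pd.Series,
    covariates: pd.DataFrame,
    survival: pd.DataFrame,
    score_name: str = "risk_score",
) -> pd.DataFrame:
    """Joint Cox fit of the score plus clinical covariates.

    Returns a table with hazard ratios, 95% CIs, z and p per term;
    categorical covariates are dummy-coded. Collinear terms are flagged
    in the ``flag`` column rather than silently dropped.
    """
    sv = survival.set_index("sample_id").loc[score.index]
    cov = covariates.loc[score.index].copy()
    for c in cov.columns:
        if cov[c].std(ddof=0) == 0 if np.issubdtype(cov[c].dtype, np.number) else cov[c].nunique() <= 1:
            raise ValueError(f"constant covariate {c!r}")
    cov = pd.get_dummies(cov, drop_first=True, dtype=float)
    frame = pd.concat(
        [sv[["time", "event"]], pd.Series(score, name=score_name), cov], axis=1
    )
    design = frame.drop(columns=["time", "event"]).to_numpy(dtype=float)
    corr = np.corrcoef(design, rowvar=False)
    collinear = np.any(np.abs(corr - np.eye(corr.shape[0])) > 0.999)
    cph = CoxPHFitter(penalizer=1e-6 if collinear else 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(frame, duration_col="time", event_col="event")
    summ = cph.summary
    out = pd.DataFrame(
        {
            "HR": np.exp(summ["coef"]),
            "HR_lower95": np.exp(summ["coef lower 95%"]),
            "HR_upper95": np.exp(summ["coef upper 95%"]),
            "z": summ["z"],
            "p": summ["p"],
        }
    )
    out["flag"] = "collinearity" if collinear else None
    return out


def concordance_index(scores: pd.Series, survival: pd.DataFrame) -> float:
    """Harrell's C for a risk score (higher score = higher risk, so a
    perfectly ordering score gives 1.0); ties in score get 0.5 credit."""
    sv = survival.set_index("sample_id").loc[scores.index]
    if int(sv["event"].sum()) == 0:
        raise ValueError("no events: no comparable pairs")
    return float(
        _ll_concordance(sv["time"], -scores.to_numpy(dtype=float), sv["event"])
    )


def write_risk_model(model: RiskModel, path) -> None:
    pd.DataFrame({"gene": model.genes, "beta": model.betas.loc[model.genes].to_numpy()}).to_csv(
        path, sep="\t", index=False
    )


def read_risk_model(path) -> RiskModel:
    df = pd.read_csv(path, sep="\t")
    return RiskModel(
        genes=df["gene"].tolist(),
        betas=pd.Series(df["beta"].to_numpy(), index=df["gene"]),
    )
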