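"""Bulk quantification of cell states and clinical associations.

Cell-state signatures are quantified in bulk expression profiles with
single-sample GSEA (rank-weighted running-sum enrichment, exponent
alpha = 0.25, integrated running-sum difference, cohort-wide max - min
normalization). Scores are then associated with overall survival
(univariate Cox), categorical variables (logistic regression) and
continuous variables (linear regression); evidence across cohorts is
combined with Liptak's weighted-z method using weights 1/sqrt(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "AssociationResult",
    "ssgsea",
    "cox_univariate",
    "assoc_categorical",
    "assoc_continuous",
    "liptak_combine",
    "signed_mlog10p",
]


@dataclass
class AssociationResult:
    signature: str
    variable: str
    statistic_type: str  # "z (Cox)", "z (logistic)", "t (linear)"
    statistic: float
    p_value: float
    n: int
    signed_mlog10p: float
    flag: str | None = None


def signed_mlog10p(statistic: float, p: float) -> float:
    """sign(statistic) * (-log10 p); p = 1 maps to 0."""
    if not 0 < p <= 1:
        raise ValueError(f"p value {p} outside (0, 1]")
    return float(np.sign(statistic) * (-np.log10(p)))


def _sample_es(expr: np.ndarray, genes: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Integrated running-sum enrichment for one sample.

    Genes are walked in descending expression (stable tie-break by gene
    symbol); in-set genes step up by rank^alpha (ascending average ranks,
    so the top gene carries rank N) normalized by the total in-set weight,
    out-of-set genes step down uniformly. The score is the sum of the
    running sum over all positions.
    """
    n = expr.size
    ranks = rankdata(expr)  # ascending, average ties -> top gene ~ N
    order = np.lexsort((genes, -expr))
    w = np.abs(ranks) ** alpha
    in_ordered = in_set[order]
    n_in = int(in_set.sum())
    if n_in == 0 or n_in == n:
        raise ValueError("gene set is empty or covers every gene after intersection")
    steps = np.where(in_ordered, w[order], 0.0)
    steps_sum = steps.sum()
    inc = steps / steps_sum
    dec = np.where(~in_ordered, 1.0 / (n - n_in), 0.0)
    running = np.cumsum(inc - dec)
    return float(running.sum())


def ssgsea(
    bulk: ExpressionMatrix | pd.DataFrame,
    signatures: GeneSetCollection | Mapping[str, Sequence[str]],
    alpha: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """ssGSEA enrichment scores, samples x signatures.

    ``normalize=True`` divides every score by (max - min) over the whole
    result matrix, making scores comparable within the cohort.
    """
    df = bulk.to_frame() if isinstance(bulk, ExpressionMatrix) else bulk
    if df.shape[0] < 2:
        raise ValueError("need at least two genes")
    genes = df.index.to_numpy(dtype=object)
    sig_items = signatures.items() if hasattr(signatures, "items") else signatures
    masks = {}
    for name, gene_list in dict(sig_items).items():
        mask = np.isin(genes, list(gene_list))
        if not mask.any():
            raise ValueError(f"signature {name!r} shares no genes with the matrix")
        masks[name] = mask
    X = df.to_numpy(dtype=float)
    out = pd.DataFrame(index=df.columns, columns=list(masks), dtype=float)
    for j, sample in enumerate(df.columns):
        expr = X[:, j]
        for name, mask in masks.items():
            out.loc[sample, name] = _sample_es(expr, genes, mask, alpha)
    if normalize:
        span = float(out.max().max() - out.min().min())
        if span > 0:
            out = out / span
    return out


def _prepare_survival(survival: pd.DataFrame, index: pd.Index) -> pd.DataFrame:
    sv = survival.set_index("sample_id").loc[index]
    return sv


def cox_univariate(
    score: pd.Series,
    survival: pd.DataFrame,
    signature: str = "signature",
) -> AssociationResult:
    """Univariate Cox PH of overall survival on a z-scored signature score.

    Positive z means higher score, higher hazard (shorter survival). Ties
    are handled with Efron's method (lifelines default).
    """
    sv = _prepare_survival(survival, score.index)
    n_events = int(sv["event"].sum())
    if n_events < 2:
        raise ValueError("need at least two events")
    sd = float(score.std(ddof=0))
    if sd == 0:
        raise ValueError("constant score has no survival association")
    z = (score - score.mean()) / sd
    frame = pd.DataFrame({"time": sv["time"], "event": sv["event"], "score": z})
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except Exception as exc:  # non-convergence -> flagged NA result
        return AssociationResult(
            signature, "OS", "z (Cox)", float("nan"), float("nan"),
            len(frame), float("nan"), flag=f"non-convergence: {exc}",
        )
    stat = float(cph.summary.loc["score", "z"])
    p = float(cph.summary.loc["score", "p"])
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return AssociationResult(
        signature, "OS", "z (Cox)", stat, p, len(frame), signed_mlog10p(stat, p)
    )


def assoc_categorical(
    score: pd.Series, labels: pd.Series, signature: str = "signature"
) -> AssociationResult | list[AssociationResult]:
    """Logistic regression of a categorical variable on the score.

    Binary labels give one result (Wald z for the score term); multi-level
    labels are handled one-vs-rest and give one result per level.
    """
    labels = labels.loc[score.index]
    levels = sorted(pd.unique(labels.dropna()))
    if len(levels) < 2:
        raise ValueError("categorical variable has fewer than two levels")
    if len(levels) > 2:
        return [
            _logistic_one(score, (labels == lv).astype(float), f"{labels.name or 'var'}={lv}", signature)
            for lv in levels
        ]
    y = (labels == levels[-1]).astype(float)
    return _logistic_one(score, y, str(labels.name or "var"), signature)


def _logistic_one(score, y, variable, signature) -> AssociationResult:
    X = sm.add_constant(score.to_numpy(dtype=float))
    flag = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y.to_numpy(), X).fit(disp=0, maxiter=100)
            stat = float(fit.tvalues[1])
            p = float(fit.pvalues[1])
        except Exception as exc:
            return AssociationResult(
                signature, variable, "z (logistic)", float("nan"), float("nan"),
                len(y), float("nan"), flag=f"separation/non-convergence: {exc}",
            )
    if not np.isfinite(stat) or abs(stat) > 1e6:
        flag = "possible perfect separation"
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return AssociationResult(
        signature, variable, "z (logistic)", stat, p, len(y),
        signed_mlog10p(stat, p), flag=flag,
    )


def assoc_continuous(
    score: pd.Series, values: pd.Series, signature: str = "signature"
) -> AssociationResult:
    """Linear model of a continuous variable on the score (t statistic)."""
    values = values.loc[score.index]
    X = sm.add_constant(score.to_numpy(dtype=float))
    fit = sm.OLS(values.to_numpy(dtype=float), X).fit()
    stat = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    flag = None
    if not np.isfinite(stat) or abs(stat) > 1e8:
        stat = float(np.sign(fit.params[1]) * 1e8)  # cap near-perfect fits
        flag = "perfect fit: t capped"
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return AssociationResult(
        signature, str(values.name or "var"), "t (linear)", stat, p, len(values),
        signed_mlog10p(stat, p), flag=flag,
    )


def liptak_combine(
    z_values: Sequence[float],
    n_values: Sequence[float],
    weights: str = "inv_sqrt_n",
) -> float:
    """Weighted z combination: Z = sum(w_i z_i) / sqrt(sum(w_i^2)).

    ``weights="inv_sqrt_n"`` uses w_i = 1/sqrt(n_i) (down-weighting larger
    cohorts, as applied in this workflow); ``"sqrt_n"`` gives the
    conventional alternative. Equal weights reduce to Stouffer's method.
    """
    z = np.asarray(z_values, dtype=float)
    n = np.asarray(n_values, dtype=float)
    if z.size == 0 or z.size != n.size:
        raise ValueError("z and n must be equal-length and non-empty")
    if (n <= 0).any():
        raise ValueError("cohort sizes must be positive")
    if weights == "inv_sqrt_n":
        w = 1.0 / np.sqrt(n)
    elif weights == "sqrt_n":
        w = np.sqrt(n)
    elif weights == "equal":
        w = np.ones_like(n)
    else:
        raise ValueError(f"unknown weighting {weights!r}")
    return float((w * z).sum() / np.sqrt((w**2).sum()))
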