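"""Single-cell signature scoring and compartment-relative abundances.

Cells are scored against meta-program signatures with a bin-matched
control-gene scheme: genes are binned by average expression, and each
signature gene contributes the difference between its expression and the
mean of seeded random control genes drawn from its bin. Each cell is
assigned to its highest-scoring state, and per-sample state abundances
are computed relative to the state's own cell-type compartment.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionMatrix

__all__ = [
    "log_normalize",
    "module_score",
    "score_states",
    "assign_states",
    "state_abundance",
]


def log_normalize(m: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Counts per ``target_sum`` per cell, log1p-transformed."""
    if m.layer != "counts":
        raise ValueError("log_normalize expects the counts layer")
    X = m.dense().astype(float)
    tot = X.sum(axis=0)
    tot[tot == 0] = 1.0
    X = np.log1p(X / tot * target_sum)
    return ExpressionMatrix(list(m.genes), list(m.columns), X, layer="normalized")


def module_score(
    m: ExpressionMatrix,
    signature: Sequence[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Bin-matched control module score per cell.

    Genes are split into ``n_bins`` equal-frequency bins on their average
    expression across cells. For each signature gene, ``n_ctrl`` control
    genes are drawn (seeded, with replacement) from the non-signature
    genes of its bin; a bin containing only signature genes falls back to
    the whole bin with a warning. The score is the mean expression of the
    signature genes minus the mean expression of the pooled control draws.

    A counts-layer matrix is log-normalized first; other layers are scored
    as given.
    """
    if m.layer == "counts":
        m = log_normalize(m)
    gene_pos = {g: i for i, g in enumerate(m.genes)}
    present = [g for g in signature if g in gene_pos]
    missing = [g for g in signature if g not in gene_pos]
    if missing:
        warnings.warn(f"{len(missing)} signature gene(s) absent from matrix", stacklevel=2)
    if not present:
        raise ValueError("signature has no genes in the matrix")

    X = m.dense()
    avg = X.mean(axis=1)
    order = np.lexsort((np.array(m.genes), avg))  # mean, then gene symbol for ties
    bins = np.empty(m.n_genes, dtype=int)
    for b, chunk in enumerate(np.array_split(order, min(n_bins, m.n_genes))):
        bins[chunk] = b

    sig_idx = np.array([gene_pos[g] for g in present])
    sig_set = set(sig_idx.tolist())
    rng = np.random.default_rng(seed)
    ctrl_rows: list[np.ndarray] = []
    for gi in sig_idx:
        pool = np.flatnonzero(bins == bins[gi])
        non_sig = np.array([j for j in pool if j not in sig_set])
        if non_sig.size == 0:
            warnings.warn(
                "expression bin contains only signature genes; using whole bin as controls",
                stacklevel=2,
            )
            non_sig = pool
        ctrl_rows.append(rng.choice(non_sig, size=n_ctrl, replace=True))
    ctrl_idx = np.concatenate(ctrl_rows)
    score = X[sig_idx].mean(axis=0) - X[ctrl_idx].mean(axis=0)
    return pd.Series(score, index=pd.Index(m.columns), name="module_score")


def score_states(
    m: ExpressionMatrix,
    signatures: Mapping[str, Sequence[str]],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every cell against every signature; cells x states."""
    cols = {}
    for name in sorted(signatures):
        cols[name] = module_score(m, signatures[name], n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    return pd.DataFrame(cols)


def assign_states(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign each cell to the highest-scoring state.

    Exact ties resolve to the lexicographically smallest state name and
    are flagged in the ``tie`` column.
    """
    if scores.shape[1] < 1:
        raise ValueError("no states scored")
    ordered = scores[sorted(scores.columns)]
    arr = ordered.to_numpy()
    best = arr.argmax(axis=1)  # first occurrence = lexicographic winner
    tie = (arr == arr.max(axis=1, keepdims=True)).sum(axis=1) > 1
    out = pd.DataFrame(
        {
            "assigned_state": [ordered.columns[i] for i in best],
            "tie": tie,
        },
        index=scores.index,
    )
    return pd.concat([scores, out], axis=1)


def state_abundance(
    assignments: pd.DataFrame,
    annotations: pd.DataFrame,
    compartments: Mapping[str, str],
    min_cells: int = 15,
    required_compartments: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Per-sample, compartment-relative state fractions.

    ``assignments`` needs columns cell_id, sample_id, assigned_state;
    ``compartments`` maps each state to its cell-type compartment.
    A sample is retained only when every required compartment has strictly
    more than ``min_cells`` cells (default: every compartment referenced by
    ``compartments``). Returns (abundance samples x states, retained
    samples, excluded samples). Within a compartment the fractions of a
    retained sample sum to one whenever that compartment has assigned cells.
    """
    ann = annotations.set_index("cell_id")
    states = sorted(compartments)
    comps = sorted(set(compartments.values()))
    if required_compartments is None:
        required_compartments = comps
    counts = (
        annotations.groupby(["sample_id", "cell_type"]).size().unstack(fill_value=0)
    )
    samples = sorted(annotations["sample_id"].unique())
    retained, excluded = [], []
    for s in samples:
        ok = all(
            c in counts.columns and counts.loc[s, c] > min_cells
            for c in required_compartments
        )
        (retained if ok else excluded).append(s)
    if not retained:
        raise ValueError(
            f"no sample has >{min_cells} cells in every required compartment"
        )
    merged = assignments.merge(
        annotations[["cell_id", "sample_id", "cell_type"]],
        on=["cell_id", "sample_id"] if "sample_id" in assignments.columns else ["cell_id"],
        how="left",
    )
    ab = pd.DataFrame(0.0, index=pd.Index(retained, name="sample_id"), columns=states)
    for s in retained:
        sub = merged[merged["sample_id"] == s]
        for state in states:
            comp = compartments[state]
            denom = int(counts.loc[s, comp]) if comp in counts.columns else 0
            if denom == 0:
                ab.loc[s, state] = np.nan
                continue
            num = int(((sub["assigned_state"] == state) & (sub["cell_type"] == comp)).sum())
            ab.loc[s, state] = num / denom
    return ab, retained, excluded
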