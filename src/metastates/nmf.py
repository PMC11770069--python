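"""Per-sample normalization and NMF program extraction.

Each sample's cells are normalized to clamped Pearson residuals under a
negative-binomial noise model and decomposed with non-negative matrix
factorization over a range of ranks K. Every factor becomes a Program:
an ordered top-gene list (default 50 genes), the factor's full gene
coefficient vector, and its per-cell usage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .io import ExpressionMatrix

__all__ = [
    "NMFDecomposition",
    "Program",
    "normalize_residuals",
    "run_nmf",
    "decompose_sample",
    "DEFAULT_K_RANGE",
]

DEFAULT_K_RANGE: tuple[int, ...] = (3, 4, 5, 6, 7, 8)


@dataclass
class NMFDecomposition:
    """One NMF fit: X (genes x cells) ~ W (genes x K) @ H (K x cells)."""

    sample_id: str
    k: int
    W: np.ndarray
    H: np.ndarray
    reconstruction_error: float
    seed: int
    n_iter: int

    def __post_init__(self) -> None:
        if (self.W < 0).any() or (self.H < 0).any():
            raise ValueError("NMF factors must be non-negative")
        if self.reconstruction_error < 0:
            raise ValueError("reconstruction error must be non-negative")


@dataclass
class Program:
    """A single NMF factor tagged by sample and rank.

    ``coefficients`` is the factor's full per-gene coefficient vector
    (a pandas Series indexed by gene); ``top_genes`` the ``n_top``
    highest-coefficient genes (ties broken lexicographically);
    ``usage`` the per-cell activity (a Series indexed by cell id).
    """

    program_id: str
    sample_id: str
    k: int
    factor_index: int
    top_genes: list[str]
    coefficients: pd.Series
    usage: pd.Series

    def top_gene_set(self) -> frozenset[str]:
        return frozenset(self.top_genes)


def normalize_residuals(
    m: ExpressionMatrix,
    theta: float = 100.0,
    clip: float | None = None,
) -> ExpressionMatrix:
    """Analytic Pearson residuals under a negative-binomial noise model.

    The expected count is mu_gc = (gene total x cell total) / grand total,
    the residual r = (x - mu) / sqrt(mu + mu^2/theta) with fixed
    inverse-dispersion ``theta``. Residuals are clipped at
    ``clip`` (default sqrt(n_cells)) and negatives are set to zero, so the
    output is a valid non-negative NMF input. All-zero genes are dropped
    with a warning; all-zero cells are an error.
    """
    if m.layer != "counts":
        raise ValueError("normalize_residuals expects the counts layer")
    if m.n_columns < 2:
        raise ValueError("need at least 2 cells")
    X = m.dense().astype(float)
    cell_tot = X.sum(axis=0)
    if (cell_tot == 0).any():
        bad = [c for c, t in zip(m.columns, cell_tot) if t == 0]
        raise ValueError(f"all-zero cells: {bad[:5]}")
    gene_tot = X.sum(axis=1)
    zero_genes = gene_tot == 0
    if zero_genes.any():
        warnings.warn(f"dropping {int(zero_genes.sum())} all-zero gene(s)", stacklevel=2)
        keep = ~zero_genes
        X = X[keep]
        genes = [g for g, k in zip(m.genes, keep) if k]
        gene_tot = gene_tot[keep]
    else:
        genes = list(m.genes)
    grand = X.sum()
    mu = np.outer(gene_tot, cell_tot) / grand
    resid = (X - mu) / np.sqrt(mu + mu * mu / theta)
    cmax = np.sqrt(m.n_columns) if clip is None else clip
    np.clip(resid, 0.0, cmax, out=resid)
    return ExpressionMatrix(genes, list(m.columns), resid, layer="residuals")


def run_nmf(
    m: ExpressionMatrix,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    n_restarts: int = 1,
    sample_id: str = "sample",
) -> NMFDecomposition:
    """Factorize a non-negative matrix at rank ``k``.

    Coordinate-descent NMF minimizing squared Frobenius error, initialized
    with non-negative double SVD plus ``n_restarts - 1`` seeded random
    restarts; the lowest-error solution is kept. Factors are returned in
    decreasing order of total usage, so results are deterministic given
    the seed.
    """
    X = m.dense().astype(float)
    if not np.isfinite(X).all():
        raise ValueError("matrix contains non-finite entries")
    if X.size and X.min() < 0:
        raise ValueError("matrix contains negative entries")
    if k < 1 or k > min(X.shape):
        raise ValueError(f"rank {k} exceeds matrix dimensions {X.shape}")

    best = None
    inits = ["nndsvd"] + ["random"] * max(0, n_restarts - 1)
    for i, init in enumerate(inits):
        model = NMF(
            n_components=k,
            init=init,
            solver="cd",
            beta_loss="frobenius",
            max_iter=max_iter,
            tol=tol,
            random_state=seed + i,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            W = model.fit_transform(X)
        H = model.components_
        err = float(model.reconstruction_err_)
        if best is None or err < best[0]:
            best = (err, W, H, model.n_iter_)
    err, W, H, n_iter = best
    order = np.argsort(-H.sum(axis=1), kind="stable")
    return NMFDecomposition(sample_id, k, W[:, order], H[order, :], err, seed, int(n_iter))


def _factor_programs(
    dec: NMFDecomposition, genes: Sequence[str], cells: Sequence[str], n_top: int
) -> list[Program]:
    programs = []
    gene_idx = pd.Index(genes)
    for j in range(dec.k):
        coef = pd.Series(dec.W[:, j], index=gene_idx)
        # descending coefficient, lexicographic gene tie-break
        ranked = coef.sort_index().sort_values(ascending=False, kind="stable")
        top = ranked.index[: min(n_top, len(ranked))].tolist()
        programs.append(
            Program(
                program_id=f"{dec.sample_id}:K{dec.k}:{j + 1}",
                sample_id=dec.sample_id,
                k=dec.k,
                factor_index=j + 1,
                top_genes=top,
                coefficients=coef,
                usage=pd.Series(dec.H[j, :], index=pd.Index(cells)),
            )
        )
    return programs


def decompose_sample(
    m: ExpressionMatrix,
    sample_id: str,
    k_range: Iterable[int] = DEFAULT_K_RANGE,
    n_top: int = 50,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
    n_restarts: int = 1,
) -> list[Program]:
    """Decompose one sample over a range of ranks.

    A counts-layer input is first converted to clamped Pearson residuals.
    Returns sum(k_range) programs (33 for the default K = 3..8).
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("empty K range")
    if m.layer == "counts":
        m = normalize_residuals(m)
    if m.n_columns < max(ks) or m.n_genes < max(ks):
        raise ValueError(
            f"sample {sample_id!r} has shape {m.shape}, too small for rank {max(ks)}"
        )
    programs: list[Program] = []
    for k in ks:
        dec = run_nmf(
            m, k, seed=seed, max_iter=max_iter, tol=tol,
            n_restarts=n_restarts, sample_id=sample_id,
        )
        programs.extend(_factor_programs(dec, m.genes, m.columns, n_top))
    return programs
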