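"""Program quality control and cross-sample robustness filtering.

Low-quality programs are removed using the median and interquartile range
of intra-rank normalized usage (per cell, the K usages of one decomposition
are normalized to sum to one). Surviving programs must then recur across
ranks within the sample, recur across samples, and be mutually distinct
within the sample:

1. share >= ceil(intra_frac * n_top) top genes with some program from a
   different K of the same sample (default 35 of 50);
2. share >= ceil(inter_frac * n_top) top genes with some program from
   another sample (default 10 of 50);
3. among same-sample survivors, a greedy pass (strongest intra-sample
   overlap first, ties by program id) keeps programs that share
   <= floor(distinct_frac * n_top) genes with every previously kept
   program of that sample.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .nmf import Program

__all__ = [
    "usage_stats",
    "qc_filter",
    "apply_qc",
    "shared_genes",
    "overlap_counts",
    "robust_filter",
]


def usage_stats(programs: Sequence[Program]) -> pd.DataFrame:
    """Median and IQR of intra-rank normalized usage for programs sharing
    one (sample, K). Cells with all-zero usage across the K factors are
    dropped. Quantiles use linear interpolation (R type 7)."""
    if not programs:
        raise ValueError("no programs given")
    keys = {(p.sample_id, p.k) for p in programs}
    if len(keys) != 1:
        raise ValueError(f"programs span multiple (sample, K) groups: {sorted(keys)}")
    U = np.vstack([p.usage.to_numpy(dtype=float) for p in programs])
    tot = U.sum(axis=0)
    live = tot > 0
    rows = []
    if not live.any():
        warnings.warn("all cells have zero usage; stats set to (0, 0)", stacklevel=2)
        for p in programs:
            rows.append({"program_id": p.program_id, "median_usage": 0.0, "iqr_usage": 0.0})
        return pd.DataFrame(rows)
    N = U[:, live] / tot[live]
    med = np.median(N, axis=1)
    q75, q25 = np.quantile(N, [0.75, 0.25], axis=1)
    for p, m, lo, hi in zip(programs, med, q25, q75):
        rows.append(
            {"program_id": p.program_id, "median_usage": float(m), "iqr_usage": float(hi - lo)}
        )
    return pd.DataFrame(rows)


def qc_filter(
    stats: pd.DataFrame,
    median_quantile: float = 0.25,
    iqr_quantile: float = 0.25,
    median_min: float | None = None,
    iqr_min: float | None = None,
) -> list[str]:
    """Retain programs whose usage median and IQR are not strictly below
    the given quantiles of the cohort (ties are kept). Absolute cutoffs
    can be supplied instead via ``median_min`` / ``iqr_min``."""
    if stats.empty:
        raise ValueError("empty stats table")
    med_thr = (
        median_min if median_min is not None
        else float(np.quantile(stats["median_usage"], median_quantile))
    )
    iqr_thr = (
        iqr_min if iqr_min is not None
        else float(np.quantile(stats["iqr_usage"], iqr_quantile))
    )
    keep = ~((stats["median_usage"] < med_thr) | (stats["iqr_usage"] < iqr_thr))
    retained = stats.loc[keep, "program_id"].tolist()
    if not retained:
        raise ValueError(
            "usage QC removed every program; relax median/iqr quantile thresholds"
        )
    return retained


def apply_qc(
    programs: Sequence[Program],
    median_quantile: float = 0.25,
    iqr_quantile: float = 0.25,
) -> list[Program]:
    """Run the usage QC within each (sample, K) cohort and concatenate."""
    groups: dict[tuple[str, int], list[Program]] = {}
    for p in programs:
        groups.setdefault((p.sample_id, p.k), []).append(p)
    kept: list[Program] = []
    for members in groups.values():
        stats = usage_stats(members)
        ids = set(qc_filter(stats, median_quantile, iqr_quantile))
        kept.extend(p for p in members if p.program_id in ids)
    return kept


def shared_genes(a: Program, b: Program) -> int:
    """Number of top genes shared by two programs."""
    return len(a.top_gene_set() & b.top_gene_set())


def overlap_counts(programs: Sequence[Program]) -> np.ndarray:
    """Pairwise shared-top-gene counts as a dense symmetric integer matrix."""
    gene_union = sorted({g for p in programs for g in p.top_genes})
    gpos = {g: i for i, g in enumerate(gene_union)}
    B = np.zeros((len(programs), len(gene_union)), dtype=np.int32)
    for i, p in enumerate(programs):
        for g in p.top_genes:
            B[i, gpos[g]] = 1
    return B @ B.T


@dataclass
class RobustFilterReport:
    """Per-program criterion outcomes from :func:`robust_filter`."""

    table: pd.DataFrame  # program_id, intra_best, inter_best, pass1, pass2, retained


def robust_filter(
    programs: Sequence[Program],
    intra_frac: float = 0.70,
    inter_frac: float = 0.20,
    distinct_frac: float = 0.20,
    n_top: int = 50,
    return_report: bool = False,
):
    """Apply the three robustness criteria; returns the retained programs
    (optionally with a per-program report)."""
    programs = list(programs)
    if len(programs) < 2:
        warnings.warn("fewer than two programs; nothing can be robust", stacklevel=2)
        return ([], RobustFilterReport(pd.DataFrame())) if return_report else []

    O = overlap_counts(programs)
    samples = np.array([p.sample_id for p in programs])
    ks = np.array([p.k for p in programs])
    n = len(programs)
    intra_thr = math.ceil(intra_frac * n_top)
    inter_thr = math.ceil(inter_frac * n_top)
    distinct_thr = math.floor(distinct_frac * n_top)

    same_sample = samples[:, None] == samples[None, :]
    diff_k = ks[:, None] != ks[None, :]
    off_diag = ~np.eye(n, dtype=bool)

    intra_mask = same_sample & diff_k & off_diag
    inter_mask = ~same_sample

    intra_best = np.where(intra_mask, O, -1).max(axis=1)
    inter_best = np.where(inter_mask, O, -1).max(axis=1)
    pass1 = intra_best >= intra_thr
    pass2 = inter_best >= inter_thr
    candidate = pass1 & pass2

    retained_idx: list[int] = []
    for sample in sorted(set(samples)):
        cand = [i for i in range(n) if candidate[i] and samples[i] == sample]
        # strongest intra-sample support first; ties by program id
        cand.sort(key=lambda i: (-intra_best[i], programs[i].program_id))
        kept: list[int] = []
        for i in cand:
            if all(O[i, j] <= distinct_thr for j in kept):
                kept.append(i)
        retained_idx.extend(kept)
    retained_idx.sort()
    retained = [programs[i] for i in retained_idx]
    if not retained:
        warnings.warn("robust_filter retained no programs", stacklevel=2)
    if return_report:
        table = pd.DataFrame(
            {
                "program_id": [p.program_id for p in programs],
                "intra_best": intra_best,
                "inter_best": inter_best,
                "pass_intra": pass1,
                "pass_inter": pass2,
                "retained": [i in set(retained_idx) for i in range(n)],
            }
        )
        return retained, RobustFilterReport(table)
    return retained
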