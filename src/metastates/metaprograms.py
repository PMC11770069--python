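"""Meta-program discovery: cluster robust programs by shared top genes.

Robust programs are clustered hierarchically (Ward linkage with the
squared-distance update, the R ``hclust`` ``ward.D2`` convention) on the
dissimilarity d = 1 - shared_genes / n_top. The cluster number is chosen
by maximal mean silhouette width over a candidate range. Each cluster is
summarized as a meta-program: the ``n_top`` genes with the largest average
NMF coefficient across member programs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .filtering import apply_qc, overlap_counts, robust_filter
from .io import GeneSetCollection
from .nmf import Program

__all__ = [
    "SharedGeneMatrix",
    "MetaProgram",
    "ClusterSolution",
    "overlap_matrix",
    "cluster_programs",
    "build_signature",
    "discover_metaprograms",
    "MetaProgramResult",
    "saturation_analysis",
    "ward_silhouette_cluster",
]


@dataclass
class SharedGeneMatrix:
    program_ids: list[str]
    counts: np.ndarray  # symmetric, diagonal = n_top
    n_top: int = 50

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.program_ids, columns=self.program_ids)


@dataclass
class MetaProgram:
    name: str
    member_program_ids: list[str]
    signature: list[str]
    mean_coefficients: pd.Series


@dataclass
class ClusterSolution:
    labels: pd.Series  # item id -> cluster label (1-based)
    chosen_k: int
    silhouette_curve: pd.DataFrame  # columns k, silhouette
    linkage_matrix: np.ndarray


def overlap_matrix(programs: Sequence[Program], n_top: int = 50) -> SharedGeneMatrix:
    """Pairwise shared-top-gene counts among programs."""
    if len(programs) < 2:
        raise ValueError("need at least two programs")
    counts = overlap_counts(programs)
    np.fill_diagonal(counts, n_top)
    return SharedGeneMatrix([p.program_id for p in programs], counts, n_top)


def ward_silhouette_cluster(
    dist: np.ndarray,
    ids: Sequence[str],
    k_range: Iterable[int],
    manual_k: int | None = None,
) -> ClusterSolution:
    """Ward (ward.D2 convention) clustering of a precomputed dissimilarity
    with silhouette-based model selection; ties go to the smaller k."""
    n = dist.shape[0]
    if n < 3:
        raise ValueError("need at least three items to cluster")
    condensed = squareform(dist, checks=False)
    if np.allclose(condensed, 0):
        raise ValueError("degenerate distances: all pairwise dissimilarities are zero")
    Z = linkage(condensed, method="ward")
    ks = sorted(set(int(k) for k in k_range))
    valid = [k for k in ks if 2 <= k <= n - 1]
    if len(valid) < len(ks):
        warnings.warn(
            f"k range truncated to [{valid[0] if valid else '-'}, {valid[-1] if valid else '-'}] "
            f"for {n} items",
            stacklevel=2,
        )
    if manual_k is None and not valid and ks == [1]:
        labels = pd.Series(np.ones(n, dtype=int), index=pd.Index(ids))
        return ClusterSolution(labels, 1, pd.DataFrame({"k": [1], "silhouette": [np.nan]}), Z)
    rows = []
    best_k, best_sil = None, -np.inf
    for k in valid:
        lab = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            rows.append({"k": k, "silhouette": np.nan})
            continue
        sil = float(silhouette_score(dist, lab, metric="precomputed"))
        rows.append({"k": k, "silhouette": sil})
        if sil > best_sil:  # strict: ties keep the smaller k
            best_k, best_sil = k, sil
    if manual_k is not None:
        best_k = int(manual_k)
    if best_k is None:
        raise ValueError("no valid cluster number in range")
    labels = fcluster(Z, t=best_k, criterion="maxclust") if best_k > 1 else np.ones(n, dtype=int)
    return ClusterSolution(
        pd.Series(labels, index=pd.Index(ids)),
        best_k,
        pd.DataFrame(rows),
        Z,
    )


def cluster_programs(
    m: SharedGeneMatrix,
    k_range: Iterable[int] = range(2, 16),
    manual_k: int | None = None,
) -> ClusterSolution:
    """Cluster programs on d = 1 - shared / n_top."""
    dist = 1.0 - m.counts.astype(float) / m.n_top
    np.fill_diagonal(dist, 0.0)
    return ward_silhouette_cluster(dist, m.program_ids, k_range, manual_k)


def build_signature(
    members: Sequence[Program],
    n_top: int = 50,
    normalize_members: bool = True,
    name: str = "MP",
) -> MetaProgram:
    """Average member coefficient vectors and keep the top ``n_top`` genes.

    Each member's coefficient vector is normalized to unit sum first
    (``normalize_members=False`` averages raw coefficients); genes absent
    from a member contribute zero. Ties break lexicographically.
    """
    if not members:
        raise ValueError("empty cluster")
    vecs = []
    for p in members:
        v = p.coefficients.astype(float)
        if normalize_members:
            s = v.sum()
            v = v / s if s > 0 else v
        vecs.append(v)
    mean = pd.concat(vecs, axis=1).fillna(0.0).mean(axis=1)
    ranked = mean.sort_index().sort_values(ascending=False, kind="stable")
    if len(ranked) < n_top:
        warnings.warn(
            f"meta-program {name}: only {len(ranked)} genes available (< {n_top})",
            stacklevel=2,
        )
    signature = ranked.index[: min(n_top, len(ranked))].tolist()
    return MetaProgram(
        name=name,
        member_program_ids=[p.program_id for p in members],
        signature=signature,
        mean_coefficients=mean,
    )


@dataclass
class MetaProgramResult:
    """Outcome of the full program -> meta-program chain."""

    metaprograms: list[MetaProgram]
    robust_programs: list[Program]
    clusters: ClusterSolution | None
    n_qc_pass: int

    @property
    def n_metaprograms(self) -> int:
        return len(self.metaprograms)

    def signatures(self) -> GeneSetCollection:
        return GeneSetCollection(
            {mp.name: list(mp.signature) for mp in self.metaprograms},
            {mp.name: f"{len(mp.member_program_ids)} member programs" for mp in self.metaprograms},
        )


def discover_metaprograms(
    programs: Sequence[Program],
    qc_median_quantile: float = 0.25,
    qc_iqr_quantile: float = 0.25,
    intra_frac: float = 0.70,
    inter_frac: float = 0.20,
    distinct_frac: float = 0.20,
    n_top: int = 50,
    k_range: Iterable[int] = range(2, 16),
    manual_k: int | None = None,
    min_cluster_size: int = 2,
    normalize_members: bool = True,
) -> MetaProgramResult:
    """Usage QC -> robustness filter -> shared-gene clustering -> signatures."""
    qc_pass = apply_qc(programs, qc_median_quantile, qc_iqr_quantile)
    robust = robust_filter(
        qc_pass, intra_frac=intra_frac, inter_frac=inter_frac,
        distinct_frac=distinct_frac, n_top=n_top,
    )
    if len(robust) < 3:
        return MetaProgramResult([], robust, None, len(qc_pass))
    sgm = overlap_matrix(robust, n_top=n_top)
    sol = cluster_programs(sgm, k_range=k_range, manual_k=manual_k)
    by_id = {p.program_id: p for p in robust}
    mps = []
    for label in sorted(sol.labels.unique()):
        member_ids = sol.labels.index[sol.labels == label].tolist()
        if len(member_ids) < min_cluster_size:
            continue
        mp = build_signature(
            [by_id[i] for i in member_ids],
            n_top=n_top,
            normalize_members=normalize_members,
            name=f"MP{label}",
        )
        mps.append(mp)
    return MetaProgramResult(mps, robust, sol, len(qc_pass))


def saturation_analysis(
    programs_by_sample: Mapping[str, Sequence[Program]],
    n_reps: int = 3,
    seed: int = 0,
    subset_sizes: Iterable[int] | None = None,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Sample-downsampling saturation of the meta-program count.

    Per-sample decompositions are independent of the cohort, so the chain
    is re-run from the QC step on each random sample subset. Returns a
    table (subset_size, replicate, n_metaprograms); subset sizes below 2
    are skipped because the inter-sample criterion needs >= 2 samples.
    """
    samples = sorted(programs_by_sample)
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if subset_sizes is None:
        subset_sizes = range(2, len(samples) + 1)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sorted(set(int(s) for s in subset_sizes)):
        if size < 2 or size > len(samples):
            continue
        for rep in range(n_reps):
            chosen = rng.choice(samples, size=size, replace=False)
            subset = [p for s in chosen for p in programs_by_sample[s]]
            try:
                res = discover_metaprograms(subset, **pipeline_kwargs)
                count = res.n_metaprograms
            except ValueError:
                count = 0
            rows.append({"subset_size": size, "replicate": rep, "n_metaprograms": count})
    return pd.DataFrame(rows)
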