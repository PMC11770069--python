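"""Cell-state co-existence ecosystems and the ACE score.

States are clustered on 1 - Spearman correlation of their abundance
profiles across samples to reveal co-existence patterns; the Jaccard
index over presence calls (abundance > threshold) validates co-existence
independently. An ecosystem's per-sample score is the geometric mean of
member-state abundances, with samples above the median labeled high.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .metaprograms import ClusterSolution, ward_silhouette_cluster

__all__ = [
    "EcosystemClusters",
    "coexistence_clusters",
    "jaccard_coexistence",
    "ace_score",
    "ace_members",
]


@dataclass
class EcosystemClusters:
    labels: pd.Series  # state -> cluster label
    n_clusters: int
    solution: ClusterSolution | None
    singletons: list[str]


def coexistence_clusters(
    abundance: pd.DataFrame,
    k_range: Iterable[int] = range(2, 9),
    manual_k: int | None = None,
) -> EcosystemClusters:
    """Hierarchically cluster states by co-occurrence across samples.

    ``abundance`` is samples x states. Distance is 1 - Spearman rho of the
    abundance profiles. Constant-abundance states have undefined
    correlation and are set aside as singleton clusters with a warning.
    """
    states = sorted(abundance.columns)
    if len(states) < 3:
        raise ValueError("need at least three states")
    A = abundance[states].to_numpy(dtype=float)
    constant = [s for s, col in zip(states, A.T) if np.nanstd(col) == 0]
    if constant:
        warnings.warn(
            f"constant-abundance state(s) assigned singleton clusters: {constant}",
            stacklevel=2,
        )
    active = [s for s in states if s not in constant]
    labels = pd.Series(dtype=int)
    solution = None
    next_label = 1
    if len(active) >= 3:
        sub = abundance[active].to_numpy(dtype=float)
        rho = spearmanr(sub).statistic
        rho = np.atleast_2d(rho)
        dist = 1.0 - rho
        np.fill_diagonal(dist, 0.0)
        dist = (dist + dist.T) / 2  # guard tiny asymmetries
        solution = ward_silhouette_cluster(dist, active, k_range, manual_k)
        labels = solution.labels.copy()
        next_label = int(labels.max()) + 1
    elif active:
        labels = pd.Series(1, index=pd.Index(active))
        next_label = 2
    for s in constant:
        labels.loc[s] = next_label
        next_label += 1
    return EcosystemClusters(labels.astype(int), int(labels.nunique()), solution, constant)


def jaccard_coexistence(
    abundance: pd.DataFrame, state_a: str, state_b: str, threshold: float = 0.5
) -> float:
    """Jaccard index of the samples where both states exceed ``threshold``
    over the samples where either does; an empty union gives 0."""
    a = abundance[state_a] > threshold
    b = abundance[state_b] > threshold
    union = int((a | b).sum())
    if union == 0:
        warnings.warn(
            f"neither {state_a} nor {state_b} exceeds {threshold} in any sample",
            stacklevel=2,
        )
        return 0.0
    return float((a & b).sum() / union)


def ace_members(clusters: EcosystemClusters, focal_state: str, extra: Sequence[str] = ()) -> list[str]:
    """Ecosystem membership: the cluster containing the focal state, the
    focal state itself, and any explicitly added states."""
    if focal_state not in clusters.labels.index:
        raise KeyError(f"unknown state {focal_state!r}")
    label = clusters.labels.loc[focal_state]
    members = clusters.labels.index[clusters.labels == label].tolist()
    for s in [focal_state, *extra]:
        if s not in members:
            members.append(s)
    return sorted(members)


def ace_score(
    abundance: pd.DataFrame,
    member_states: Sequence[str],
    pseudocount: float = 1e-4,
) -> pd.DataFrame:
    """Per-sample geometric mean of member-state abundances with a
    median hi/lo split (strictly above the median = high)."""
    members = list(member_states)
    if not members:
        raise ValueError("empty member set")
    missing = [s for s in members if s not in abundance.columns]
    if missing:
        raise KeyError(f"states absent from abundance matrix: {missing}")
    vals = abundance[members].to_numpy(dtype=float) + pseudocount
    if (vals < 0).any():
        raise ValueError("negative abundances")
    with np.errstate(divide="ignore"):
        score = np.exp(np.mean(np.log(np.maximum(vals, 0)), axis=1)) if (vals > 0).all() else np.zeros(len(vals))
    if not (vals > 0).all():
        score = np.array([np.prod(row) ** (1 / len(members)) for row in vals])
    med = float(np.median(score))
    group = np.where(score > med, "hi", "lo")
    return pd.DataFrame({"score": score, "group": group}, index=abundance.index)
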