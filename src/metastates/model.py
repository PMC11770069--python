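"""Model / Results objects over the functional pipeline.

``CellStateModel`` wraps the full meta-program discovery chain for a
multi-sample single-cell cohort: per-sample NMF decomposition, program
QC, robustness filtering, shared-gene clustering and signature
construction. ``PrognosticModel`` wraps the risk-signature pipeline:
stability-selected LASSO-Cox gene filtering followed by stepwise Cox
coefficient fitting. Both ``fit()`` methods return results objects that
carry the estimates and diagnostics and render a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection
from .metaprograms import (
    MetaProgramResult,
    discover_metaprograms,
    saturation_analysis,
)
from .nmf import DEFAULT_K_RANGE, Program, decompose_sample
from .prognosis import (
    RiskModel,
    RiskStratification,
    concordance_index,
    lasso_stability_select,
    logrank_test,
    risk_score,
    stepwise_cox,
)
from .scoring import assign_states, score_states, state_abundance

__all__ = ["CellStateModel", "CellStateResults", "PrognosticModel", "PrognosticResults"]


class CellStateModel:
    """Discover recurrent transcriptional cell states across samples.

    Parameters
    ----------
    counts : ExpressionMatrix
        Gene-by-cell counts for all samples of one cell-type compartment.
    annotations : DataFrame
        Columns cell_id, sample_id (cell_type optional here).
    """

    def __init__(self, counts: ExpressionMatrix, annotations: pd.DataFrame):
        required = {"cell_id", "sample_id"}
        if not required <= set(annotations.columns):
            raise ValueError(f"annotations need columns {sorted(required)}")
        unknown = set(annotations["cell_id"]) - set(counts.columns)
        if unknown:
            raise ValueError(f"{len(unknown)} annotated cells absent from the matrix")
        self.counts = counts
        self.annotations = annotations.reset_index(drop=True)

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, annotations: pd.DataFrame) -> "CellStateModel":
        m = ExpressionMatrix(
            list(counts.index), list(counts.columns), counts.to_numpy(), layer="counts"
        )
        return cls(m, annotations)

    def decompose(
        self,
        k_range: Iterable[int] = DEFAULT_K_RANGE,
        n_top: int = 50,
        seed: int = 0,
        **nmf_kwargs,
    ) -> dict[str, list[Program]]:
        """Per-sample NMF programs (independent across samples)."""
        programs: dict[str, list[Program]] = {}
        for i, (sample, grp) in enumerate(sorted(self.annotations.groupby("sample_id"))):
            sub = self.counts.subset_columns(grp["cell_id"].tolist())
            programs[sample] = decompose_sample(
                sub, sample, k_range=k_range, n_top=n_top,
                seed=seed + i, **nmf_kwargs,
            )
        return programs

    def fit(
        self,
        k_range: Iterable[int] = DEFAULT_K_RANGE,
        n_top: int = 50,
        seed: int = 0,
        cluster_k_range: Iterable[int] = range(2, 16),
        nmf_kwargs: Mapping | None = None,
        **pipeline_kwargs,
    ) -> "CellStateResults":
        programs = self.decompose(k_range=k_range, n_top=n_top, seed=seed, **(nmf_kwargs or {}))
        flat = [p for ps in programs.values() for p in ps]
        result = discover_metaprograms(
            flat, n_top=n_top, k_range=cluster_k_range, **pipeline_kwargs
        )
        return CellStateResults(self, programs, result, n_top=n_top, seed=seed)


@dataclass
class CellStateResults:
    """Fitted cell-state landscape: programs, meta-programs, diagnostics."""

    model: CellStateModel
    programs_by_sample: dict[str, list[Program]]
    discovery: MetaProgramResult
    n_top: int = 50
    seed: int = 0

    @property
    def n_metaprograms(self) -> int:
        return self.discovery.n_metaprograms

    @property
    def metaprograms(self):
        return self.discovery.metaprograms

    def signatures(self) -> GeneSetCollection:
        return self.discovery.signatures()

    @property
    def n_programs(self) -> int:
        return sum(len(v) for v in self.programs_by_sample.values())

    def silhouette_curve(self) -> pd.DataFrame:
        if self.discovery.clusters is None:
            return pd.DataFrame(columns=["k", "silhouette"])
        return self.discovery.clusters.silhouette_curve

    def score_cells(self, n_bins: int = 24, n_ctrl: int = 100, seed: int | None = None) -> pd.DataFrame:
        sigs = {mp.name: mp.signature for mp in self.metaprograms}
        scores = score_states(
            self.model.counts, sigs, n_bins=n_bins, n_ctrl=n_ctrl,
            seed=self.seed if seed is None else seed,
        )
        return assign_states(scores)

    def state_abundance(
        self,
        assignments: pd.DataFrame | None = None,
        compartments: Mapping[str, str] | None = None,
        min_cells: int = 15,
    ):
        if assignments is None:
            assignments = self.score_cells().reset_index(names="cell_id").merge(
                self.model.annotations[["cell_id", "sample_id"]], on="cell_id"
            )
        if compartments is None:
            comp = (
                self.model.annotations["cell_type"].iloc[0]
                if "cell_type" in self.model.annotations.columns
                else "leukemic"
            )
            compartments = {mp.name: comp for mp in self.metaprograms}
        return state_abundance(
            assignments, self.model.annotations, compartments, min_cells=min_cells
        )

    def saturation(self, n_reps: int = 3, seed: int | None = None, subset_sizes=None, **kw) -> pd.DataFrame:
        return saturation_analysis(
            self.programs_by_sample,
            n_reps=n_reps,
            seed=self.seed if seed is None else seed,
            subset_sizes=subset_sizes,
            n_top=self.n_top,
            **kw,
        )

    def summary(self) -> str:
        lines = [
            "Cell-state discovery summary",
            "=" * 60,
            f"samples:               {len(self.programs_by_sample)}",
            f"programs decomposed:   {self.n_programs}",
            f"programs after QC:     {self.discovery.n_qc_pass}",
            f"robust programs:       {len(self.discovery.robust_programs)}",
            f"meta-programs:         {self.n_metaprograms}",
        ]
        if self.discovery.clusters is not None:
            lines.append(f"chosen cluster number: {self.discovery.clusters.chosen_k}")
            best = self.silhouette_curve().dropna()
            if not best.empty:
                row = best.loc[best["silhouette"].idxmax()]
                lines.append(f"best mean silhouette:  {row['silhouette']:.3f} (k={int(row['k'])})")
        for mp in self.metaprograms:
            lines.append(
                f"  {mp.name}: {len(mp.member_program_ids)} member programs, "
                f"signature {', '.join(mp.signature[:5])}, ..."
            )
        return "\n".join(lines)

    def plot_silhouette(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.silhouette_curve().dropna()
        ax.plot(curve["k"], curve["silhouette"], marker="o")
        ax.set_xlabel("number of clusters")
        ax.set_ylabel("mean silhouette width")
        return ax


class PrognosticModel:
    """Stability-selected Cox risk signature from bulk expression.

    Parameters
    ----------
    bulk : DataFrame or ExpressionMatrix
        Genes x samples expression (normalized scale).
    survival : DataFrame
        Columns sample_id, time, event (plus covariates, ignored here).
    candidate_genes : sequence of str
        The pooled ecosystem signature genes to select from.
    """

    def __init__(self, bulk, survival: pd.DataFrame, candidate_genes: Sequence[str]):
        self.bulk = bulk
        self.survival = survival
        self.candidate_genes = list(dict.fromkeys(candidate_genes))

    def fit(
        self,
        n_iter: int = 1000,
        holdout_frac: float = 0.10,
        min_freq: int | None = None,
        seed: int = 0,
        cv_folds: int = 10,
        standardize: bool = True,
    ) -> "PrognosticResults":
        if min_freq is None:
            min_freq = int(round(0.9 * n_iter))
        selected, freq = lasso_stability_select(
            self.bulk, self.survival, self.candidate_genes,
            n_iter=n_iter, holdout_frac=holdout_frac, min_freq=min_freq,
            seed=seed, cv_folds=cv_folds,
        )
        if selected:
            model = stepwise_cox(self.bulk, self.survival, selected, standardize=standardize)
        else:
            model = RiskModel(genes=[], betas=pd.Series(dtype=float), standardized=standardize)
        model.selection_frequencies = freq
        model.n_iterations = n_iter
        return PrognosticResults(self, model, selected, freq)


@dataclass
class PrognosticResults:
    model: PrognosticModel
    risk_model: RiskModel
    stable_genes: list[str]
    selection_frequencies: pd.Series

    def stratify(self, bulk=None) -> RiskStratification:
        return risk_score(self.risk_model, self.model.bulk if bulk is None else bulk)

    def evaluate(self, bulk=None, survival: pd.DataFrame | None = None) -> dict:
        sv = self.model.survival if survival is None else survival
        strat = self.stratify(bulk)
        chi2, p = logrank_test(strat.groups, sv)
        cidx = concordance_index(strat.scores, sv)
        return {"logrank_chi2": chi2, "logrank_p": p, "c_index": cidx, "stratification": strat}

    def summary(self) -> str:
        lines = [
            "Prognostic risk signature",
            "=" * 60,
            f"candidate genes:      {len(self.model.candidate_genes)}",
            f"stability iterations: {self.risk_model.n_iterations}",
            f"stable genes:         {len(self.stable_genes)}",
            f"final signature:      {len(self.risk_model.genes)} genes",
            "",
            f"{'gene':<12}{'beta':>10}{'freq':>8}",
        ]
        for g in self.risk_model.genes:
            freq = int(self.selection_frequencies.get(g, 0))
            lines.append(f"{g:<12}{self.risk_model.betas[g]:>10.4f}{freq:>8d}")
        return "\n".join(lines)

    def plot_km(self, bulk=None, survival: pd.DataFrame | None = None, ax=None):
        """Kaplan-Meier curves of the high/low risk groups."""
        import matplotlib.pyplot as plt
        from lifelines import KaplanMeierFitter

        sv = (self.model.survival if survival is None else survival).set_index("sample_id")
        strat = self.stratify(bulk)
        if ax is None:
            _, ax = plt.subplots()
        for grp in ["hi", "lo"]:
            idx = strat.groups.index[strat.groups == grp]
            if len(idx) == 0:
                continue
            km = KaplanMeierFitter()
            km.fit(sv.loc[idx, "time"], sv.loc[idx, "event"], label=f"risk {grp}")
            km.plot_survival_function(ax=ax)
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        return ax
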