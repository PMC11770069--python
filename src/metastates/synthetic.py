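"""Seeded synthetic data with the structure the workflow assumes.

``simulate_cells`` emulates a multi-sample scRNA-seq cohort: negative-
binomial baseline counts with log-normal library-size variation, and a
set of planted gene programs whose genes are over-expressed (mean
multiplied by an effect size) in the program-active cells of the samples
that share the program. ``simulate_survival_cohort`` emulates a bulk
cohort with Gaussian expression and exponential survival times whose
hazard is log-linear in a chosen set of prognostic genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = ["SyntheticSpec", "simulate_cells", "simulate_survival_cohort"]


@dataclass
class SyntheticSpec:
    """Study-condition parameters for the single-cell generator.

    Defaults describe a cohort of 20 samples x 300 cells with three
    disjoint 50-gene programs shared by every sample, effect size 5 on
    program genes in active cells, negative-binomial noise with
    dispersion 0.5 and log-normal library-size variation (CV 0.3).
    By default the programs partition the cells of each sample (equal
    active fractions summing to one), mirroring the assignment of every
    cell to a state; fractions summing to less than one leave the
    remainder of cells program-free.
    """

    n_samples: int = 20
    cells_per_sample: int = 300
    n_genes: int = 500
    n_programs: int = 3
    program_size: int = 50
    active_fractions: tuple[float, ...] | None = None  # default: equal shares of 1.0
    effect_size: float = 5.0
    shared_across: Mapping[str, Sequence[str]] | None = None  # program -> sample ids
    nb_dispersion: float = 0.5
    libsize_cv: float = 0.3
    base_mean_log_mu: float = np.log(0.4)
    base_mean_log_sigma: float = 0.6
    seed: int = 0

    def fractions(self) -> np.ndarray:
        if self.active_fractions is not None:
            f = np.asarray(self.active_fractions, dtype=float)
            if len(f) != self.n_programs or f.sum() > 1 + 1e-9:
                raise ValueError("active fractions must match n_programs and sum to <= 1")
            return f
        return np.full(self.n_programs, 1.0 / self.n_programs)


def simulate_cells(spec: SyntheticSpec):
    """Generate counts, annotations and ground truth.

    Returns (ExpressionMatrix counts, annotation DataFrame with cell_id /
    sample_id / cell_type, truth dict with ``programs`` (name -> gene
    list) and ``cell_program`` (Series cell -> program or "none")).
    """
    if spec.effect_size <= 1:
        warnings.warn("effect size <= 1 plants no detectable signal", stacklevel=2)
    if spec.n_programs * spec.program_size > spec.n_genes:
        raise ValueError("programs do not fit in the gene universe")
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]
    program_names = [f"P{i + 1}" for i in range(spec.n_programs)]
    programs = {
        name: genes[i * spec.program_size : (i + 1) * spec.program_size]
        for i, name in enumerate(program_names)
    }
    gene_of_program = {
        name: np.arange(i * spec.program_size, (i + 1) * spec.program_size)
        for i, name in enumerate(program_names)
    }
    samples = [f"S{i + 1:02d}" for i in range(spec.n_samples)]
    shared = spec.shared_across or {name: samples for name in program_names}
    base_mean = rng.lognormal(spec.base_mean_log_mu, spec.base_mean_log_sigma, spec.n_genes)
    fracs = spec.fractions()
    sigma = np.sqrt(np.log(1 + spec.libsize_cv**2))

    blocks, cells, ann_rows, labels = [], [], [], []
    r = 1.0 / spec.nb_dispersion  # NB size parameter; var = mu + dispersion * mu^2
    for s in samples:
        n_c = spec.cells_per_sample
        probs = [float(fracs[i]) if s in shared[program_names[i]] else 0.0
                 for i in range(spec.n_programs)]
        probs.append(max(0.0, 1.0 - sum(probs)))
        choice = rng.choice(spec.n_programs + 1, size=n_c, p=np.array(probs) / sum(probs))
        lib = rng.lognormal(-sigma**2 / 2, sigma, n_c)
        mu = np.outer(base_mean, lib)
        for name in program_names:
            active = np.flatnonzero(choice == program_names.index(name))
            if active.size:
                mu[np.ix_(gene_of_program[name], active)] *= spec.effect_size
        counts = rng.negative_binomial(r, r / (r + mu))
        blocks.append(counts)
        for c in range(n_c):
            cid = f"{s}_c{c:04d}"
            cells.append(cid)
            ann_rows.append({"cell_id": cid, "sample_id": s, "cell_type": "leukemic"})
            labels.append(program_names[choice[c]] if choice[c] < spec.n_programs else "none")
    X = np.concatenate(blocks, axis=1)
    matrix = ExpressionMatrix(genes, cells, X, layer="counts")
    annotations = pd.DataFrame(ann_rows)
    truth = {
        "programs": programs,
        "cell_program": pd.Series(labels, index=pd.Index(cells, name="cell_id")),
    }
    return matrix, annotations, truth


def simulate_survival_cohort(
    n: int,
    genes: int | Sequence[str],
    prognostic_effects: Mapping[str, float],
    censor_rate: float = 0.3,
    baseline_hazard: float = 0.1,
    seed: int = 0,
):
    """Bulk cohort with survival linked to known gene effects.

    Expression is standard normal per gene; event times are exponential
    with hazard ``baseline_hazard * exp(sum effect_g * expr_g)``; censoring
    is uniform on [0, c] with c calibrated on the drawn event times so the
    observed censoring fraction approximates ``censor_rate``.

    Returns (bulk genes x samples DataFrame, survival DataFrame, truth dict).
    """
    if not 0 <= censor_rate < 1:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    gene_list = [f"B{i:04d}" for i in range(genes)] if isinstance(genes, int) else list(genes)
    unknown = set(prognostic_effects) - set(gene_list)
    if unknown:
        raise ValueError(f"effects refer to unknown genes: {sorted(unknown)}")
    samples = [f"pt{i + 1:04d}" for i in range(n)]
    X = rng.standard_normal((len(gene_list), n))
    bulk = pd.DataFrame(X, index=gene_list, columns=samples)
    eta = np.zeros(n)
    for g, eff in prognostic_effects.items():
        eta += eff * bulk.loc[g].to_numpy()
    hazard = baseline_hazard * np.exp(eta)
    T = rng.exponential(1.0 / hazard)
    if censor_rate == 0:
        obs, event = T, np.ones(n, dtype=int)
    else:
        # calibrate uniform censoring horizon on the drawn times
        lo, hi = 1e-6, float(T.max()) * 10
        U = rng.uniform(0, 1, n)
        for _ in range(60):
            c = (lo + hi) / 2
            frac = float(np.mean(U * c < T))  # censored fraction falls as c grows
            if frac > censor_rate:
                lo = c
            else:
                hi = c
        C = U * (lo + hi) / 2
        event = (T <= C).astype(int)
        obs = np.minimum(T, C)
    survival = pd.DataFrame({"sample_id": samples, "time": obs, "event": event})
    truth = {"effects": dict(prognostic_effects), "linear_predictor": pd.Series(eta, index=samples)}
    return bulk, survival, truth
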