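import numpy as np
import pandas as pd
import pytest

from metastates import ExpressionMatrix
from metastates.nmf import Program


def make_program(
    pid: str,
    sample: str,
    k: int,
    top_genes,
    factor_index: int = 1,
    coefficients: pd.Series | None = None,
    usage: pd.Series | None = None,
) -> Program:
    """Construct a Program fixture; coefficients default to a descending
    ramp over the top genes so orderings are well-defined."""
    top_genes = list(top_genes)
    if coefficients is None:
        coefficients = pd.Series(
            np.linspace(1.0, 0.5, len(top_genes)), index=top_genes
        )
    if usage is None:
        usage = pd.Series(np.ones(4), index=[f"{sample}_c{i}" for i in range(4)])
    return Program(
        program_id=pid,
        sample_id=sample,
        k=k,
        factor_index=factor_index,
        top_genes=top_genes,
        coefficients=coefficients,
        usage=usage,
    )


def genes(prefix: str, n: int, start: int = 0) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(start, start + n)]


@pytest.fixture
def tiny_counts() -> ExpressionMatrix:
    rng = np.random.default_rng(0)
    X = rng.poisson(2.0, size=(30, 20))
    return ExpressionMatrix(
        genes("g", 30), [f"c{i}" for i in range(20)], X, layer="counts"
    )


@pytest.fixture
def small_cohort():
    """A 6-sample synthetic cohort with 3 planted programs plus truth."""
    from metastates import SyntheticSpec, simulate_cells

    spec = SyntheticSpec(n_samples=6, cells_per_sample=120, n_genes=240, seed=42)
    return simulate_cells(spec)
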