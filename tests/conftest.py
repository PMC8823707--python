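import numpy as np
import pandas as pd
import pytest

from chepflow import QuantMatrix, SimulationConfig, simulate_quant_matrix
from chepflow.quant import sample_columns


def make_matrix(
    values: np.ndarray,
    histones: list[int] | None = None,
    log2: bool = True,
    intensities: np.ndarray | None = None,
    ids: list[str] | None = None,
) -> QuantMatrix:
    """Build a QuantMatrix by hand from a (proteins x 14) value array."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    cols = sample_columns()
    if values.shape[1] != len(cols):
        raise ValueError("hand-built matrices must span the full 14-sample grid")
    index = pd.Index(ids if ids is not None else [f"P{i:03d}" for i in range(n)], name="protein_id")
    ratios = pd.DataFrame(values, index=index, columns=cols)
    if intensities is None:
        intensities = np.full_like(values, 1e6)
    intens = pd.DataFrame(intensities, index=index, columns=cols).where(ratios.notna())
    flags = pd.Series(False, index=index)
    if histones:
        flags.iloc[histones] = True
    return QuantMatrix(ratios=ratios, intensities=intens, histone_flags=flags, log2=log2)


@pytest.fixture(scope="session")
def clean_simulation():
    """Noise-bearing but dropout-free simulation: complete matrix + truth."""
    config = SimulationConfig(n_proteins_per_archetype=50, noise_sd=0.2, dropout=False, seed=42)
    return simulate_quant_matrix(config)


@pytest.fixture(scope="session")
def dropout_simulation():
    """Default-condition simulation with intensity-dependent missingness."""
    config = SimulationConfig(n_proteins_per_archetype=50, seed=7)
    return simulate_quant_matrix(config)
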