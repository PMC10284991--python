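from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from pmsig import (
    ExpressionMatrix,
    SimulationConfig,
    simulate_cohort,
    fot_normalize,
    filter_proteins,
    log2_zscore,
)


@dataclass
class Cohort:
    """A simulated cohort carried through preprocessing, shared across tests."""

    config: SimulationConfig
    raw: ExpressionMatrix
    peptides: pd.DataFrame
    samples: pd.DataFrame
    truth: object
    mz: ExpressionMatrix            # log2 z-scores, filtered
    log2_fot: pd.DataFrame          # unstandardized log2 FOT (fold-change scale)
    tumor: ExpressionMatrix
    normal: ExpressionMatrix
    pairs: list
    pm_labels: pd.Series            # tumor sample -> 0/1


def _build(config: SimulationConfig) -> Cohort:
    raw, peptides, samples, truth = simulate_cohort(config)
    fot = fot_normalize(raw)
    filtered, _ = filter_proteins(fot, peptides)
    mz = log2_zscore(filtered)
    log2_fot = pd.DataFrame(
        np.log2(np.maximum(filtered.values, 1e-8)),
        index=filtered.data.index,
        columns=filtered.data.columns,
    )
    si = samples.set_index("sample_id")
    tum = [s for s in mz.sample_ids if si.loc[s, "tissue"] == "T"]
    nor = [s for s in mz.sample_ids if si.loc[s, "tissue"] == "N"]
    pairs = [(f"{sub}_T", f"{sub}_N") for sub in si["subject_id"].unique()]
    return Cohort(
        config=config,
        raw=raw,
        peptides=peptides,
        samples=samples,
        truth=truth,
        mz=mz,
        log2_fot=log2_fot,
        tumor=mz.subset(samples=tum),
        normal=mz.subset(samples=nor),
        pairs=pairs,
        pm_labels=si.loc[tum, "pm_status"],
    )


@pytest.fixture(scope="session")
def cohort() -> Cohort:
    """Default-size cohort (2000 proteins, 14 PM vs 6 PM-free subjects)."""
    return _build(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Fast cohort for tests that only need the data shapes."""
    return _build(SimulationConfig(n_proteins=300, n_dep=60, module_size=10, seed=5))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_matrix(values, state="log2z", prefix="P", samples=None) -> ExpressionMatrix:
    """Small helper to wrap an ndarray as an ExpressionMatrix."""
    values = np.asarray(values, dtype=float)
    proteins = [f"{prefix}{i + 1:03d}" for i in range(values.shape[0])]
    if samples is None:
        samples = [f"S{j + 1:02d}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=proteins, columns=samples), state)
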