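"""Expression matrix container with an explicit normalization state.

The pipeline moves a protein x sample abundance table through three states:
``raw`` (reporter intensities), ``fot`` (fraction-of-total, each sample
column sums to one) and ``log2z`` (log2 of FOT, z-scored within each sample
column).  Every stage checks the state tag of its input so that out-of-order
calls fail loudly instead of silently producing nonsense.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_STATES = ("raw", "fot", "log2z")


class StateError(ValueError):
    """Raised when a matrix is in the wrong normalization state for an operation."""


@dataclass
class ExpressionMatrix:
    """A proteins x samples abundance table.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by protein id, columns by sample id.
    state : str
        One of ``raw``, ``fot``, ``log2z``.
    """

    data: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in VALID_STATES:
            raise StateError(f"unknown matrix state {self.state!r}; expected one of {VALID_STATES}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate protein ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_proteins(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def require_state(self, state: str, op: str) -> None:
        if self.state != state:
            raise StateError(f"{op} requires a matrix in state {state!r}, got {self.state!r}")

    def subset(self, proteins=None, samples=None) -> "ExpressionMatrix":
        """Return a sub-matrix, preserving order of the requested ids."""
        df = self.data
        if proteins is not None:
            missing = [p for p in proteins if p not in df.index]
            if missing:
                raise KeyError(f"proteins not in matrix: {missing[:5]}")
            df = df.loc[list(proteins)]
        if samples is not None:
            missing = [s for s in samples if s not in df.columns]
            if missing:
                raise KeyError(f"samples not in matrix: {missing[:5]}")
            df = df[list(samples)]
        return ExpressionMatrix(df, self.state)

    def check_invariants(self, atol: float = 1e-9) -> None:
        """Verify the numeric invariant attached to the current state."""
        if self.state == "fot":
            vals = self.values
            if (vals < 0).any():
                raise ValueError("fot matrix contains negative values")
            sums = vals.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=atol):
                bad = [self.sample_ids[i] for i in np.where(np.abs(sums - 1) > atol)[0][:5]]
                raise ValueError(f"fot columns do not sum to 1: {bad}")
        elif self.state == "log2z":
            vals = self.values
            means = vals.mean(axis=0)
            sds = vals.std(axis=0, ddof=1)
            if not (np.allclose(means, 0.0, atol=atol) and np.allclose(sds, 1.0, atol=atol)):
                raise ValueError("log2z columns are not standardized")

    # --- TSV round-trip (first column protein_id, one column per sample) ---

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "protein_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, state: str = "raw") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t")
        df = df.set_index("protein_id")
        df.index.name = None
        return cls(df, state)
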