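"""Lightweight in-memory containers shared by all analysis stages.

Feature tables are stored frame-major (``T`` frames x ``N`` features): each
row is one trajectory frame.  This is the transpose of the column-per-frame
convention common in the Koopman/transfer-operator literature, and matches
how frames stream off disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureMatrix"]


@dataclass
class FeatureMatrix:
    """A frames x features numeric table with column labels and a time step.

    Parameters
    ----------
    values : ndarray, shape (T, N)
        One row per frame, one column per feature.  Must be finite.
    labels : list of str, optional
        Column labels; generated as ``f0..f{N-1}`` when omitted.
    timestep_ns : float
        Physical time separating consecutive frames, in nanoseconds.
    meta : dict
        Free-form provenance (seeds, architectures, source description).
    """

    values: np.ndarray
    labels: list[str] | None = None
    timestep_ns: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(
                f"feature matrix must be 2-D (frames x features), "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if self.labels is None:
            self.labels = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.labels) != self.values.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.values.shape[1]} columns"
            )
        if self.timestep_ns <= 0:
            raise ValueError("timestep_ns must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, timestep_ns: float = 1.0,
                   meta: dict | None = None) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=np.float64), list(map(str, df.columns)),
                   timestep_ns, meta or {})
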