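"""The observations-by-variables container all modules operate on."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class DataMatrix:
    """An ``n x d`` real-valued matrix of observations (cells) by variables
    (markers or transcripts).

    Parameters
    ----------
    values
        Dense ``(n, d)`` float array.  Every entry must be finite; ``n >= 2``
        and ``d >= 1``.
    variable_names
        ``d`` unique strings.
    observation_ids
        ``n`` strings; autogenerated (``obs_0`` ...) when omitted.
    """

    values: np.ndarray
    variable_names: list[str]
    observation_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, d = self.values.shape
        if n < 2:
            raise ValueError(f"need at least 2 observations, got {n}")
        if d < 1:
            raise ValueError("need at least 1 variable")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries (NaN or inf)")
        self.variable_names = [str(v) for v in self.variable_names]
        if len(self.variable_names) != d:
            raise ValueError(
                f"{len(self.variable_names)} variable names for {d} variables"
            )
        if len(set(self.variable_names)) != d:
            raise ValueError("variable names must be unique")
        if self.observation_ids is None:
            self.observation_ids = [f"obs_{i}" for i in range(n)]
        else:
            self.observation_ids = [str(o) for o in self.observation_ids]
            if len(self.observation_ids) != n:
                raise ValueError(
                    f"{len(self.observation_ids)} observation ids for {n} rows"
                )

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "DataMatrix":
        """A copy sharing names/ids but holding new values of the same shape."""
        return DataMatrix(values, list(self.variable_names), list(self.observation_ids))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DataMatrix":
        return cls(
            df.to_numpy(dtype=float),
            [str(c) for c in df.columns],
            [str(i) for i in df.index],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.observation_ids, columns=self.variable_names
        )


def as_values(data) -> np.ndarray:
    """Accept a DataMatrix or a plain array-like; return the float ndarray."""
    if isinstance(data, DataMatrix):
        return data.values
    return np.asarray(data, dtype=float)
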