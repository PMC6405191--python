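"""Data-adaptive transformation and centering.

The clustering penalty is linear in the center coordinates, so *where zero
sits* in each variable decides what "sparse" means.  Three steps are applied
in order:

1. an optional entry-wise log2 transform, triggered automatically when the
   pooled kurtosis of all entries is very high (a few variables with variance
   orders of magnitude above the rest — typical of raw transcript counts);
2. division of the whole matrix by its single pooled standard deviation, so
   penalties are comparable across datasets;
3. centering: for low-dimensional data (d < 100) each variable's zero is
   moved to its histogram mode ("maximal density centering" — sparsity then
   reads as non-deviance from the most common outcome); for high-dimensional
   data the mean is used instead, keeping the origin at the center of mass.

Every step is recorded in a :class:`PreprocessRecord` so that fitted cluster
centers can be mapped back to the original units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .matrix import DataMatrix

DEFAULT_KURTOSIS_THRESHOLD = 25.0
DEFAULT_LOG2_OFFSET = 1.0
HIGH_DIM_THRESHOLD = 100


@dataclass
class PreprocessRecord:
    """What was done to the data, sufficient to invert the affine part.

    ``offsets`` are expressed in the scaled (post-division) space because
    centering happens after scaling; the inverse affine map is therefore
    ``original = (value + offsets) * pooled_sd`` (followed by ``2**x - log2_offset``
    when the log transform was applied).
    """

    log_applied: bool
    log2_offset: float
    pooled_sd: float
    offsets: np.ndarray
    centering_mode: str  # "max_density" | "mean"
    n_bins: int | None = None

    def __post_init__(self) -> None:
        if self.pooled_sd <= 0:
            raise ValueError("pooled_sd must be positive")
        if self.centering_mode not in ("max_density", "mean"):
            raise ValueError(f"unknown centering_mode {self.centering_mode!r}")
        self.offsets = np.asarray(self.offsets, dtype=float)

    def apply_affine(self, values: np.ndarray) -> np.ndarray:
        """Scale and center (log-space) values into preprocessed space."""
        return np.asarray(values, dtype=float) / self.pooled_sd - self.offsets

    def inverse_affine(self, values: np.ndarray) -> np.ndarray:
        """Undo centering and scaling; leaves the log transform in place."""
        return (np.asarray(values, dtype=float) + self.offsets) * self.pooled_sd

    def inverse(self, values: np.ndarray) -> np.ndarray:
        """Map preprocessed-space values all the way back to raw units."""
        out = self.inverse_affine(values)
        if self.log_applied:
            out = np.exp2(out) - self.log2_offset
        return out


def detect_high_kurtosis(
    data: DataMatrix, threshold: float = DEFAULT_KURTOSIS_THRESHOLD
) -> bool:
    """True when the kurtosis of all n*d entries pooled into one vector
    exceeds ``threshold``.

    The pooled (non-excess, biased) kurtosis of a matrix whose variables have
    comparable variance sits near 3; variables whose variance differs by
    orders of magnitude turn the pooled vector into a scale mixture with very
    heavy tails and kurtosis far above that.
    """
    pooled = data.values.ravel()
    if np.ptp(pooled) == 0 or np.var(pooled) == 0:
        raise ValueError("constant data: kurtosis undefined (zero variance)")
    kurt = float(stats.kurtosis(pooled, fisher=False, bias=True))
    return kurt > threshold


def log2_transform(data: DataMatrix, offset: float = DEFAULT_LOG2_OFFSET) -> DataMatrix:
    """Entry-wise ``log2(value + offset)``; shape and names preserved."""
    shifted = data.values + offset
    if np.any(shifted <= 0):
        bad = float(data.values[shifted <= 0].min())
        raise ValueError(
            f"log2 transform undefined: entry {bad} + offset {offset} <= 0"
        )
    return data.with_values(np.log2(shifted))


def pooled_standard_deviation(values: np.ndarray) -> float:
    """Population SD (divisor n*d) of every entry pooled into one vector."""
    return float(np.std(values, ddof=0))


def scale_by_pooled_sd(data: DataMatrix) -> tuple[DataMatrix, float]:
    """Divide every entry by the single pooled standard deviation of the
    whole matrix.  Uses the population convention (divisor ``n*d``)."""
    sd = pooled_standard_deviation(data.values)
    if sd == 0:
        raise ValueError("pooled standard deviation is zero (constant data)")
    return data.with_values(data.values / sd), sd


def default_n_bins(n: int) -> int:
    """Histogram bin count for mode estimation: n/50, floored at 10."""
    return max(n // 50, 10)


def _mode_bin_midpoint(x: np.ndarray, n_bins: int) -> float:
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:  # constant variable: its value is the mode
        return lo
    counts, edges = np.histogram(x, bins=n_bins, range=(lo, hi))
    # np.histogram bins are left-closed, last bin closed on both ends;
    # argmax breaks count ties toward the lowest bin index.
    m = int(np.argmax(counts))
    return float(0.5 * (edges[m] + edges[m + 1]))


def center_max_density(
    data: DataMatrix, n_bins: int | None = None
) -> tuple[DataMatrix, np.ndarray]:
    """Shift each variable so the midpoint of its most populated histogram
    bin (equal-width bins over [min, max]) sits at zero.

    Returns the centered matrix and the per-variable offsets subtracted.
    """
    if n_bins is None:
        n_bins = default_n_bins(data.n)
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    offsets = np.array(
        [_mode_bin_midpoint(data.values[:, j], n_bins) for j in range(data.d)]
    )
    return data.with_values(data.values - offsets), offsets


def center_mean(data: DataMatrix) -> tuple[DataMatrix, np.ndarray]:
    """Subtract each variable's arithmetic mean (origin at center of mass)."""
    offsets = data.values.mean(axis=0)
    return data.with_values(data.values - offsets), offsets


def preprocess(
    data: DataMatrix,
    *,
    log2: str = "auto",
    centering: str = "auto",
    kurtosis_threshold: float = DEFAULT_KURTOSIS_THRESHOLD,
    log2_offset: float = DEFAULT_LOG2_OFFSET,
    n_bins: int | None = None,
) -> tuple[DataMatrix, PreprocessRecord]:
    """Full preprocessing: optional log2 -> pooled-SD scaling -> centering.

    Parameters
    ----------
    log2
        ``"auto"`` (kurtosis-triggered), ``"on"`` or ``"off"``.
    centering
        ``"auto"`` (max-density for d < 100, mean otherwise),
        ``"max_density"`` or ``"mean"``.
    """
    if log2 not in ("auto", "on", "off"):
        raise ValueError(f"log2 must be auto/on/off, got {log2!r}")
    if centering not in ("auto", "max_density", "mean"):
        raise ValueError(f"centering must be auto/max_density/mean, got {centering!r}")

    log_applied = (
        detect_high_kurtosis(data, kurtosis_threshold) if log2 == "auto" else log2 == "on"
    )
    out = log2_transform(data, log2_offset) if log_applied else data

    out, sd = scale_by_pooled_sd(out)

    mode = centering
    if mode == "auto":
        mode = "max_density" if data.d < HIGH_DIM_THRESHOLD else "mean"
    if mode == "max_density":
        bins = n_bins if n_bins is not None else default_n_bins(data.n)
        out, offsets = center_max_density(out, bins)
    else:
        bins = None
        out, offsets = center_mean(out)

    record = PreprocessRecord(
        log_applied=log_applied,
        log2_offset=log2_offset,
        pooled_sd=sd,
        offsets=offsets,
        centering_mode=mode,
        n_bins=bins,
    )
    return out, record
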