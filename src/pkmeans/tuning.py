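"""Penalty selection by resampling stability.

The penalty that yields the most *reproducible* clustering is selected as
follows.  For each candidate penalty on a wide, exponentially spaced grid,
pairs of bootstrap datasets (``N_r`` points drawn with replacement) are
clustered independently; every observation of the full dataset is then
allocated to the nearest center of each fit, and the agreement of the two
induced partitions is measured with the Adjusted Rand Index.  Rounds are
repeated, balanced across penalties, until the mean ARI of the best penalty
is statistically separated from the rest (2-standard-error intervals), its
standard error drops below a threshold, or a round cap is reached.  The
optimal penalty is the one with the largest mean ARI; an optimum on the grid
boundary triggers a warning suggesting a wider grid or a larger sample.

When the full dataset is subsampled (``N_r < n``), the penalty appropriate
for clustering all n points is approximately ``lambda * n / N_r``, because
the attraction force of a cluster scales with its member count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ari import ari
from .core import (
    DEFAULT_K,
    DEFAULT_MAX_ITER,
    DEFAULT_RAMP_STEPS,
    DegenerateModelError,
    estep_allocate,
    multi_restart_fit,
)
from .matrix import as_values

DEFAULT_N_R = 10_000
DEFAULT_INIT_ROUNDS = 20
DEFAULT_MAX_ROUNDS = 100
DEFAULT_SE_THRESHOLD = 0.01
DEFAULT_TUNING_RESTARTS = 2
ROUND_BATCH = 5
EXTENSION_STEP = 3  # half-octave grid points added per boundary extension
MIN_EXPONENT = -6.0  # extension floor 2^-6
MAX_EXPONENT = 14.0  # extension ceiling 2^14
SCOUT_ROUNDS = 3  # cheap look-ahead rounds per scout penalty
SCOUT_OCTAVES = (1, 2, 3, 4, 5)  # scouts at 2x..32x the top grid penalty


def default_penalty_grid() -> np.ndarray:
    """The default penalty grid: 2^0, 2^0.5, ..., 2^5 (11 values)."""
    return np.exp2(np.linspace(0.0, 5.0, 11))


def _derived_seed(*parts: int) -> int:
    """A deterministic 31-bit seed from a tuple of integers."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] >> 1)


@dataclass
class StabilityRound:
    """One bootstrap-pair stability measurement at a single penalty."""

    ari: float
    centers_1: np.ndarray | None
    centers_2: np.ndarray | None
    failed: bool = False


@dataclass
class TuningResult:
    """Outcome of the stability-based penalty scan."""

    penalties: np.ndarray
    ari_means: np.ndarray
    ari_ses: np.ndarray
    runs_per_penalty: int
    center_sets: list[list[np.ndarray]]
    optimal_index: int
    N_r: int
    stopped_by: str  # "separation" | "se_threshold" | "max_runs"
    boundary_warning: bool = False
    ari_values: list[list[float]] = field(default_factory=list)

    @property
    def optimal_penalty(self) -> float:
        return float(self.penalties[self.optimal_index])

    def report(self) -> pd.DataFrame:
        """Per-penalty summary table (penalty, mean ARI, SE, rounds)."""
        return pd.DataFrame(
            {
                "penalty": self.penalties,
                "mean_ari": self.ari_means,
                "se_ari": self.ari_ses,
                "rounds": self.runs_per_penalty,
                "optimal": [i == self.optimal_index for i in range(len(self.penalties))],
            }
        )


def stability_round(
    data,
    lam: float,
    N_r: int,
    k: int = DEFAULT_K,
    rng_seed: int = 0,
    n_restarts: int = DEFAULT_TUNING_RESTARTS,
    ramp_steps: int = DEFAULT_RAMP_STEPS,
    max_iter: int = DEFAULT_MAX_ITER,
) -> StabilityRound:
    """Draw two bootstrap datasets of size ``N_r``, cluster each, allocate
    the *full* data to both center sets and return the partitions' ARI.

    A fit in which no cluster survives makes the round fail: its ARI is
    recorded as 0 (a maximally unstable outcome) with a warning.
    """
    X = as_values(data)
    n = X.shape[0]
    if N_r < 2:
        raise ValueError(f"N_r must be >= 2, got {N_r}")
    rng = np.random.default_rng(rng_seed)
    centers = []
    for _ in range(2):
        idx = rng.integers(0, n, size=N_r)
        fit_seed = int(rng.integers(0, 2**31 - 1))
        try:
            model, _ = multi_restart_fit(
                X[idx], min(k, N_r), lam, n_restarts, fit_seed, ramp_steps, max_iter
            )
        except DegenerateModelError:
            warnings.warn(
                f"stability round failed at lambda={lam}: no surviving clusters",
                RuntimeWarning,
                stacklevel=2,
            )
            return StabilityRound(ari=0.0, centers_1=None, centers_2=None, failed=True)
        centers.append(model.centers)
    p1 = estep_allocate(X, centers[0]).labels
    p2 = estep_allocate(X, centers[1]).labels
    # trivial partitions (all points in one cluster) carry no reproducibility
    # information and must not win the stability contest: similarity 0
    if np.unique(p1).size < 2 or np.unique(p2).size < 2:
        value = 0.0
    else:
        ari_seed = int(rng.integers(0, 2**31 - 1))
        value = ari(p1, p2, rng_seed=ari_seed)
    return StabilityRound(ari=value, centers_1=centers[0], centers_2=centers[1])


def _penalty_key(lam: float, index: int) -> int:
    """Seed-derivation key for a penalty: its position on the half-octave
    exponent lattice when positive, else its grid index.  Keys are stable
    under grid extension, so every (round, penalty) pair re-uses the same
    bootstrap sample regardless of when the penalty joined the grid."""
    if lam > 0:
        return 1_000_000 + int(round(1e6 * np.log2(lam)))
    return index


def tune_penalty(
    data,
    penalties=None,
    N_r: int | None = None,
    k: int = DEFAULT_K,
    init_rounds: int = DEFAULT_INIT_ROUNDS,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
    se_threshold: float = DEFAULT_SE_THRESHOLD,
    base_seed: int = 0,
    n_restarts: int = DEFAULT_TUNING_RESTARTS,
    ramp_steps: int = DEFAULT_RAMP_STEPS,
    max_iter: int = DEFAULT_MAX_ITER,
    round_batch: int = ROUND_BATCH,
    extend_grid: bool | None = None,
) -> TuningResult:
    """Scan the penalty grid with balanced stability rounds until a stopping
    criterion fires; the optimal penalty maximizes the mean ARI.

    Stopping criteria, checked after ``init_rounds`` rounds and then after
    every batch of ``round_batch`` additional rounds (counts stay balanced
    across penalties):

    a. the 2-SE interval around the best penalty's mean ARI overlaps no
       other penalty's interval ("separation");
    b. the best penalty's standard error falls below ``se_threshold``;
    c. ``max_rounds`` rounds reached.

    The optimal penalty is the argmax of the mean ARI; when several
    penalties are exactly tied at the maximum (a reproducibility plateau),
    the largest of them is selected — the sparsest model among equally
    reproducible ones.

    When the default grid is used and the running optimum sits on a grid
    boundary, the grid is extended beyond that edge in half-octave steps
    (the data evidently calls for a penalty range the default does not
    cover) before the stopping criteria are consulted; extension stops at
    2^-6 / 2^14 or once the optimum is interior.  A user-supplied grid is
    never extended (``extend_grid=True`` opts in); an optimum remaining on
    a boundary raises the usual warning to widen the range.
    """
    X = as_values(data)
    n = X.shape[0]
    if penalties is None:
        penalties = default_penalty_grid()
        if extend_grid is None:
            extend_grid = True
    penalties = list(np.asarray(penalties, dtype=float))
    if len(penalties) < 1:
        raise ValueError("penalties must be a non-empty 1-D sequence")
    if np.any(np.diff(penalties) <= 0):
        raise ValueError("penalties must be strictly increasing")
    if N_r is None:
        N_r = min(n, DEFAULT_N_R)
    if init_rounds < 2:
        raise ValueError("init_rounds must be >= 2")
    if max_rounds < init_rounds:
        raise ValueError("max_rounds must be >= init_rounds")
    extend = bool(extend_grid)
    # extension walks the half-octave lattice; only lattice grids qualify
    if extend and any(
        lam <= 0 or abs(2 * np.log2(lam) - round(2 * np.log2(lam))) > 1e-9
        for lam in penalties
    ):
        extend = False

    aris: dict[int, list[float]] = {}
    center_sets: dict[int, list[np.ndarray]] = {}

    def run_rounds(lam: float, index: int, upto: int) -> None:
        key = _penalty_key(lam, index)
        a = aris.setdefault(key, [])
        c = center_sets.setdefault(key, [])
        for r in range(len(a), upto):
            res = stability_round(
                X,
                lam,
                N_r,
                k=k,
                rng_seed=_derived_seed(base_seed, r, key),
                n_restarts=n_restarts,
                ramp_steps=ramp_steps,
                max_iter=max_iter,
            )
            a.append(res.ari)
            if res.centers_1 is not None:
                c.append(res.centers_1)
            if res.centers_2 is not None:
                c.append(res.centers_2)

    rounds_done = init_rounds
    stopped_by = "max_runs"
    while True:
        for p, lam in enumerate(penalties):
            run_rounds(lam, p, rounds_done)
        keys = [_penalty_key(lam, p) for p, lam in enumerate(penalties)]
        means = np.array([np.mean(aris[key]) for key in keys])
        ses = np.array([np.std(aris[key], ddof=1) / np.sqrt(len(aris[key])) for key in keys])
        # among penalties whose mean ARIs are exactly tied at the maximum,
        # the largest is optimal: the sparsest model at equal reproducibility
        best = int(np.flatnonzero(means == means.max())[-1])
        n_pen = len(penalties)

        if extend and n_pen > 1:
            expo = 2 * np.log2(penalties[best])  # half-octave lattice index
            if best == n_pen - 1 and expo < 2 * MAX_EXPONENT:
                top = 2 * np.log2(penalties[-1])
                new = [0.5 * (top + s) for s in range(1, EXTENSION_STEP + 1)]
                penalties += [float(np.exp2(e)) for e in new if e <= MAX_EXPONENT]
                continue
            if best == 0 and expo > 2 * MIN_EXPONENT:
                bottom = 2 * np.log2(penalties[0])
                new = [0.5 * (bottom - s) for s in range(EXTENSION_STEP, 0, -1)]
                penalties = [float(np.exp2(e)) for e in new if e >= MIN_EXPONENT] + penalties
                continue

        stop: str | None = None
        if n_pen == 1:
            stop = "separation"
        else:
            lo, hi = means - 2 * ses, means + 2 * ses
            others = np.arange(n_pen) != best
            if np.all((hi[others] < lo[best]) | (lo[others] > hi[best])):
                stop = "separation"
            elif ses[best] < se_threshold:
                stop = "se_threshold"
            elif rounds_done >= max_rounds:
                stop = "max_runs"
        if stop is None:
            rounds_done = min(rounds_done + round_batch, max_rounds)
            continue
        # before accepting a stop, scout a few octaves beyond the grid top:
        # the ARI-vs-penalty curve can dip at a resolution change and rise
        # again, so an interior argmax does not prove the optimum is bracketed
        if extend:
            top = 2 * np.log2(penalties[-1])
            scouts = [
                float(penalties[-1] * 2**o)
                for o in SCOUT_OCTAVES
                if 0.5 * top + o <= MAX_EXPONENT
            ]
            for lam in scouts:
                run_rounds(lam, -1, SCOUT_ROUNDS)
            scout_means = {
                lam: float(np.mean(aris[_penalty_key(lam, -1)])) for lam in scouts
            }
            better = [lam for lam, m in scout_means.items() if m > means.max()]
            if better:
                target_expo = 2 * np.log2(max(better))  # half-octave units
                steps = int(round(target_expo - top))
                penalties += [
                    float(np.exp2(0.5 * (top + s))) for s in range(1, steps + 1)
                ]
                continue
        stopped_by = stop
        break

    boundary = best in (0, len(penalties) - 1)
    if boundary:
        warnings.warn(
            f"optimal penalty {penalties[best]:g} lies on the grid boundary; "
            "consider a wider penalty range or a larger sample size",
            UserWarning,
            stacklevel=2,
        )
    keys = [_penalty_key(lam, p) for p, lam in enumerate(penalties)]
    return TuningResult(
        penalties=np.asarray(penalties),
        ari_means=means,
        ari_ses=ses,
        runs_per_penalty=rounds_done,
        center_sets=[center_sets[key] for key in keys],
        optimal_index=best,
        N_r=N_r,
        stopped_by=stopped_by,
        boundary_warning=boundary,
        ari_values=[aris[key] for key in keys],
    )


def rescale_penalty(lambda_opt: float, n: int, N_r: int) -> float:
    """Penalty found on subsamples of size ``N_r``, rescaled for the full
    dataset of size ``n``: ``lambda_opt * n / N_r``."""
    if lambda_opt <= 0 or n <= 0 or N_r <= 0:
        raise ValueError("lambda_opt, n and N_r must all be positive")
    return lambda_opt * n / N_r


def select_generalizable_centers(
    center_sets: list[np.ndarray],
    data,
    rng_seed: int = 0,
) -> np.ndarray:
    """Among center sets fitted at one penalty, return the most
    generalizable one: the set whose induced full-data partition has the
    highest average ARI to the partitions induced by all the other sets.

    Ties break to the earliest-produced set.  A single set is returned
    as-is with a warning.
    """
    sets = [c for c in center_sets if c is not None]
    if len(sets) == 0:
        raise ValueError("no center sets to choose from")
    if len(sets) == 1:
        warnings.warn(
            "only one center set available; returning it without comparison",
            UserWarning,
            stacklevel=2,
        )
        return sets[0]
    X = as_values(data)
    parts = [estep_allocate(X, c).labels for c in sets]
    m = len(sets)
    sim = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            sim[i, j] = sim[j, i] = ari(
                parts[i], parts[j], rng_seed=_derived_seed(rng_seed, i, j)
            )
    avg = sim.sum(axis=1) / (m - 1)
    return sets[int(np.argmax(avg))]
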