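"""Penalized k-means: EM with an L1 soft-thresholded M-step.

The objective minimized is

    Q(z, mu) = sum_m sum_{l in m} ||x_l - mu_m||^2 + lambda * sum_{m,j} |mu_{m,j}|

For a fixed allocation z, the per-coordinate minimizer is the soft threshold

    mu_{m,j} = sign(a) * max(|a| - lambda / (2 * n_m), 0),

where ``a`` is the member mean and ``n_m`` the member count.  Coordinates
whose member mean is small relative to the penalty are set to *exactly* zero;
a cluster whose whole center row is zeroed is eliminated and its members are
reabsorbed by the survivors at the next allocation step.  Because of this
elimination, the surviving cluster count is controlled by ``lambda`` rather
than by the requested ``k`` (as long as k is generous enough that at least
one cluster dies).

Each run ramps the effective penalty linearly from 0 up to the requested
``lambda`` over the first E-steps, which protects against wiping out too many
clusters while the centers are still poorly placed.  Initial centers come
from vanilla k-means++ (D^2-weighted) seeding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

from .matrix import as_values

DEFAULT_K = 30
DEFAULT_RAMP_STEPS = 10
DEFAULT_MAX_ITER = 100
DEFAULT_N_RUNS = 21


class DegenerateModelError(RuntimeError):
    """Raised when the penalty shrinks every cluster center to the origin."""


@dataclass
class ClusterModel:
    """Surviving cluster centers of one penalized k-means fit.

    ``centers`` is a ``(k', d)`` matrix with exact zeros marking variables
    that do not contribute to the definition of a cluster.  No row is all
    zero (such clusters were eliminated).  ``score`` is the minimized
    objective Q on the training data.
    """

    centers: np.ndarray
    penalty: float
    k_requested: int
    score: float
    seed: int
    converged: bool = True

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


@dataclass
class Partition:
    """Cluster labels, indexing rows of an accompanying center matrix."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


def kmeanspp_init(data, k: int, rng_seed: int) -> np.ndarray:
    """Vanilla k-means++ seeding: the first center is uniform over the data,
    each later one is a data point drawn with probability proportional to its
    squared distance to the nearest center chosen so far.

    Already-chosen points have zero weight, so with ``k == n`` every distinct
    point becomes a center.  Deterministic given ``rng_seed``.
    """
    X = as_values(data)
    n = X.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of observations n={n}")
    rng = np.random.default_rng(rng_seed)
    idx = np.empty(k, dtype=int)
    idx[0] = rng.integers(n)
    d2 = cdist(X, X[idx[0]][None, :], "sqeuclidean").ravel()
    for i in range(1, k):
        total = d2.sum()
        if total > 0:
            probs = d2 / total
            idx[i] = rng.choice(n, p=probs)
        else:
            # all remaining points coincide with chosen centers; fall back
            # to a uniform draw among the not-yet-chosen indices
            remaining = np.setdiff1d(np.arange(n), idx[:i])
            idx[i] = rng.choice(remaining)
        d2 = np.minimum(d2, cdist(X, X[idx[i]][None, :], "sqeuclidean").ravel())
    return X[idx].copy()


def estep_allocate(data, centers: np.ndarray) -> Partition:
    """Allocate each observation to its nearest center (squared Euclidean
    distance); distance ties break to the lowest center index."""
    X = as_values(data)
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[0] < 1:
        raise ValueError("need at least one cluster center")
    d2 = cdist(X, centers, "sqeuclidean")
    return Partition(d2.argmin(axis=1))


def _cluster_sums(X: np.ndarray, labels: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(labels, minlength=k)
    d = X.shape[1]
    if d <= 64:  # column-wise bincount beats sparse matmul for narrow data
        sums = np.empty((k, d))
        for j in range(d):
            sums[:, j] = np.bincount(labels, weights=X[:, j], minlength=k)
        return sums, counts
    ind = sparse.csr_matrix(
        (np.ones(labels.size), (labels, np.arange(labels.size))),
        shape=(k, X.shape[0]),
    )
    return np.asarray(ind @ X), counts


def mstep_update(data, partition: Partition | np.ndarray, lam: float, n_centers: int | None = None) -> np.ndarray:
    """Soft-threshold M-step.

    For each cluster m and variable j, with member mean ``a`` and member
    count ``n_m``: ``mu = sign(a) * max(|a| - lam / (2 n_m), 0)``.  Rows that
    come out all zero correspond to eliminated clusters; the caller removes
    them.  Every cluster index in ``partition`` must have at least one member.
    """
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    X = as_values(data)
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition, dtype=int)
    k = n_centers if n_centers is not None else int(labels.max()) + 1
    sums, counts = _cluster_sums(X, labels, k)
    if np.any(counts == 0):
        raise ValueError("empty cluster passed to mstep_update; drop it first")
    means = sums / counts[:, None]
    thresh = lam / (2.0 * counts)
    return np.sign(means) * np.maximum(np.abs(means) - thresh[:, None], 0.0)


def model_score(X: np.ndarray, labels: np.ndarray, centers: np.ndarray, lam: float) -> float:
    """The objective Q = sum of squared distances to assigned centers plus
    lam * sum |mu|, as minimized."""
    diffs = X - centers[labels]
    return float(np.einsum("ij,ij->", diffs, diffs) + lam * np.abs(centers).sum())


def penalized_kmeans_fit(
    data,
    k: int,
    lam: float,
    rng_seed: int,
    ramp_steps: int = DEFAULT_RAMP_STEPS,
    max_iter: int = DEFAULT_MAX_ITER,
    init_centers: np.ndarray | None = None,
) -> tuple[ClusterModel, Partition]:
    """One penalized k-means run: k-means++ init, linear penalty ramp, EM to
    convergence (no reallocation in an E-step at the full penalty).

    Clusters emptied by an E-step or shrunk entirely to zero by the M-step
    are removed; their members are reallocated at the next E-step.  Raises
    :class:`DegenerateModelError` when no cluster survives.  If ``max_iter``
    is reached without convergence the best-so-far model is returned with
    ``converged=False`` and a warning.  ``init_centers`` overrides the
    k-means++ initialization (e.g. to continue from a known state).
    """
    X = as_values(data)
    n = X.shape[0]
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if init_centers is not None:
        centers = np.array(init_centers, dtype=float)
    else:
        centers = kmeanspp_init(X, min(k, n), rng_seed)

    prev_labels: np.ndarray | None = None
    prev_at_full = False
    prev_k = -1
    labels = np.zeros(n, dtype=int)
    converged = False
    for it in range(max_iter):
        eff = lam if ramp_steps <= 0 else lam * min(it / ramp_steps, 1.0)
        # argmin of ||x - c||^2 = argmin of ||c||^2 - 2 x.c  (x-term constant)
        gram = X @ centers.T
        gram *= -2.0
        gram += np.einsum("ij,ij->i", centers, centers)
        labels = gram.argmin(axis=1)
        counts = np.bincount(labels, minlength=centers.shape[0])
        if np.any(counts == 0):  # empty clusters are eliminated
            keep = counts > 0
            centers = centers[keep]
            labels = np.cumsum(keep)[labels] - 1
        if (
            prev_at_full
            and eff == lam
            and prev_labels is not None
            and prev_k == centers.shape[0]
            and np.array_equal(prev_labels, labels)
        ):
            converged = True
            break
        prev_labels = labels
        prev_at_full = eff == lam
        prev_k = centers.shape[0]
        centers = mstep_update(X, labels, eff, centers.shape[0])
        alive = np.any(centers != 0, axis=1)
        if not alive.any():
            raise DegenerateModelError(
                f"penalty lambda={lam} eliminated every cluster"
            )
        centers = centers[alive]
    if not converged:
        warnings.warn(
            f"penalized k-means did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
        # make labels consistent with the final centers
        labels = estep_allocate(X, centers).labels
        counts = np.bincount(labels, minlength=centers.shape[0])
        keep = counts > 0
        centers = centers[keep]
        labels = np.cumsum(keep)[labels] - 1

    score = model_score(X, labels, centers, lam)
    model = ClusterModel(
        centers=centers,
        penalty=lam,
        k_requested=k,
        score=score,
        seed=rng_seed,
        converged=converged,
    )
    return model, Partition(labels)


def multi_restart_fit(
    data,
    k: int,
    lam: float,
    n_runs: int = DEFAULT_N_RUNS,
    base_seed: int = 0,
    ramp_steps: int = DEFAULT_RAMP_STEPS,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[ClusterModel, Partition]:
    """Run ``n_runs`` independent fits (seeds ``base_seed + r``) and return
    the one with the lowest objective Q."""
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    best: tuple[ClusterModel, Partition] | None = None
    failures: list[str] = []
    for r in range(n_runs):
        try:
            model, part = penalized_kmeans_fit(
                data, k, lam, base_seed + r, ramp_steps, max_iter
            )
        except DegenerateModelError as exc:
            failures.append(str(exc))
            continue
        if best is None or model.score < best[0].score:
            best = (model, part)
    if best is None:
        raise DegenerateModelError(
            f"all {n_runs} restarts degenerate at lambda={lam}: {failures[0]}"
        )
    return best
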