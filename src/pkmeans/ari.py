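"""Adjusted Rand Index between two partitions, exact and pair-sampled.

The ARI is the chance-corrected fraction of observation pairs on which two
partitions agree (placed together in both, or apart in both).  It is 1 for
identical partitions up to relabeling and has expectation ~0 under random
label permutation, which makes it suitable as a reproducibility score: a
trivial all-in-one-cluster partition scores 0 against anything non-trivial.

The exact value comes from the contingency table in O(n + #cells).  For very
large n the pair-level identity

    ARI = 2 (a d - b c) / ((a + b)(b + d) + (a + c)(c + d))

over the concordance counts of all C(n, 2) unordered pairs (a: together in
both, b: together only in the first, c: together only in the second, d:
apart in both) is estimated from a random sample of pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import sparse

DEFAULT_N_PAIRS = 10_000
EXACT_MAX_N = 5_000


def _check_pair(labels_a, labels_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.ndim != 1 or b.ndim != 1:
        raise ValueError("label vectors must be one-dimensional")
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"label vectors differ in length: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 observations")
    return a, b


def ari_exact(labels_a, labels_b) -> float:
    """Exact ARI from the contingency table (permutation-model expectation).

    Returns 1.0 when both partitions are trivial in the same degenerate way
    (the correction denominator vanishes for, e.g., two all-singleton
    partitions, which agree perfectly).
    """
    a, b = _check_pair(labels_a, labels_b)
    _, ia = np.unique(a, return_inverse=True)
    _, ib = np.unique(b, return_inverse=True)
    contingency = sparse.coo_matrix(
        (np.ones(a.size), (ia, ib)),
        shape=(ia.max() + 1, ib.max() + 1),
    ).tocsr()
    nij = contingency.data
    ai = np.asarray(contingency.sum(axis=1)).ravel()
    bj = np.asarray(contingency.sum(axis=0)).ravel()
    n = a.size

    def comb2(x):
        return (x * (x - 1.0)) / 2.0

    sum_comb = comb2(nij).sum()
    sum_a = comb2(ai).sum()
    sum_b = comb2(bj).sum()
    total = comb2(np.array([n], dtype=float))[0]
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        # both partitions degenerate identically (all singletons / one cluster)
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def ari_sampled(labels_a, labels_b, n_pairs: int = DEFAULT_N_PAIRS, rng_seed: int = 0) -> float:
    """ARI estimated from ``n_pairs`` unordered observation pairs sampled
    uniformly with replacement.

    Deterministic given ``rng_seed``.  When the pair-level denominator is
    degenerate (e.g. one partition all singletons against one all-in-one)
    the defined fallback value 0.0 is returned with a warning.
    """
    a, b = _check_pair(labels_a, labels_b)
    if n_pairs < 1:
        raise ValueError(f"n_pairs must be >= 1, got {n_pairs}")
    n = a.size
    rng = np.random.default_rng(rng_seed)
    i = rng.integers(0, n, size=n_pairs)
    j = rng.integers(0, n - 1, size=n_pairs)
    j[j >= i] += 1  # uniform over ordered pairs i != j; symmetric in (i, j)
    same_a = a[i] == a[j]
    same_b = b[i] == b[j]
    aa = float(np.sum(same_a & same_b))
    bb = float(np.sum(same_a & ~same_b))
    cc = float(np.sum(~same_a & same_b))
    dd = float(np.sum(~same_a & ~same_b))
    denom = (aa + bb) * (bb + dd) + (aa + cc) * (cc + dd)
    if denom == 0:
        warnings.warn(
            "degenerate pair-concordance counts; returning ARI fallback 0.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return float(2.0 * (aa * dd - bb * cc) / denom)


def ari(
    labels_a,
    labels_b,
    exact_max_n: int = EXACT_MAX_N,
    n_pairs: int = DEFAULT_N_PAIRS,
    rng_seed: int = 0,
) -> float:
    """Exact ARI for n <= ``exact_max_n``, pair-sampled estimate otherwise."""
    a, b = _check_pair(labels_a, labels_b)
    if a.size <= exact_max_n:
        return ari_exact(a, b)
    return ari_sampled(a, b, n_pairs=n_pairs, rng_seed=rng_seed)
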