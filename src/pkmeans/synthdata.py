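"""Synthetic Gaussian-mixture benchmarks with known cluster structure.

Two named benchmarks emulate the classic demonstrations of per-cluster
variable selection:

* :func:`gen_paired_markers` — 10,000 points in 11 dimensions, 10 spherical
  clusters.  Cluster ``m`` sits at ``delta * (e_m + e_{m+1 mod 10})``, so each
  of the first ten variables separates exactly two clusters, every cluster is
  defined by exactly two variables, and the eleventh variable is pure noise
  that defines nothing.  A per-cluster sparse method should drop nine of the
  eleven variables from every cluster; a global variable selector can drop
  only the eleventh.
* :func:`gen_axis_bivariate` — 2,000 points in 2 dimensions, three clusters:
  two larger ones (40% each) on the coordinate axes at ``(c, 0)`` and
  ``(0, c)`` and a smaller off-axis one (20%) near the origin.  After
  max-density centering each axis cluster needs only one variable to define
  its position; penalty tuning should recover the three-cluster resolution.

All clusters share one spherical standard deviation, and every generator is
deterministic given its seed and returns ground-truth labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import DataMatrix


@dataclass
class MixtureSpec:
    """A mixture of spherical Gaussians with one shared standard deviation."""

    n: int
    centers: np.ndarray  # (n_clusters, d)
    proportions: np.ndarray  # simplex vector, length n_clusters
    sd: float = 1.0
    variable_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.proportions.shape[0] != self.centers.shape[0]:
            raise ValueError("one proportion per cluster required")
        if np.any(self.proportions < 0) or not np.isclose(self.proportions.sum(), 1.0):
            raise ValueError("proportions must be non-negative and sum to 1")

    @property
    def d(self) -> int:
        return self.centers.shape[1]

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def gen_gaussian_mixture(spec: MixtureSpec, seed: int) -> tuple[DataMatrix, np.ndarray]:
    """Draw ``spec.n`` points from the mixture; returns data and true labels."""
    rng = np.random.default_rng(seed)
    labels = rng.choice(spec.n_clusters, size=spec.n, p=spec.proportions)
    values = spec.centers[labels] + spec.sd * rng.standard_normal((spec.n, spec.d))
    names = spec.variable_names or [f"var_{j + 1}" for j in range(spec.d)]
    return DataMatrix(values, names), labels


def gen_paired_markers(
    seed: int, n: int = 10_000, delta: float = 6.0, sd: float = 1.0
) -> tuple[DataMatrix, np.ndarray]:
    """The 11-variate, 10-cluster benchmark with pairwise-shared markers.

    Cluster ``m`` (m = 0..9) is centered at ``delta * (e_m + e_{m+1 mod 10})``
    over the first ten variables; variable 11 is identically distributed
    noise in every cluster.  Clusters are equiprobable.
    """
    centers = np.zeros((10, 11))
    for m in range(10):
        centers[m, m] = delta
        centers[m, (m + 1) % 10] = delta
    spec = MixtureSpec(
        n=n,
        centers=centers,
        proportions=np.full(10, 0.1),
        sd=sd,
    )
    return gen_gaussian_mixture(spec, seed)


def gen_axis_bivariate(
    seed: int, n: int = 2_000, c: float = 6.0, sd: float = 1.0
) -> tuple[DataMatrix, np.ndarray]:
    """The bivariate three-cluster benchmark: axis clusters at ``(c, 0)``
    and ``(0, c)`` (40% each) and a smaller off-axis cluster (20%) at
    ``(0.2c, 0.2c)``.

    The off-axis cluster sits near (not at) the origin so that each
    variable's density mode is anchored at its zero level: the mode of
    variable 1 is the x of the ``(0, c)`` cluster plus the small cluster's
    contribution, and symmetrically for variable 2.  Max-density centering
    therefore leaves the two axis clusters defined by a single variable
    each, the structure this benchmark exists to exhibit; were the modes
    left to a coin flip between the two 40% levels, the origin could land
    on a large cluster and destroy it.
    """
    spec = MixtureSpec(
        n=n,
        centers=np.array([[c, 0.0], [0.0, c], [0.2 * c, 0.2 * c]]),
        proportions=np.array([0.4, 0.4, 0.2]),
        sd=sd,
    )
    return gen_gaussian_mixture(spec, seed)


def gen_three_blobs(
    seed: int, n: int = 600, scale: float = 6.0, sd: float = 1.0
) -> tuple[DataMatrix, np.ndarray]:
    """A generic well-separated 3-blob fixture in 2-D for property tests.

    The geometry is chosen so that after max-density centering the origin
    (the per-variable modes) coincides with no blob center: variable 1's
    mode comes from the two blobs sharing x = scale, variable 2's from the
    heaviest blob at y = 2/3 scale.
    """
    spec = MixtureSpec(
        n=n,
        centers=scale * np.array([[1.0, 0.0], [1.0, 4 / 3], [0.0, 2 / 3]]),
        proportions=np.array([0.3, 0.3, 0.4]),
        sd=sd,
    )
    return gen_gaussian_mixture(spec, seed)
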