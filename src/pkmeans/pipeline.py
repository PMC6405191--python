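"""End-to-end orchestration: preprocess, tune the penalty, cluster, report.

Two routes produce the final partition:

* ``recluster`` (n up to a threshold, default 10^4): the full preprocessed
  dataset is refitted at the selected penalty — rescaled by ``n / N_r`` when
  tuning ran on subsamples — with a generous number of restarts;
* ``allocate`` (larger n): the most generalizable center set already
  produced during tuning at the optimal penalty is reused and every
  observation is simply allocated to its nearest center, avoiding another
  expensive fit.

The result carries, per surviving cluster, the list of *defining* variables:
those whose center coordinate is exactly non-zero in preprocessed space.
Centers are also mapped back to original units; there a zero is not a raw
value but the centering offset, so the non-defining mask travels alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_K,
    DEFAULT_MAX_ITER,
    DEFAULT_N_RUNS,
    DEFAULT_RAMP_STEPS,
    ClusterModel,
    Partition,
    estep_allocate,
    model_score,
    multi_restart_fit,
)
from .matrix import DataMatrix
from .preprocess import PreprocessRecord, preprocess
from .tuning import (
    DEFAULT_INIT_ROUNDS,
    DEFAULT_MAX_ROUNDS,
    DEFAULT_SE_THRESHOLD,
    DEFAULT_TUNING_RESTARTS,
    TuningResult,
    rescale_penalty,
    select_generalizable_centers,
    tune_penalty,
    _derived_seed,
)

DEFAULT_RECLUSTER_THRESHOLD = 10_000


@dataclass
class PipelineResult:
    """Everything the pipeline produced for one dataset."""

    partition: Partition
    model: ClusterModel
    centers_original_units: np.ndarray
    defining_mask: np.ndarray  # (k', d) bool: center coordinate non-zero
    defining_variables: list[list[str]]
    tuning: TuningResult
    preprocess_record: PreprocessRecord
    route: str  # "recluster" | "allocate"
    variable_names: list[str]
    observation_ids: list[str]
    seed: int

    @property
    def n_clusters(self) -> int:
        return self.model.n_clusters


def defining_variables(model: ClusterModel, names: list[str]) -> list[list[str]]:
    """Per cluster, the names of variables with a non-zero center entry
    (the soft-threshold M-step produces exact zeros, so this is an exact
    test)."""
    if len(names) != model.centers.shape[1]:
        raise ValueError(
            f"{len(names)} names for {model.centers.shape[1]} variables"
        )
    names = list(names)
    return [
        [names[j] for j in np.flatnonzero(row != 0)] for row in model.centers
    ]


def cluster_overlap_table(partition, reference_labels) -> pd.DataFrame:
    """Contingency table of percentages: rows are reference classes, columns
    are clusters, each row sums to 100 (percent of the reference class found
    in each cluster)."""
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    ref = np.asarray(reference_labels)
    if labels.shape[0] != ref.shape[0]:
        raise ValueError(
            f"length mismatch: {labels.shape[0]} labels vs {ref.shape[0]} references"
        )
    table = pd.crosstab(pd.Series(ref, name="reference"), pd.Series(labels, name="cluster"))
    return table.div(table.sum(axis=1), axis=0) * 100.0


def run(
    data: DataMatrix,
    *,
    k: int = DEFAULT_K,
    penalties=None,
    N_r: int | None = None,
    init_rounds: int = DEFAULT_INIT_ROUNDS,
    max_rounds: int = DEFAULT_MAX_ROUNDS,
    se_threshold: float = DEFAULT_SE_THRESHOLD,
    n_runs_final: int = DEFAULT_N_RUNS,
    n_restarts_tuning: int = DEFAULT_TUNING_RESTARTS,
    recluster_threshold: int = DEFAULT_RECLUSTER_THRESHOLD,
    log2: str = "auto",
    centering: str = "auto",
    ramp_steps: int = DEFAULT_RAMP_STEPS,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    route: str | None = None,
) -> PipelineResult:
    """Full workflow on a raw data matrix.

    ``route`` forces ``"recluster"`` or ``"allocate"``; by default the
    recluster route is taken when ``n <= recluster_threshold``.
    """
    pp, record = preprocess(data, log2=log2, centering=centering)
    n = pp.n

    tuning = tune_penalty(
        pp.values,
        penalties=penalties,
        N_r=N_r,
        k=k,
        init_rounds=init_rounds,
        max_rounds=max_rounds,
        se_threshold=se_threshold,
        base_seed=seed,
        n_restarts=n_restarts_tuning,
        ramp_steps=ramp_steps,
        max_iter=max_iter,
    )
    lam_opt = tuning.optimal_penalty

    if route is None:
        route = "recluster" if n <= recluster_threshold else "allocate"
    if route not in ("recluster", "allocate"):
        raise ValueError(f"route must be recluster/allocate, got {route!r}")

    if route == "recluster":
        lam_full = rescale_penalty(lam_opt, n, tuning.N_r)
        model, partition = multi_restart_fit(
            pp.values,
            k,
            lam_full,
            n_runs=n_runs_final,
            base_seed=_derived_seed(seed, 9_999),
            ramp_steps=ramp_steps,
            max_iter=max_iter,
        )
    else:
        sets = tuning.center_sets[tuning.optimal_index]
        centers = select_generalizable_centers(
            sets, pp.values, rng_seed=_derived_seed(seed, 8_888)
        )
        partition = estep_allocate(pp.values, centers)
        # drop centers that attract no observation of the full data
        counts = np.bincount(partition.labels, minlength=centers.shape[0])
        keep = counts > 0
        if not keep.all():
            centers = centers[keep]
            partition = Partition(np.cumsum(keep)[partition.labels] - 1)
        model = ClusterModel(
            centers=centers,
            penalty=lam_opt,
            k_requested=k,
            score=model_score(pp.values, partition.labels, centers, lam_opt),
            seed=seed,
        )

    if model.n_clusters < 1:
        raise RuntimeError("no surviving clusters")

    mask = model.centers != 0
    centers_orig = record.inverse(model.centers)
    defs = defining_variables(model, pp.variable_names)
    return PipelineResult(
        partition=partition,
        model=model,
        centers_original_units=centers_orig,
        defining_mask=mask,
        defining_variables=defs,
        tuning=tuning,
        preprocess_record=record,
        route=route,
        variable_names=list(pp.variable_names),
        observation_ids=list(pp.observation_ids),
        seed=seed,
    )
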