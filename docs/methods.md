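# Methods

## Model

`pkmeans` fits a mixture of `k` equal-weight, unit-variance spherical
Gaussians to an `n × d` data matrix by minimizing the penalized k-means
objective

    Q(z, μ) = Σ_m Σ_{l ∈ m} ‖x_l − μ_m‖² + λ Σ_m Σ_j |μ_{m,j}|,

where `z` allocates each observation to one cluster and `μ` holds the `k`
cluster centers. The L1 term penalizes every coordinate of every center
independently. For a fixed allocation the per-coordinate minimizer is the
soft threshold

    μ_{m,j} = sign(a_{m,j}) · max(|a_{m,j}| − λ / (2 n_m), 0),

with `a_{m,j}` the member mean and `n_m` the member count. Coordinates whose
member mean is small relative to the penalty become *exactly* zero; a zero
marks a variable as non-contributing to that cluster's definition. A cluster
whose entire center row is zeroed is eliminated and its members are
reabsorbed at the next allocation step. Because of elimination, the number
of surviving clusters is governed by `λ`, not by the requested `k`, as long
as `k` is generous enough that at least one cluster dies.

Assumptions inherited from the model: clusters are roughly spherical in the
preprocessed space, share a common scale, and are adequately summarized by
their centers. Elongated, heavy-tailed or strongly unbalanced-variance
clusters will be split or blurred, exactly as in ordinary k-means.

### Fitting

Each run seeds `k` centers with vanilla k-means++ (D²-weighted sampling of
data points; the greedy multi-candidate variant is deliberately not used so
that the `k = n` limit is exactly deterministic), then iterates E- and
M-steps. The effective penalty ramps linearly from 0 to `λ` over the first
`ramp_steps` E-steps (default 10) so that a poor initialization is not
massacred by a full-strength penalty before the centers have settled.
Convergence is declared when an E-step at the full penalty changes no label;
`max_iter` (default 100) caps the iteration count, returning the current
state with a warning on the rare non-converged run. The final model is the
best of `n_runs` random restarts by `Q` (21 for the final fit, 2 inside
tuning rounds, both user-settable).

Two tie-breaks are fixed for determinism: nearest-center allocation breaks
distance ties toward the lower center index, and the histogram-mode search
in centering breaks count ties toward the lower bin.

## Penalty selection by resampling stability

The resolution (how many clusters, how many defining variables) is decided
by reproducibility, not by fit. For each candidate penalty on an
exponentially spaced grid, two bootstrap samples of `N_r` observations are
clustered independently; all `n` observations are then allocated to each
center set, and the Adjusted Rand Index (ARI) between the two induced
partitions measures how much of the solution survives resampling. Rounds are
repeated — balanced across penalties — until one of three stopping rules
fires: the best penalty's 2-standard-error interval separates from all
others, its standard error drops below `se_threshold` (default 0.01), or
`max_rounds` (default 100) is reached, with `init_rounds = 20` rounds always
run first. The ARI is computed exactly from the contingency table up to
n = 5000 and estimated from 10^4 random observation pairs above that; the
chance correction gives trivial partitions (everything in one cluster) a
similarity of 0, so degenerate solutions cannot win.

The selected penalty is the argmax of the mean ARI. Two refinements, both
package design choices, deal with situations the basic scheme leaves open:

* **Plateau tie-break.** On clean data several penalties often attain a mean
  ARI of exactly 1.0. Among exactly tied penalties the *largest* is chosen:
  the sparsest model among equally reproducible ones (the same parsimony
  logic as the `lambda.1se` rule in penalized regression). This matters in
  practice because the low end of a reproducibility plateau still carries
  small non-zero center coordinates caused by centering noise (below), while
  the high end thresholds them away without losing reproducibility.

* **Data-driven grid extension with scouting.** The soft threshold is
  `λ/(2 n_m)`, so the penalty equivalent to a given resolution scales with
  the sample size; a fixed default grid (2^0 … 2^5 in half-octave steps)
  cannot cover every dataset. When the running optimum sits on the default
  grid's edge, the grid is extended in half-octave steps (floor 2^-6,
  ceiling 2^14). Because the ARI-vs-penalty curve can dip at a resolution
  change and rise again, an interior argmax does not prove the optimum is
  bracketed: before any stopping decision is accepted, three cheap scout
  rounds are run at 2×…32× the top grid penalty, and the grid is extended
  whenever a scout's mean beats the current maximum. A user-supplied grid is
  never modified; if the optimum still lands on a boundary the result
  carries a warning recommending a wider range. Every (round, penalty) pair
  derives its RNG seed from the base seed and the penalty's position on the
  half-octave lattice, so the whole procedure — including any extensions —
  is reproducible from one seed, and scout rounds are identical to the first
  rounds the penalty would run as a full grid member.

When tuning runs on subsamples (`N_r = min(n, 10^4)` by default), the
penalty appropriate for a final fit on all `n` points is `λ · n / N_r`,
because a cluster's attraction on its center grows with its member count.

### Final model

For `n` up to `recluster_threshold` (default 10^4) the full data are
refitted at the (rescaled) optimal penalty with 21 restarts. For larger `n`
the most *generalizable* center set already produced during tuning is
reused: among the center sets fitted at the optimal penalty, the one whose
induced full-data partition has the highest mean ARI to all the others; all
observations are then allocated to their nearest center. On data where both
routes are feasible they agree to ARI ≥ 0.95 (tested).

## Preprocessing

Order: optional log2 → pooled-SD scaling → centering. All steps are recorded
so centers can be mapped back to original units; in original units a zero is
the centering offset, so the non-defining mask is reported alongside rather
than inferred from values.

* **log2 transform** (`log2(x + 1)`) is applied automatically when the
  kurtosis of all `n·d` entries pooled into one vector exceeds 25 — the
  signature of a few variables whose variance dwarfs the rest, typical of
  raw counts. The pooled kurtosis of comparable-variance data sits near 3; a
  single dominant variable among eleven pushes it to ≈ 3/(1/11) ≈ 33. The
  threshold and the +1 offset are package defaults, overridable
  (`log2 = on/off`).
* **Pooled-SD scaling** divides the whole matrix by one number, the
  population standard deviation (divisor `n·d`) of all entries, making
  penalties comparable across datasets without reweighting variables.
* **Centering** decides what "zero" — and hence sparsity — means. For
  `d < 100`, max-density centering puts each variable's histogram mode at
  zero (`max(n/50, 10)` equal-width bins over the observed range): a zero
  center coordinate then reads "this cluster does not deviate from the most
  common outcome". For `d ≥ 100` the mean is used instead, because in high
  dimension the mode vector can sit far from the center of mass and the
  penalty would distort the clustering. The mode estimate carries sampling
  noise of a few bin widths (~±0.1–0.3 raw units at n = 10^4); this noise
  shifts whole columns slightly off zero and is the main reason small
  spurious center coordinates appear at weak penalties — the plateau
  tie-break above is what removes them.

A cluster genuinely centered at the origin of the preprocessed space cannot
be represented (its center is all zeros, which means elimination); data
where the densest point of every variable coincides with a real cluster
center should be centered with `centering = mean` instead.

## Synthetic benchmarks

Two generators reproduce the structure of the classic demonstrations of
per-cluster variable selection; both return ground-truth labels and are
deterministic given a seed.

* **Paired-marker benchmark** (default n = 10,000, d = 11, 10 equiprobable
  clusters, δ = 6, σ = 1): cluster m sits at δ(e_m + e_{m+1 mod 10}); the
  eleventh variable is pure noise. Every cluster is defined by exactly two
  variables, each informative variable separates exactly two clusters, and a
  per-cluster selector should discard nine variables per cluster — a global
  selector can discard only one. δ/σ = 6 puts the Bayes error near zero.
* **Axis benchmark** (default n = 2,000, c = 6, σ = 1): clusters at (c, 0)
  and (0, c) with weight 0.4 each and a smaller cluster (0.2) at
  (0.2c, 0.2c). The small cluster near the origin anchors each variable's
  density mode at its zero level, so max-density centering leaves the two
  large clusters defined by one variable each — the structure the benchmark
  exists to exhibit. (With the small cluster far from both axes the two 40%
  clusters tie for the mode and the origin can land on one of them, which
  the model cannot represent.)
* A generic three-blob fixture backs the property tests (k-independence of
  the surviving cluster count, route agreement); its geometry keeps the
  centered origin away from every blob center.

What these fixtures do *not* emulate: measurement noise models of real
single-cell data (zero inflation, overdispersion, batch effects), unequal
cluster variances, or correlated variables. Passing tests demonstrate the
estimator's correctness and the resolution-selection logic, not robustness
to those real-data complications.

## Numerical choices and degenerate inputs

* Distances in the inner loop use the expanded form `‖c‖² − 2x·c` (the
  `‖x‖²` term is constant under argmin); the public allocation routine uses
  exact squared distances so the documented tie-break holds exactly.
* Exact zeros from the soft threshold are preserved end-to-end; the
  defining-variable report tests `μ ≠ 0` exactly, never against a tolerance.
* Constant data (zero pooled SD), penalties that eliminate every cluster,
  empty center sets, ragged input files and mismatched label lengths raise
  errors; a stability round whose fit loses every cluster scores ARI 0 with
  a warning rather than aborting the scan.
* All randomness flows through explicit integer seeds; restart r uses
  `base_seed + r`; tuning derives per-round seeds via `SeedSequence` from
  `(base_seed, round, penalty-lattice-index)`.

## Problem sizes used in the shipped tests

The acceptance-style tests run the full pipeline at the benchmarks' native
sizes (n = 10^4 × 5 seeds for sparse recovery, ≈ 2.5–3 min per seed on one
core; n = 2000 × 5 seeds for resolution selection, ≈ 0.5–2 min per seed).
Unit and property tests use n = 150–600 fixtures chosen to exercise the same
code paths in seconds. `scripts/acceptance.py` reproduces the resolution-
selection experiment (5 replicate datasets at n = 2000) from a single seed.

## Known limitations

* The stability criterion prefers the most reproducible resolution; a
  coarser-than-truth solution that is perfectly reproducible can in
  principle outscore the true one (stability is necessary, not sufficient,
  for correctness).
* Max-density centering is only as good as the histogram mode estimate;
  with `n/50` bins the origin can wander a few bin widths, and for
  multimodal variables with near-tied modes the centered origin can jump
  between runs on different data samples of the same source.
* Tuning cost scales with `N_λ × rounds × N_r`; the defaults keep n = 10^4
  tractable on one core but the scheme is embarrassingly parallel across
  rounds if needed (runs are seeded independently).
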