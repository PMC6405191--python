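# pkmeans — penalized k-means with sparse cluster centers

`pkmeans` clusters large single-cell datasets — mass-cytometry marker tables,
scRNA-seq expression matrices, or any observations-by-variables matrix — while
simultaneously deciding, *per cluster*, which variables actually define that
cluster. It is aimed at analysts who want cluster phenotypes they can read:
each cluster comes with a short list of defining markers instead of a dense
centroid over thousands of variables.

## The method

Standard k-means minimizes the within-cluster sum of squares. `pkmeans` adds
an L1 penalty on every coordinate of every cluster center:

    Q(z, μ) = Σ_m Σ_{l∈m} ‖x_l − μ_m‖² + λ Σ_{m,j} |μ_{m,j}|

The M-step becomes a soft threshold, μ_{m,j} = sign(a)·max(|a| − λ/(2n_m), 0)
for member mean `a` and member count `n_m`, which drives uninformative
coordinates to exactly zero — and different clusters may keep different
variables. Clusters whose whole center hits the origin are eliminated, so the
penalty λ, not the requested k, controls how many clusters survive.

λ itself is tuned automatically: for each candidate penalty, pairs of
bootstrap resamples are clustered independently and compared with the
Adjusted Rand Index (ARI); the most *reproducible* resolution wins. The
candidate grid starts at 2^0…2^5 and extends itself (with cheap look-ahead
"scout" rounds) when the data ask for penalties outside it. See
`docs/methods.md` for the full model, the stopping rules, and the design
choices.

## Worked example

Generate the bivariate three-cluster benchmark (two 800-point clusters on
the coordinate axes, one 400-point cluster near the origin) and cluster it:

```sh
$ pkmeans simulate axis2d --seed 7 -o benchmark.csv
INFO wrote benchmark.csv (2000 x 2) and truth labels
$ pkmeans cluster benchmark.csv --seed 7 -o results
INFO read 2000 observations x 2 variables
INFO penalty grid scan:
   penalty  mean_ari   se_ari  rounds  optimal
  1.000000  0.484030 0.010486      20    False
  2.000000  0.500767 0.008736      20    False
  ...
 32.000000  0.806911 0.023058      20    False
 64.000000  0.970782 0.005829      20    False
128.000000  0.997091 0.000646      20    False
181.019336  0.997477 0.000445      20     True
256.000000  0.796110 0.035420      20    False
INFO route: recluster
INFO selected penalty 181 -> 3 clusters
```

Reading the scan: at weak penalties (λ ≤ 32) the fits keep many spurious
clusters whose boundaries move from resample to resample, so the mean ARI
hovers near 0.5–0.8. Around λ ≈ 128–181 the solutions collapse to the three
real clusters and become almost perfectly reproducible (ARI ≈ 0.997). By
λ = 256 the penalty begins to destroy real structure and reproducibility
drops again. The tuner picks λ ≈ 181, refits the full data with 21 restarts
(`route: recluster`; for n > 10^4 it would instead reuse the most
generalizable centers from tuning), and reports three clusters.

The center table shows per-cluster sparsity — an empty cell means "this
variable does not help define this cluster":

```
$ head -3 results/centers.tsv
cluster	var_1	var_2
0		1.7795990883980863
1	1.8847416115111715	-0.002516030676313036
```

Cluster 0 is the cluster on the y-axis: it deviates from the data's densest
point only in `var_2`, so one variable suffices to define it. `summary.json`
records the seed, the selected penalty, the route taken and the
defining-variable lists; `assignments.tsv` holds the partition.

The same pipeline is available as a library:

```python
from pkmeans import run
from pkmeans.synthdata import gen_axis_bivariate

data, truth = gen_axis_bivariate(seed=7)
result = run(data, seed=7)
result.n_clusters            # 3
result.defining_variables    # [['var_2'], ['var_1', 'var_2'], ['var_1', 'var_2']]
```

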