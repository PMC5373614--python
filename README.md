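# elnnpaired

Empirical-Bayes classification of gene probes from **paired/matched
designs** (tumor vs adjacent tissue, before vs after treatment, matched
case–control) into over-expressed (OE), under-expressed (UE) and
non-differentially-expressed (NE) clusters.

Instead of running one hypothesis test per gene and correcting for
multiplicity, the package fits a single three-component mixture of
conjugate normal–gamma hierarchies to the within-pair log2 differences
`d_gl = log2 y_gl − log2 x_gl`:

    cluster c ∈ {OE, UE}:  d_gl | μ_g, τ_g ~ N(μ_g, 1/τ_g),
                           μ_g | τ_g ~ N(μ_c, k_c/τ_g),
                           τ_g ~ Gamma(α_c, rate β_c)
    cluster NE:            μ_g = 0

with `μ_1 > 0 > μ_2`, `0 < k_c < 1`, and mode-of-precision constraints
`α_c > 1 + β_c((c − √k_c z)/μ_c)²` that keep "over-expressed" genes
genuinely positive.  A generalized EM algorithm with a Dirichlet(2)-MAP
update for the mixing proportions estimates everything on an unconstrained
reparameterized scale; genes take their maximum-posterior cluster.
Because the few hyper-parameters are shared across all genes, the method
borrows strength genome-wide and behaves well at small pair counts.

The package also ships both simulation designs used to benchmark the
method (the hierarchical generator at hyper-parameters estimated from the
GSE43292 carotid-atheroma dataset, and a simple three-normal design), the
pair-counting agreement indices (Rand, Hubert–Arabie and Morey–Agresti
adjusted Rand, Fowlkes–Mallows, Jaccard), the DE/NE error rates (FPR, FNR,
FDR, FNDR), and a paired-t + Benjamini–Hochberg baseline classifier.

## Worked example

```sh
$ elnnpaired simulate --scenario G --genes 1000 --pairs 30 --seed 1 --out-prefix demo
wrote demo_data.tsv and demo_truth.tsv
$ elnnpaired fit --matrix demo_data.tsv --seed 1 --out-prefix demo
converged=True after 6 iterations; labels: {'NE': 854, 'OE': 79, 'UE': 67}
$ elnnpaired evaluate --truth demo_truth.tsv --labels demo_results.tsv --out demo_metrics.tsv
Rand    0.996272
HA      0.990355
MA      0.990358
FM      0.997477
Jaccard 0.994963
FPR     0
FNR     0.0135135
FDR     0
FNDR    0.00234192
```

`fit` writes per-gene posterior probabilities and labels
(`demo_results.tsv`), the fitted model (`demo_model.txt`, 15 significant
digits) and a weighted one-dimensional density grid (`demo_density.tsv`)
for plotting the fitted mixture.  Here 79 + 67 of 1000 simulated genes are
called differentially expressed; agreement with the simulation truth is
near-perfect (Rand 0.996, Jaccard 0.995) with no false discoveries and a
false negative rate of 1.4%.  The same fit is available in Python:

```python
from elnnpaired import FitConfig, fit, simulate_elnn

d, truth = simulate_elnn(1000, 30, seed=1)
result = fit(d, FitConfig(seed=1))
result.model.pi        # estimated cluster proportions
result.labels          # per-gene OE / UE / NE
```

Real data enter either as a differences matrix (`fit --matrix diffs.tsv`)
or as an expression matrix plus a pairing map
(`fit --matrix expr.tsv --pairing pairs.tsv`), where the pairing file has
columns `pair_id`, `case_col`, `control_col`; raw-scale intensities are
log2-transformed automatically (override with `--scale`).

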