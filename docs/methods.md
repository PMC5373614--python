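# Methods

## Model

`elnnpaired` classifies gene probes measured under a paired/matched design
into three clusters — over-expressed (OE), under-expressed (UE) and
non-differentially expressed (NE) — by fitting a three-component mixture of
conjugate Bayesian hierarchies to the within-pair log2 differences
`d_gl = log2 y_gl − log2 x_gl` (case minus control for gene `g`, pair `l`).

For a gene in cluster `c ∈ {1, 2}` (OE, UE):

    d_gl | μ_g, τ_g ~ N(μ_g, 1/τ_g)
    μ_g | τ_g       ~ N(μ_c, k_c/τ_g)
    τ_g             ~ Gamma(α_c, rate β_c)

with `μ_1 > 0`, `μ_2 < 0` and `0 < k_c < 1` (gene means vary less than the
observations).  NE genes have `μ_g ≡ 0` and `τ_g ~ Gamma(α_3, β_3)`.  All
gamma distributions are shape/RATE; a shape/scale slip silently rescales
every variance, so the simulator's docstring calls this out and the
moment test `E[1/τ] = β_3/(α_3 − 1)` would catch it.

Conjugacy gives a closed-form marginal per cluster,

    log f_c(d_g) = −(n/2) log 2π − ½ log(1 + n k_c)
                   + log Γ(α_c + n/2) − log Γ(α_c)
                   + α_c log β_c − (α_c + n/2) log(β_c + Q_c/2),
    Q_c = Σ_l (d_gl − μ_c)² − k_c/(1 + n k_c) · (Σ_l (d_gl − μ_c))²,

the `k = 0, μ = 0` case serving cluster 3.  These forms were derived by
integrating the gene mean and then the precision out of the joint, and the
test suite validates them against nested adaptive quadrature of the raw
hierarchy (50 random parameter draws, 1e-5 relative tolerance) so the
closed form can never silently drift from the generative model.  Densities
are only ever handled in log space: with `n` in the hundreds an un-logged
marginal underflows double precision.

## Constraints and reparameterization

To keep OE genes genuinely positive without abandoning conjugacy, the
precision mode `(α_c − 1)/β_c` must be large enough that a cluster-1 gene's
standardized mean exceeds the upper normal percentile:

    α_1 > 1 + β_1 ((c_1 − √k_1 · Φ⁻¹(p_lo)) / μ_1)²,
    α_2 > 1 + β_2 ((c_2 − √k_2 · Φ⁻¹(p_hi)) / μ_2)²,

with `c_1 = Φ⁻¹(p_hi)`, `c_2 = Φ⁻¹(p_lo)`.  The percentiles default to
0.95/0.05 and are exposed in the fit config (`p_hi`, `p_lo`) so a stricter
setting such as 0.975/0.025 can be used; no adaptive tightening loop is
implemented.

Estimation works on an unconstrained 10-vector
`θ = (δ_1, ξ_1, λ_1, ν_1, δ_2, ξ_2, λ_2, ν_2, λ_3, ν_3)`:

    μ_1 = exp(δ_1)   k_1 = Φ(ξ_1)   β_1 = exp(ν_1)
    α_1 = exp(λ_1) + 1 + β_1 ((c_1 − √k_1 Φ⁻¹(p_lo))/μ_1)²

(mirrored for cluster 2 with `μ_2 = −exp(δ_2)`; `α_3 = exp(λ_3)`,
`β_3 = exp(ν_3)`).  Every real `θ` maps to a strictly feasible model, so
the optimizer never needs explicit constraint handling; the inverse map is
exact and raises a named error on the constraint boundary (where
`λ = log 0`).

A documented quirk: the shipped simulation defaults — the hyper-parameters
estimated from the GSE43292 carotid-atheroma dataset, printed to three
decimals — sit a hair *below* the α bounds (slacks ≈ −0.010 and −0.007),
presumably rounding of the published estimates.  The simulator therefore
only warns about infeasible generating values instead of refusing them,
and nothing asserts feasibility of those constants.

## EM estimation

The mixing proportions carry a symmetric Dirichlet(b) prior, `b = 2` by
default (any `b > 1` puts the prior mode at equal proportions).  One sweep:

* **E-step** — responsibilities `z̃_gc ∝ π_c f_c(d_g)` via log-sum-exp.
* **π update** — closed-form Dirichlet-MAP,
  `π_c = (Σ_g z̃_gc + b − 1)/(G + 3(b − 1))`; the `b − 1` pseudo-counts
  floor each proportion at `1/(G + 3)` and keep empty clusters alive.
* **ψ update** — L-BFGS-B with finite-difference gradients on θ for the
  weighted-density part of the expected complete-data objective.  This is
  a *generalized* EM: ascent is enforced (one seeded random restart if the
  line search stalls, and θ is returned unchanged if nothing improves),
  exact maximization is not claimed.  π and ψ are updated coordinate-wise
  — π has a closed form, so joint numerical optimization would only add
  dimensions.

The observed-data log posterior (mixture log-likelihood plus Dirichlet
terms) is recorded every iteration and is non-decreasing up to 1e-6 by the
GEM argument; the test suite asserts this on twenty seeded fits.  The loop
stops when the max-abs change of the stacked `(θ, π)` vector falls below
`tol = 1e-3` (dimensionless on the unconstrained scale) or after
`max_iter = 100` sweeps.  Genes take the arg-max-responsibility label;
exact posterior ties resolve to NE, the conservative direction for
discovery.

**Initialization** is deterministic: per-gene t statistics
`t_g = m_g/(s_g/√n)` cut at the 5th/95th standard-normal percentiles give
provisional OE/UE/NE labels; cluster-wise method-of-moments on the gene
means `m_g` and precision proxies `1/s_g²` yields
`μ_c = mean(m_g)`, `k_c = clip(var(m_g)·median(1/s_g²), 1e-4, 0.99)`,
`(α_c, β_c) = (mean²/var, mean/var)` of `1/s_g²`; α values are lifted to a
slack of at least 0.05 above their bound before inverting to θ.  A
provisional cluster with fewer than three genes falls back to global
moments with a fixed ±0.5 mean offset (logged).  On data from the
hierarchical generator these starting labels already agree with truth at
Rand > 0.9, so EM typically converges in well under ten sweeps.

## Simulation designs

`simulate_elnn` draws from the model itself.  Its defaults are the
GSE43292-derived values μ1 = 0.441, k1 = 0.118, α1 = 1.718, β1 = 0.029,
μ2 = −0.442, k2 = 0.079, α2 = 1.766, β2 = 0.034, α3 = 2.138, β3 = 0.131,
π = (0.086, 0.071, 0.843) — the G30/G100 scenarios use these at 1000 genes
and 30/100 pairs.  `simulate_simple` is deliberately misspecified relative
to the model: plain normals `N(±2, 1)` for DE genes and `N(0, 4)` for NE,
5% OE and 5% UE (the S30/S100 scenarios).  Cluster membership is a
categorical draw per gene, so DE counts fluctuate binomially around their
expectations.

What the generators do *not* emulate: probe–probe correlation, array-level
batch effects, raw two-channel intensities, missing values, or outliers.
Passing the replicate tests therefore demonstrates correctness of the
estimator under its own assumptions (and mild misspecification via the S
design), not robustness to the full messiness of real microarray data.

## Evaluation

Pair-counting agreement between true and estimated partitions: Rand,
Jaccard, Fowlkes–Mallows, and two chance-corrected Rand variants —
Hubert–Arabie (hypergeometric null given both margins; cross-checked
against scikit-learn's adjusted Rand) and Morey–Agresti (multinomial null,
`E[Σ n_ij²] = Σ_i a_i² Σ_j b_j² / G²`).  On partitions like these
scenarios the two corrections coincide to three decimals, which the
replicate tables confirm.  Error rates collapse to DE-vs-NE: FPR, FNR,
FDR, FNDR as fractions of truly-NE, truly-DE, detected-DE and detected-NE
genes respectively; an empty reference set yields 0 (the natural reading
of "percentage of ... among" an empty set).  Perfectly identical
partitions return 1 for every index even when the chance-corrected
denominators vanish.

The bundled frequentist comparator is a per-gene one-sample t test with
Benjamini–Hochberg adjustment at level 0.05, signed by the gene mean.

## Problem sizes and numerics

The replicate experiments use 25 replicates of 1000 genes × 30 pairs per
scenario — enough that the replicate mean of each index has a Monte-Carlo
standard error of at most ~0.002 given the published per-replicate spreads
— and the large-sample recovery check uses one dataset of 10000 genes ×
100 pairs.  A single G30 fit takes well under a second.  Degenerate inputs
are rejected early (single-pair matrices, non-finite values, constant rows
in tiny datasets); optimizer excursions to non-finite parameter images are
penalized rather than fatal.  Per-replicate seeds are spawned from one
root seed via `numpy.random.SeedSequence`, so every number the package
reports is reproducible from a single integer.

## Limitations

* Genes are assumed independent; correlated probes would understate
  uncertainty and the fitted proportions inherit that bias.
* The M-step is a local quasi-Newton improvement from a moment-based
  start; a pathological initialization could converge to a poor local
  optimum (not observed on the tested designs).
* The constraint percentiles are fixed per fit; choosing them by
  comparison with an external method is out of scope.
* Real-data preprocessing (normalization, QC, probe filtering) is the
  caller's responsibility; the reader only distinguishes raw from log2
  intensity scales by a simple magnitude heuristic, overridable with
  `--scale`.
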