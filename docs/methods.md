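# Methods

## Model and estimation

All four pipelines are instances of one multi-block Bayesian ridge
model,

```
y = μ1 + Σ_b W_b β_b + ε,   β_b ~ N(0, σ²_b I),   ε ~ N(0, σ²_ε I),
```

with a flat prior on μ and scaled-inverse-χ² hyperpriors on every
variance. A design block `W_b` is an eigen-projection of a kernel (so
`W_b β_b` is a genetic effect with covariance `σ²_b W_b W_b′`), an
environment incidence matrix, or in principle raw markers. Estimation
is a conjugate Gibbs sampler; missing phenotypes are treated as unknowns
and redrawn from their predictive conditional every sweep, which is how
test-set predictions are produced (their retained-sweep averages are the
reported predictions).

**Transductive convention.** Kernels, Nyström blocks and projection
bases are built over *all* observations — training and test — and test
phenotypes are masked. Marker-centering statistics likewise use all
lines. This makes the Nyström blocks exact sub-blocks of the full-data
kernel (required for the block identities) and gives test rows a basis
representation without a separate out-of-sample formula. Inducing lines,
by contrast, are always drawn from the training set only.

**Prior calibration.** Every variance gets df = 5. With no user-supplied
scale, the residual prior mode is (1 − R²)·var(y) and each block's prior
mode contributes R²·var(y)/B on the phenotype scale (B = number of
blocks, R² = 0.5), converting between coefficient scale and phenotype
scale through msx_b = mean diagonal of `W_b W_b′`. These are the common
defaults of genomic-prediction Gibbs engines. Setting an explicit scale
together with a huge df (e.g. 1e8) acts as a point mass and is how the
sampler is checked against the closed-form BLUP. Phenotypes are not
standardized unless `standardize_y` is set; with it, metrics and
variance components are reported back on the raw scale.

**Sampler numerics.** Each block's design is rotated once into the
eigenbasis of its Gram matrix `W′W`; the iid normal prior is rotation
invariant, so every coefficient full conditional becomes diagonal and a
sweep costs two matrix-vector products per block with no per-sweep
decompositions. Coefficients are therefore effectively drawn jointly
per block (better mixing than scalar updates), and summaries are rotated
back. The residual-variance update uses all n residuals of the
augmented model (imputed rows included), the standard data-augmentation
scheme.

## Kernels and the Nyström approximation

* Linear (GBLUP) kernel `K = X_c X_c′/p`; markers are column-centered by
  default and not scaled. Centering is the standard GBLUP convention
  and gives the expected rank min(n−1, p); both are config flags.
* Gaussian kernel `exp(−h d²/q)` with q the 50th percentile of the
  off-diagonal squared Euclidean distances by default (5th percentile is
  the other convention in use; configurable). In the Nyström path q is
  taken from the n × m cross-distance block excluding self pairs, since
  the full off-diagonal set would require the n × n matrix the path
  exists to avoid.
* `K_mm` is never hard-inverted: all pseudo-inverses and bases go
  through a truncated eigendecomposition with relative tolerance 1e-10,
  because randomly selected inducing lines can be near-duplicates.
  Round-off negatives are clipped to zero before any S^{±1/2}.
* The approximate basis `P = K_nm U_mm S_mm^{−1/2}` satisfies `PP′ = Q`
  exactly; when rank(K_mm) = rank(K) (always when m ≥ rank K), Q = K and
  the approximate fit is the full fit up to a basis rotation.
* For G×E, the interaction blocks are Hadamard masks of the main-effect
  blocks: `GE_nm = G_nm # M_nm`, `M = Z_e E Z_e′` restricted to the
  relevant rows/columns. E defaults to the identity; a user-supplied E
  is validated symmetric PSD. Inducing selection for APGE is stratified
  by environment (equal quota per environment, remainder to the largest
  strata) so every environment's interaction effects are representable;
  an environment with no inducing lines under E = I triggers a warning
  because its interaction effects then have no basis support. The same
  inducing set drives both the main and the interaction basis.
* φ(m) is computed from the full kernel's spectrum and is therefore
  only reported when that spectrum is affordable (n below the full-path
  cap); full-kernel pipelines refuse n > 15,000 unless forced, since
  that regime is what the approximation is for.

## Synthetic data

The generator draws exactly from the generative model: dosages
Binomial(2, q_j) with q_j uniform on the allele-frequency range
(default 0.05–0.95); genetic effects from N(0, σ²_g G̃) with G̃ the
marker kernel normalized to unit mean diagonal, so σ²_g is the average
genetic variance and h² = σ²_g/(σ²_g + σ²_ε) holds by construction;
interaction effects drawn per environment (E = I) from the within-
environment kernel; environment effects as a single N(0, σ²_e) value
per environment; residuals iid. The row-exact decomposition
y = μ + e + g + ge + ε is stored.

Eigen-decay is controlled by `decay_blocks`: b independent founder
markers copied (with 5% per-entry resampling) across the panel
concentrate the kernel spectrum on ~b directions. This provides both
regimes that matter for the approximation — fast decay, where few
inducing lines suffice, and flat-within-rank spectra, where φ(m)
overstates what m random lines capture.

What the generator does *not* emulate: linkage-disequilibrium structure
from real pedigrees or coalescent histories, dominance/epistasis,
environmental covariates, and heterogeneous residual variances. Passing
tests therefore demonstrate correctness of the algebra and calibration
of the estimation machinery under the stated model, not performance on
any particular real population.

Named fixtures: `tiny` (30 shared lines × 2 environments, p = 20),
`small` (200 shared lines × 3 environments, p = 500, decay_blocks = 40,
σ²_g = σ²_ge = σ²_ε = 1, σ²_e = 0.5), `medium` (3 × 1000 disjoint lines,
p = 1000).

## Study sizes, chain lengths and declared tolerances

Default chain settings are 20,000 sweeps, 3,000 burn-in, thinning 2.
The validation experiments use sizes chosen so each answers its question
with comfortable statistical margin: the sampler-vs-BLUP check runs the
full default chain at n = 200; heritability recovery uses n = 1000,
p = 500 with 6,000-sweep chains (variance posteriors are tight long
before the default length at these sizes); the φ-rule sweep uses
n = 600, p = 50 with decay_blocks = 25, five data seeds and four 80/20
partitions per seed with 3,000-sweep chains.

Two comparison resolutions are declared up front for paired CV means:
0.005 on a correlation and 0.01 on a residual variance. They matter
because, with p = 50, every m at or above the kernel rank yields the
*same* model up to rotation, so the accuracy sweep compares quantities
that are exactly tied in expectation and differ only by Monte-Carlo
noise; monotonicity assertions are made up to these resolutions.

All randomness flows from one user seed through named derived streams
(selection, partitions, sampler, simulator), so any component can be
reproduced in isolation; identical seeds give bit-identical chains.

## Design choices where the design was open

* **Centering for Nyström blocks** uses statistics from all n lines, not
  the m inducing lines — the only convention under which the blocks are
  exact sub-blocks of the full-data kernel.
* **Interaction blocks as Hadamard masks of the G blocks** — the only
  construction consistent with the dense interaction covariance
  GE = G # Z_e E Z_e′.
* **Independent 80/20 splits** rather than k-fold; splitting is over
  observations by default, with a line-level option for data sets where
  the same lines appear in every environment.
* **Blocked (rotated-basis) coefficient updates** rather than scalar
  sweeps: identical posterior, better mixing, and the rotation makes the
  per-sweep cost linear in the design size.
* **`predict` is a lookup into a transductive fit**: target rows must be
  present (masked) at fit time. A true out-of-sample path would need
  kernel rows for unseen lines against the training set; it is not
  offered because the transductive route is how the masked-row
  predictive means are defined here.

## Limitations

* Single trait, Gaussian likelihood, homogeneous residual variance.
* Inducing lines are selected uniformly at random (optionally
  stratified); no optimized or variational selection of the subset, and
  no diagonal (FITC-style) correction of the Nyström kernel.
* The Gaussian-kernel bandwidth is user-set, not estimated.
* φ requires the full spectrum, so it is a validation-scale diagnostic,
  not something computable in the very regime where the approximation is
  most needed.
* Chain diagnostics (ESS, split-R̂ via arviz) are computed from a single
  chain split in half; multi-chain R̂ is not run by default.
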