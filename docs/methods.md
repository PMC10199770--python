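# Methods

## Mixture model and purity estimation

A serum-exosome miRNA profile of a cancer patient is modelled as a
two-source mixture: exosomes shed by tumour cells and exosomes shed by
healthy cells. Over a set of m signature miRNAs, the observed CPM profile
T satisfies

    T = E α + ε,      α ≥ 0,  α₁ + α₂ = 1,

where E (m × 2) holds the mean CPM of each signature miRNA in
cancer-cell-derived and healthy-cell-derived exosomes, and α₁ is the tumour
purity. The estimate minimizes ‖Eα − T‖² over the probability simplex.

The quadratic program (Hessian EᵀE, linear term −EᵀT, one equality and two
bound constraints) is solved exactly by enumerating the active sets of the
KKT system; with two components there are three candidate sets and the
unique optimum is the first primal- and dual-feasible candidate. Numerical
guards:

- if cond(EᵀE) > 1e12, a ridge term 1e-10·I is added before solving;
- components within 1e-10 below zero are clamped to 0 and the pair is
  renormalized to sum exactly 1;
- E columns that are exactly identical are rejected as unidentifiable.

For two components the solution has the closed form
α₁ = clip((E₁−E₂)ᵀ(T−E₂) / ‖E₁−E₂‖², 0, 1), which is kept as an
independent reference: the test suite requires QP = closed form to 1e-6 and
QP = a 1e-4-step grid search to 1e-3 on random noisy instances.

Deliberate choices: the model is solved on the linear CPM scale (the
mixture is linear in expression), and T is **not** re-normalized to the
signature subset before solving — purity is a property of the full library,
and rescaling T rescales the residual without changing the constrained
minimizer's interpretation. Multiplying T and both columns of E by a common
positive factor leaves α unchanged (scale equivariance, tested).

## Signature selection

A signature miRNA must separate the two exosome sources and be stable
within each source.

1. **Differential expression**: per-miRNA negative-binomial Wald test of
   cancer vs healthy on raw counts — median-of-ratios size factors,
   per-miRNA method-of-moments dispersion (pooled within-group variance of
   normalized counts, Poisson component removed, floored at 1e-8), NB GLM
   with a group indicator and log size-factor offset, Wald p-value on the
   group coefficient against the standard normal, BH-adjusted FDR. This is
   a transparent stand-in for DESeq2 without dispersion shrinkage or LFC
   moderation; a precomputed DE table can be supplied to reproduce
   DESeq2-exact signatures. Under a null NB simulation (2000 miRNAs, 20+20
   samples) the empirical type-I error at nominal 0.05 is ≈ 0.055, inside
   the accepted [0.03, 0.07] band.
2. **Thresholds**: |log2FC| > 1 and FDR < 0.01, both strict; miRNAs exactly
   at a threshold are excluded.
3. **Stability**: within-group variance of log2(CPM+1) strictly below 2 in
   *both* groups (sample variance, ddof = 1). The threshold is only
   meaningful on the log scale — raw-CPM variance of an expressed miRNA is
   essentially never below 2 — so the log2(CPM+1) scale is fixed and
   exposed as a parameter.

E is the arithmetic mean CPM per group over the selected miRNAs. The
**pan-cancer** signature keeps miRNAs present in strictly more than five
per-cancer signatures (so at least six) and averages their per-cancer E
rows unweighted over the cancers that carry them; an abundance-weighted
average would bias E toward deeply sequenced cohorts.

## Tumour/normal classification

Healthy-derived samples are deconvolved with the same signature and their
predicted purities form the empirical null H₀. For an observed purity t,

    p = (1 + #{null ≥ t}) / (1 + n),

the add-one permutation-style estimator, so p is never exactly 0 and a
sample can only be called tumour when the null is large enough
(n ≥ 19 at the default threshold 0.05). Nulls below 10 values are rejected,
below 20 a warning is issued.

## Simulation

`simulate_cohort` builds a mixture at purity x as x·cancer + (1−x)·healthy
on the CPM scale and then adds i.i.d. Gaussian(0, σ²) noise, truncating
negatives at 0 (the deconvolution requires T ≥ 0; the truncation bias is
negligible for signature miRNAs, whose CPM is large relative to the
benchmark σ ≤ 9). Two source modes exist:

- `"mean"` (default, the benchmark design): mix the group mean profiles —
  "the expression profile of the cancer cell line" as a cohort-level
  quantity. This isolates the deconvolution error itself and reproduces the
  near-perfect noiseless recovery the model is capable of.
- `"sample"`: draw one random cancer and one random healthy source column
  per mixture. This additionally propagates biological sample-to-sample
  variability into the mixture; with the default NB dispersion of 0.05 it
  caps the purity-recovery correlation around 0.91–0.98, which measures the
  generative spread of the sources, not the estimator.

`synthetic_cohort` emulates a cancer-line / healthy-control cohort:
baseline per-miRNA mean CPM log-uniform over 1–10⁴ (the dynamic range of a
typical small-RNA library), planted fold changes with random sign on a
random subset of miRNAs, counts NB(mean = cpm/10⁶ × library size,
dispersion). Defaults — 500 miRNAs, 30 planted at |log2FC| = 3, dispersion
0.05, 20+20 samples, 5·10⁶ reads — describe a modest cell-line exosome
study; the dispersion corresponds to a within-group CV of ≈ 22%, consistent
with cultured-cell replicates (patient serum would be more dispersed).
A `world_seed` separates the generative world (baselines, planted effects)
from the sampling noise, so independent cohorts from one world support
train/validation protocols. `synthetic_pan_cancer` draws one global
baseline and a shared differential core (common fold changes across
types — the pan-cancer signal) plus per-type private differential miRNAs.

What a green benchmark does and does not establish: the generator plants
group-stable, strongly separated signature miRNAs and library sizes without
batch effects, so near-perfect recovery certifies the estimator and the
pipeline plumbing, not performance on real serum data with heterogeneous
subpopulations, batch structure, or signatures that transfer imperfectly
from cell lines to serum.

## Purity-corrected differential expression

For miRNA i, expression in a patient sample with purity λ is modelled as
baseline plus a purity-scaled tumour shift:

    Z = m_i + λ μ_i + ε.

Stacking healthy samples (rows [1, 0]) and patients (rows [1, λⱼ]) gives
Z = Wβ + ε with β = (m, μ). The fit is feasible generalized least squares
with a diagonal covariance holding one variance per group (healthy /
tumour), estimated from the residuals of an initial OLS fit — a single
re-weighting pass; `--ols` disables the weighting. The two-group
heteroscedastic Σ reflects the model's own asymmetry (patient expression
variance includes the tumour-shift component, so the groups need not share
a variance), with no further structure assumed. μ = 0 is Wald-tested
against the standard normal — appropriate for the target regime of ≥ 30
samples per group — and p-values are BH-adjusted across miRNAs.

Choices worth stating:

- Z is log2(CPM+1): it makes μ directly a log2 fold change and stabilizes
  the variance; the additive mixture is then approximate rather than exact,
  a standard trade against the heavy right tail of linear CPM.
- The corrected fold change is defined as μ̂ itself — the effect
  extrapolated to purity 1 — since a "fold change at observed purity" would
  depend on each cohort's purity distribution.
- Significance: FDR < 0.05 and |log2FC| > 1, strict.
- λ may come from the deconvolution or be supplied externally; the design
  only requires λ ∈ [0, 1] with at least one λ > 0 (rank 2).

Calibration and recovery are tested: type-I error in [0.03, 0.07] at
nominal 0.05 over 2000 null features, planted μ = 2 recovered within ±0.15
in the mean over 200 replicates, and at low purity (λ ≈ 0.3) the corrected
test recovers planted effects that an uncorrected two-group test misses.

## Evaluation protocols

The recovery benchmark simulates the purity grid at each noise level,
deconvolves, and reports Pearson r and MAE against the planted purities.
Cohort splitting for cross-validation is stratified by group (and cancer
type when present): one of five parts held out, the rest folded three
ways; the paper-style protocol builds the signature on training folds and
validates purity on the remainder. Precision, recall, specificity and F1
are computed with undefined ratios reported as NaN, never coerced to 0.

## Known limitations

- Strictly two mixture components; exosome subpopulations, batch effects
  and biogenesis are out of scope.
- The NB test is unshrunk; at very small n per group DESeq2's moderation
  would be more powerful (the pluggable DE-table input exists for this).
- The empirical p-value resolution is 1/(n+1); small healthy cohorts bound
  the achievable significance.
- The Wald normal reference (both tests) is a large-sample approximation.
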