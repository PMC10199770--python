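# exopurity

Tumour purity deconvolution for serum-exosome miRNA-Seq data.

Liquid biopsies of cancer patients contain a mixture of exosomes shed by
tumour cells and by healthy cells. The fraction of tumour-derived exosomes —
the **tumour purity** of the sample — matters twice: it is itself a
non-invasive readout of disease burden (including at low purity, the early
diagnosis regime), and leaving it uncorrected biases differential expression
between patients and controls, because each patient's tumour signal is
diluted by a different healthy-derived fraction.

`exopurity` is a library plus command-line tool for researchers working with
small-RNA sequencing of serum exosomes. It implements:

- **Signature selection** — miRNAs that are differentially expressed between
  cancer-cell-derived and healthy-cell-derived exosomes (negative-binomial
  Wald test, |log2FC| > 1, FDR < 0.01) and stably expressed within each
  group (log2(CPM+1) variance < 2 in both). The signature profile `E` is the
  m × 2 matrix of mean CPM in each source. Per-cancer signatures can be
  merged into a **pan-cancer** signature from miRNAs shared by more than
  five cancer types.
- **Deconvolution** — for a sample's CPM profile `T` over the signature
  miRNAs, the model `T = Eα + ε` is solved for the mixing proportions by
  constrained least squares on the probability simplex:
  `α̂ = argmin ‖Eα − T‖²` subject to `α ≥ 0`, `α₁ + α₂ = 1`
  (quadratic program; `α₁` is the tumour purity).
- **Classification** — a sample is called tumour-derived when its purity is
  extreme against the empirical null distribution of purities predicted for
  healthy-derived samples (add-one empirical p-value, threshold 0.05).
- **Simulation** — mixtures of known purity with Gaussian noise on the CPM
  scale, and fully synthetic NB cohorts with planted fold changes, so every
  step is benchmarkable without any external data.
- **Purity-corrected differential expression** — per miRNA, expression on
  the log2(CPM+1) scale is regressed on purity, `Z = m + λμ + ε` (design
  rows `[1, 0]` for controls, `[1, λⱼ]` for patients), fitted by feasible
  GLS with per-group variances; the Wald test of `μ = 0` with BH adjustment
  recovers tumour-associated miRNAs undiluted by the healthy fraction.

## Worked example

Build a signature on a synthetic cohort, then recover planted purities from
simulated mixtures of an independent validation cohort drawn from the same
generative world:

```python
from dataclasses import replace
import exopurity as xp

spec = xp.SyntheticCohortSpec(seed=11, world_seed=11)   # 500 miRNAs, 30 planted DE, 20+20 samples
counts, meta, truth = xp.synthetic_cohort(spec)
sig = xp.build_signature(counts, meta)                  # |log2FC|>1, FDR<0.01, variance<2
print(f"signature: {sig.m} miRNAs")

val_counts, val_meta, _ = xp.synthetic_cohort(replace(spec, seed=12))
cpm = xp.cpm_normalize(val_counts)
cancer = cpm.subset_samples(val_meta.loc[val_meta.group == "cancer", "sample_id"])
healthy = cpm.subset_samples(val_meta.loc[val_meta.group == "healthy", "sample_id"])

report = xp.run_recovery_benchmark(
    sig, cancer, healthy, xp.purity_grid(0, 1, 100), sigmas=[0, 1, 3, 5, 7, 9], seed=13
)
for sigma, res in report["per_sigma"].items():
    print(f"sigma={sigma:>3}: Pearson r = {res['pearson_r']:.4f}, MAE = {res['mae']:.5f}")
```

Output:

```
signature: 30 miRNAs
sigma=0.0: Pearson r = 1.0000, MAE = 0.00603
sigma=1.0: Pearson r = 1.0000, MAE = 0.00604
sigma=3.0: Pearson r = 1.0000, MAE = 0.00604
sigma=5.0: Pearson r = 1.0000, MAE = 0.00603
sigma=7.0: Pearson r = 1.0000, MAE = 0.00603
sigma=9.0: Pearson r = 1.0000, MAE = 0.00604
```

All 30 planted differential miRNAs enter the signature, and the predicted
purities track the planted grid essentially perfectly: the Pearson
correlation stays at 1.00 at every noise level, and the mean absolute error
(~0.006) reflects only the estimation error of the signature means. Noise
with SD up to 9 CPM barely registers because the least-squares fit is
dominated by the strongly separated signature miRNAs.

The same workflow is available from the shell:

```sh
exopurity synth --seed 11 --out-prefix synth_
exopurity signature --counts synth_counts.tsv --meta synth_meta.tsv --out sig.tsv
exopurity deconvolve --counts mixtures.tsv --signature sig.tsv --out purity.tsv
exopurity de-correct --counts serum.tsv --meta meta.tsv --purity purity.tsv --out de.tsv
```

Subcommands: `signature`, `pan-signature`, `deconvolve`, `simulate`,
`synth`, `benchmark`, `de-correct`, `evaluate`, `split`. All tables are TSV
with a `#` provenance header; reports are JSON.

## Acceptance benchmarks

`scripts/acceptance.py` recomputes the simulation benchmarks end to end —
synthetic cohort → signature → mixtures → deconvolution — and writes the
resulting Pearson correlations to JSON: the noiseless purity-recovery
correlation over a 0–1 purity grid, the minimum correlation across Gaussian
noise levels SD 1–9, and the same minimum for a pan-cancer signature
assembled from six synthetic cancer types sharing a core set of 40
differential miRNAs.

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model, its assumptions and the numerical
choices.
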