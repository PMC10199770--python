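"""In-silico mixtures at known purity and fully synthetic two-group cohorts.

Two generators live here.  ``simulate_cohort`` follows the benchmark design
for the deconvolution model: a mixture at purity x is x times a cancer
expression profile plus (1-x) times a healthy profile, optionally with
additive Gaussian noise (mean 0, SD sigma on the CPM scale, negatives
truncated at 0).  ``synthetic_cohort`` emulates a cancer-line /
healthy-control miRNA-Seq cohort with negative-binomial counts and planted
fold changes, so that signature selection, deconvolution and the corrected
differential test are all exercisable without any external download.

All randomness flows through one ``numpy`` generator seeded from the design;
identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from exopurity.data_io import CPM, RAW_COUNTS, CountMatrix

SOURCE_MODES = ("sample", "mean")


def mix_profiles(cancer_profile, healthy_profile, purity: float) -> np.ndarray:
    """purity x cancer + (1 - purity) x healthy, elementwise."""
    c = np.asarray(cancer_profile, dtype=float)
    h = np.asarray(healthy_profile, dtype=float)
    if c.shape != h.shape:
        raise ValueError(f"profile shapes differ: {c.shape} vs {h.shape}")
    if (c < 0).any() or (h < 0).any():
        raise ValueError("profiles must be non-negative")
    if not 0.0 <= purity <= 1.0:
        raise ValueError(f"purity must lie in [0, 1], got {purity}")
    return purity * c + (1.0 - purity) * h


def purity_grid(lo: float, hi: float, n: int) -> np.ndarray:
    """n evenly spaced purities including both endpoints."""
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"need 0 <= lo < hi <= 1, got lo={lo}, hi={hi}")
    if n < 2:
        raise ValueError("need at least 2 grid points")
    return np.linspace(lo, hi, n)


@dataclass
class MixtureDesign:
    """Planted purities, noise level and seed for one simulated mixture cohort.

    ``source_mode`` selects how the source profiles are formed: ``"sample"``
    draws one random source column per mixture; ``"mean"`` mixes the group
    mean profiles (the benchmark design — a cohort's expression profile
    rather than an individual library).
    """

    purities: np.ndarray
    noise_sd: float = 0.0
    seed: int = 0
    source_mode: str = "mean"

    def __post_init__(self) -> None:
        self.purities = np.asarray(self.purities, dtype=float)
        if ((self.purities < 0) | (self.purities > 1)).any():
            raise ValueError("all purities must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if self.source_mode not in SOURCE_MODES:
            raise ValueError(f"source_mode must be one of {SOURCE_MODES}")


def simulate_cohort(
    cancer_samples: CountMatrix, healthy_samples: CountMatrix, design: MixtureDesign
) -> tuple[CountMatrix, np.ndarray]:
    """Simulated mixtures at the designed purities, plus the planted truth.

    Sources must be CPM matrices sharing miRNA ids in the same order.  Noise
    is i.i.d. Gaussian(0, sigma^2) added to the final CPM mixture, truncated
    at zero (the deconvolution requires non-negative profiles).
    """
    if cancer_samples.scale != CPM or healthy_samples.scale != CPM:
        raise ValueError("simulate_cohort expects CPM source matrices")
    if cancer_samples.mirna_ids != healthy_samples.mirna_ids:
        raise ValueError("source matrices must share miRNA ids in the same order")
    rng = np.random.default_rng(design.seed)
    c_arr = cancer_samples.values.to_numpy(dtype=float)
    h_arr = healthy_samples.values.to_numpy(dtype=float)
    cols = {}
    for k, x in enumerate(design.purities):
        if design.source_mode == "sample":
            c = c_arr[:, rng.integers(c_arr.shape[1])]
            h = h_arr[:, rng.integers(h_arr.shape[1])]
        else:
            c = c_arr.mean(axis=1)
            h = h_arr.mean(axis=1)
        mixed = mix_profiles(c, h, float(x))
        if design.noise_sd > 0:
            mixed = np.maximum(mixed + rng.normal(0.0, design.noise_sd, len(mixed)), 0.0)
        cols[f"mix_{k:04d}"] = mixed
    mixtures = CountMatrix(
        pd.DataFrame(cols, index=cancer_samples.values.index), scale=CPM
    )
    return mixtures, design.purities.copy()


@dataclass
class SyntheticCohortSpec:
    """Generative settings for a synthetic cancer-vs-healthy miRNA-Seq cohort.

    Defaults describe a small but realistic serum-exosome study: 500 miRNAs
    with baseline abundance log-uniform over 1-10^4 CPM (the dynamic range
    of a typical miRNA-Seq library), 30 planted differential miRNAs at
    |log2FC| = 3, NB dispersion 0.05 (within-group biological variability of
    cell-line exosome profiles), 20 samples per group and 5 million counted
    reads per library.
    """

    n_mirna: int = 500
    n_de: int = 30
    n_cancer_samples: int = 20
    n_healthy_samples: int = 20
    log2fc_range: tuple[float, float] = (3.0, 3.0)
    nb_dispersion: float = 0.05
    mean_cpm_range: tuple[float, float] = (1.0, 1e4)
    library_size: int = 5_000_000
    seed: int = 0
    world_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_de > self.n_mirna:
            raise ValueError("n_de cannot exceed n_mirna")
        if min(self.n_mirna, self.n_cancer_samples, self.n_healthy_samples) < 1:
            raise ValueError("cohort dimensions must be positive")
        if self.nb_dispersion <= 0 or self.library_size <= 0:
            raise ValueError("nb_dispersion and library_size must be positive")
        lo, hi = self.mean_cpm_range
        if lo <= 0 or hi < lo:
            raise ValueError("mean_cpm_range must be positive and ordered")
        lo, hi = self.log2fc_range
        if lo < 0 or hi < lo:
            raise ValueError("log2fc_range must be non-negative magnitudes, ordered")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    # NB2: var = mu + dispersion * mu^2; numpy parametrizes by (n, p)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def synthetic_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate (counts, metadata, truth) for one synthetic two-group cohort.

    Baseline per-miRNA mean CPM is log-uniform over ``mean_cpm_range``; the
    first ``n_de`` miRNAs (after a seeded shuffle of identities) carry a
    group fold change with magnitude drawn from ``log2fc_range`` and random
    sign, applied to the cancer group.  Counts are NB(mean = cpm/1e6 x
    library_size, dispersion).  The truth table records every miRNA's true
    log2 fold change (0 for nulls).

    When ``world_seed`` is set, the world parameters (baselines and DE
    assignment) are drawn from it while sampling noise follows ``seed``:
    two specs sharing a ``world_seed`` but differing in ``seed`` describe
    independent cohorts from the same underlying population, e.g. a
    training cohort for signature building and a validation cohort for
    mixture simulation.
    """
    world_rng = np.random.default_rng(
        spec.seed if spec.world_seed is None else spec.world_seed
    )
    # separate stream for sampling noise so cohorts sharing a world differ
    # only in their draws
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(1,)))
    mirna_ids = [f"mir-{i:04d}" for i in range(spec.n_mirna)]
    lo, hi = spec.mean_cpm_range
    base_cpm = np.exp(world_rng.uniform(np.log(lo), np.log(hi), spec.n_mirna))
    de_idx = world_rng.choice(spec.n_mirna, size=spec.n_de, replace=False)
    lfc = np.zeros(spec.n_mirna)
    if spec.n_de:
        mag = world_rng.uniform(spec.log2fc_range[0], spec.log2fc_range[1], spec.n_de)
        sign = world_rng.choice([-1.0, 1.0], spec.n_de)
        lfc[de_idx] = mag * sign

    mean_healthy = base_cpm / 1e6 * spec.library_size
    mean_cancer = mean_healthy * 2.0**lfc
    counts_c = _nb_draw(
        rng, np.tile(mean_cancer[:, None], (1, spec.n_cancer_samples)), spec.nb_dispersion
    )
    counts_h = _nb_draw(
        rng, np.tile(mean_healthy[:, None], (1, spec.n_healthy_samples)), spec.nb_dispersion
    )
    sample_ids = [f"cancer_{j:03d}" for j in range(spec.n_cancer_samples)] + [
        f"healthy_{j:03d}" for j in range(spec.n_healthy_samples)
    ]
    counts = CountMatrix(
        pd.DataFrame(
            np.hstack([counts_c, counts_h]).astype(float),
            index=pd.Index(mirna_ids, name="mirna_id"),
            columns=sample_ids,
        ),
        scale=RAW_COUNTS,
    )
    meta = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": ["cancer"] * spec.n_cancer_samples + ["healthy"] * spec.n_healthy_samples,
            "cancer_type": None,
        }
    )
    truth = pd.DataFrame(
        {"mirna_id": mirna_ids, "true_log2fc": lfc, "is_de": lfc != 0.0}
    )
    return counts, meta, truth


def synthetic_pan_cancer(
    n_types: int = 6,
    n_shared_de: int = 40,
    n_private_de: int = 10,
    spec: SyntheticCohortSpec | None = None,
    seed: int = 0,
) -> dict[str, tuple[CountMatrix, pd.DataFrame, pd.DataFrame]]:
    """Synthetic multi-cancer world: several cohorts sharing a core DE set.

    One global baseline expression vector is drawn, plus a shared set of
    ``n_shared_de`` differential miRNAs whose fold changes are common to all
    cancer types (the pan-cancer signal); each type additionally gets
    ``n_private_de`` private differential miRNAs.  Returns a mapping
    cancer_type -> (counts, metadata, truth) with per-type independent NB
    sampling noise.
    """
    spec = spec or SyntheticCohortSpec()
    if n_shared_de + n_private_de * n_types > spec.n_mirna:
        raise ValueError("not enough miRNAs for the requested shared + private DE sets")
    rng = np.random.default_rng(seed)
    mirna_ids = [f"mir-{i:04d}" for i in range(spec.n_mirna)]
    lo, hi = spec.mean_cpm_range
    base_cpm = np.exp(rng.uniform(np.log(lo), np.log(hi), spec.n_mirna))
    perm = rng.permutation(spec.n_mirna)
    shared_idx = perm[:n_shared_de]
    shared_lfc = rng.uniform(*spec.log2fc_range, n_shared_de) * rng.choice(
        [-1.0, 1.0], n_shared_de
    )
    out = {}
    for t in range(n_types):
        lfc = np.zeros(spec.n_mirna)
        lfc[shared_idx] = shared_lfc
        private_idx = perm[
            n_shared_de + t * n_private_de : n_shared_de + (t + 1) * n_private_de
        ]
        lfc[private_idx] = rng.uniform(*spec.log2fc_range, n_private_de) * rng.choice(
            [-1.0, 1.0], n_private_de
        )
        mean_h = base_cpm / 1e6 * spec.library_size
        mean_c = mean_h * 2.0**lfc
        counts_c = _nb_draw(
            rng, np.tile(mean_c[:, None], (1, spec.n_cancer_samples)), spec.nb_dispersion
        )
        counts_h = _nb_draw(
            rng, np.tile(mean_h[:, None], (1, spec.n_healthy_samples)), spec.nb_dispersion
        )
        name = f"cancer_type_{t}"
        sample_ids = [f"{name}_c{j:03d}" for j in range(spec.n_cancer_samples)] + [
            f"{name}_h{j:03d}" for j in range(spec.n_healthy_samples)
        ]
        counts = CountMatrix(
            pd.DataFrame(
                np.hstack([counts_c, counts_h]).astype(float),
                index=pd.Index(mirna_ids, name="mirna_id"),
                columns=sample_ids,
            ),
            scale=RAW_COUNTS,
        )
        meta = pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": ["cancer"] * spec.n_cancer_samples
                + ["healthy"] * spec.n_healthy_samples,
                "cancer_type": name,
            }
        )
        truth = pd.DataFrame(
            {"mirna_id": mirna_ids, "true_log2fc": lfc, "is_de": lfc != 0.0}
        )
        out[name] = (counts, meta, truth)
    return out
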