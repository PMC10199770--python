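"""miRNA signature selection for exosome deconvolution.

A signature miRNA must (i) separate cancer-cell-derived from
healthy-cell-derived exosomes — negative-binomial Wald test, |log2FC| > 1
at FDR < 0.01 by default — and (ii) be stably expressed within each group,
with log2(CPM+1) variance below 2 in both groups.  The signature profile E
stores, per retained miRNA, the mean CPM in cancer-derived and in
healthy-derived exosomes; the mixture model downstream is linear in
expression, so E lives on the linear CPM scale.

The differential test is a documented stand-in for DESeq2: median-of-ratios
size factors, per-miRNA method-of-moments dispersion, an NB GLM with a group
indicator and a Wald test on the group coefficient — no dispersion shrinkage
and no fold-change moderation.  A precomputed DE table can be supplied to
reproduce DESeq2-exact signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from exopurity.data_io import CPM, RAW_COUNTS, CountMatrix, check_samples_match, cpm_normalize

logger = logging.getLogger(__name__)

_DISPERSION_FLOOR = 1e-8


@dataclass
class SignatureProfile:
    """Signature expression profile E.

    ``E`` is an m x 2 matrix of mean CPM values: column 0 is the cancer-
    exosome mean, column 1 the healthy-exosome mean.  A miRNA with identical
    means in both columns carries no deconvolution signal and is rejected.
    """

    mirna_ids: list[str]
    E: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.mirna_ids = list(self.mirna_ids)
        if len(self.mirna_ids) != len(set(self.mirna_ids)):
            raise ValueError("duplicate miRNA ids in signature")
        if self.E.ndim != 2 or self.E.shape[1] != 2:
            raise ValueError(f"E must be m x 2, got shape {self.E.shape}")
        if self.E.shape[0] != len(self.mirna_ids):
            raise ValueError("mirna_ids and E row count disagree")
        if self.E.shape[0] < 2:
            raise ValueError("a signature needs at least 2 miRNAs")
        if (self.E < 0).any():
            raise ValueError("signature expression must be non-negative")
        same = self.E[:, 0] == self.E[:, 1]
        if same.any():
            bad = [m for m, s in zip(self.mirna_ids, same) if s]
            raise ValueError(f"miRNA(s) with identical cancer/healthy means: {bad}")

    @property
    def m(self) -> int:
        return self.E.shape[0]

    @property
    def e_cancer(self) -> np.ndarray:
        return self.E[:, 0]

    @property
    def e_healthy(self) -> np.ndarray:
        return self.E[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mirna_id": self.mirna_ids, "E_cancer": self.E[:, 0], "E_healthy": self.E[:, 1]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: dict | None = None) -> "SignatureProfile":
        return cls(
            mirna_ids=list(df["mirna_id"]),
            E=df[["E_cancer", "E_healthy"]].to_numpy(dtype=float),
            provenance=provenance or {},
        )


def size_factors(values: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors (DESeq-style).

    The per-sample factor is the median, over miRNAs expressed in every
    sample, of the ratio of the sample's count to the miRNA's geometric
    mean across samples.
    """
    values = np.asarray(values, dtype=float)
    with np.errstate(divide="ignore"):
        logv = np.log(values)
    ok = np.isfinite(logv).all(axis=1)
    if not ok.any():
        raise ValueError("no miRNA is expressed in every sample; cannot compute size factors")
    log_geo = logv[ok].mean(axis=1)
    sf = np.exp(np.median(logv[ok] - log_geo[:, None], axis=0))
    return sf


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR)."""
    pvalues = np.asarray(pvalues, dtype=float)
    return multipletests(pvalues, method="fdr_bh")[1]


def _mom_dispersion(y: np.ndarray, sf: np.ndarray, is_cancer: np.ndarray) -> float:
    # Method-of-moments on normalized counts, pooling within-group residual
    # variance so a real group difference does not inflate the dispersion.
    q = y / sf
    resid_ss = 0.0
    for g in (True, False):
        sel = is_cancer == g
        resid_ss += ((q[sel] - q[sel].mean()) ** 2).sum()
    resid_var = resid_ss / max(len(y) - 2, 1)
    base = q.mean()
    if base <= 0:
        return _DISPERSION_FLOOR
    # subtract the Poisson component (scaled by 1/sf) before dividing by mean^2
    alpha = (resid_var - base * np.mean(1.0 / sf)) / base**2
    return max(alpha, _DISPERSION_FLOOR)


def nb_de_test(counts: CountMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-miRNA negative-binomial Wald test, cancer vs healthy.

    Returns a DataFrame with columns ``mirna_id``, ``base_mean``,
    ``log2fc`` (cancer over healthy, from the fitted group coefficient),
    ``pvalue`` and BH-adjusted ``fdr``.  All-zero miRNA rows are dropped
    (their number is logged).  Requires at least two samples per group.
    """
    if counts.scale != RAW_COUNTS:
        raise ValueError("nb_de_test expects raw counts")
    meta = check_samples_match(counts, meta)
    is_cancer = (meta["group"] == "cancer").to_numpy()
    n_c, n_h = int(is_cancer.sum()), int((~is_cancer).sum())
    if n_c < 2 or n_h < 2:
        raise ValueError(f"need >=2 samples per group, got cancer={n_c}, healthy={n_h}")

    values = counts.values.to_numpy(dtype=float)
    nonzero = values.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d all-zero miRNA rows", n_dropped)
    values = values[nonzero]
    ids = [m for m, keep in zip(counts.mirna_ids, nonzero) if keep]

    sf = size_factors(values)
    offset = np.log(sf)
    X = np.column_stack([np.ones(len(sf)), is_cancer.astype(float)])

    rows = []
    for mirna, y in zip(ids, values):
        alpha = _mom_dispersion(y, sf, is_cancer)
        base_mean = float(np.mean(y / sf))
        try:
            fit = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
            ).fit()
            coef, se = fit.params[1], fit.bse[1]
            z = coef / se if se > 0 else 0.0
            pval = 2.0 * stats.norm.sf(abs(z))
            log2fc = coef / np.log(2.0)
        except Exception:  # noqa: BLE001 - rare non-convergence, keep the row
            logger.warning("NB fit failed for %s; reporting a null result", mirna)
            log2fc, pval = 0.0, 1.0
        rows.append((mirna, base_mean, float(log2fc), float(pval)))

    out = pd.DataFrame(rows, columns=["mirna_id", "base_mean", "log2fc", "pvalue"])
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    return out


def variance_filter(
    cpm: CountMatrix, meta: pd.DataFrame, var_threshold: float = 2.0
) -> set[str]:
    """miRNAs with log2(CPM+1) variance strictly below threshold in BOTH groups.

    Stability is assessed on the log scale; the variance of raw CPM is
    essentially never below 2 for an expressed miRNA, so the threshold is
    meaningful only after the log2(CPM+1) transform.
    """
    if cpm.scale != CPM:
        raise ValueError("variance_filter expects a CPM matrix")
    meta = check_samples_match(cpm, meta)
    log_expr = np.log2(cpm.values.to_numpy(dtype=float) + 1.0)
    keep = np.ones(cpm.n_mirna, dtype=bool)
    for group in ("cancer", "healthy"):
        sel = (meta["group"] == group).to_numpy()
        if not sel.any():
            raise ValueError(f"no samples in group {group!r}")
        var = log_expr[:, sel].var(axis=1, ddof=1) if sel.sum() > 1 else np.zeros(cpm.n_mirna)
        keep &= var < var_threshold
    return {m for m, k in zip(cpm.mirna_ids, keep) if k}


def build_signature(
    counts: CountMatrix,
    meta: pd.DataFrame,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.01,
    var_threshold: float = 2.0,
    de_table: pd.DataFrame | None = None,
) -> SignatureProfile:
    """Assemble the signature profile E from raw counts and group labels.

    Signature set = {miRNA : |log2FC| > lfc_threshold and FDR < fdr_threshold}
    intersected with the within-group stability filter; all inequalities are
    strict.  E columns are the arithmetic mean CPM per group.  ``de_table``
    (columns ``mirna_id``, ``log2fc``, ``pvalue``, ``fdr``) bypasses the
    internal NB test, e.g. to use DESeq2 output directly.
    """
    meta = check_samples_match(counts, meta)
    de = de_table if de_table is not None else nb_de_test(counts, meta)
    de_hits = set(
        de.loc[
            (de["log2fc"].abs() > lfc_threshold) & (de["fdr"] < fdr_threshold), "mirna_id"
        ]
    )
    cpm = cpm_normalize(counts)
    stable = variance_filter(cpm, meta, var_threshold=var_threshold)
    chosen = de_hits & stable
    if len(chosen) < 2:
        raise ValueError(
            f"signature has {len(chosen)} miRNA(s); need >=2 — relax the thresholds "
            f"(|log2FC|>{lfc_threshold}, FDR<{fdr_threshold}, variance<{var_threshold})"
        )
    # keep the input row order for reproducible output
    ordered = [m for m in counts.mirna_ids if m in chosen]
    is_cancer = (meta["group"] == "cancer").to_numpy()
    expr = cpm.values.loc[ordered].to_numpy(dtype=float)
    E = np.column_stack([expr[:, is_cancer].mean(axis=1), expr[:, ~is_cancer].mean(axis=1)])
    return SignatureProfile(
        mirna_ids=ordered,
        E=E,
        provenance={
            "lfc_threshold": lfc_threshold,
            "fdr_threshold": fdr_threshold,
            "var_threshold": var_threshold,
            "n_cancer": int(is_cancer.sum()),
            "n_healthy": int((~is_cancer).sum()),
        },
    )


def pan_cancer_signature(
    signatures: dict[str, SignatureProfile], min_cancer_count: int = 5
) -> SignatureProfile:
    """Pan-cancer signature: miRNAs present in MORE THAN ``min_cancer_count`` types.

    The E columns of a retained miRNA are the unweighted mean of its
    per-cancer E values over the cancers whose signature contains it.
    """
    if len(signatures) < min_cancer_count + 1:
        raise ValueError(
            f"need more than {min_cancer_count} input signatures, got {len(signatures)}"
        )
    counts: dict[str, int] = {}
    order: list[str] = []
    for sig in signatures.values():
        for m in sig.mirna_ids:
            if m not in counts:
                order.append(m)
            counts[m] = counts.get(m, 0) + 1
    chosen = [m for m in order if counts[m] > min_cancer_count]
    if len(chosen) < 2:
        raise ValueError(
            f"only {len(chosen)} miRNA(s) shared by more than {min_cancer_count} cancers"
        )
    E = np.zeros((len(chosen), 2))
    for i, m in enumerate(chosen):
        rows = [
            sig.E[sig.mirna_ids.index(m)] for sig in signatures.values() if m in sig.mirna_ids
        ]
        E[i] = np.mean(rows, axis=0)
    return SignatureProfile(
        mirna_ids=chosen,
        E=E,
        provenance={
            "min_cancer_count": min_cancer_count,
            "n_input_signatures": len(signatures),
            "cancer_types": sorted(signatures),
        },
    )
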