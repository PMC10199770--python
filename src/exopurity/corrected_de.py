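"""Purity-corrected differential expression.

In a serum sample with tumour purity lambda, the expression of miRNA i is
modelled as Z = m_i + lambda * mu_i + e: the healthy baseline m_i plus the
tumour-associated shift mu_i diluted by the healthy-derived fraction.  A
plain two-group test estimates lambda-bar * mu_i (attenuated by the average
purity); regressing on purity instead recovers the undiluted effect.

Per miRNA, the design is W = [1, lambda_j] with lambda_j = 0 for healthy
samples, and the model Z = W beta + e is fitted by feasible generalized
least squares with a diagonal covariance holding one variance per group
(healthy / tumour), estimated from the residuals of an initial ordinary
fit — one re-weighting pass.  The tumour effect mu is Wald-tested against
the standard normal, and p-values are Benjamini-Hochberg adjusted across
miRNAs.  Expression enters on the log2(CPM+1) scale, so mu is directly a
log2 fold change extrapolated to purity 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from exopurity.data_io import CPM, CountMatrix, check_samples_match, cpm_normalize
from exopurity.deconvolution import PurityEstimate
from exopurity.signature import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class PurityDesign:
    """Design matrix W: rows [1, 0] for healthy samples, [1, lambda_j] for tumour."""

    W: np.ndarray
    sample_ids: list[str]
    is_tumour: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.is_tumour = np.asarray(self.is_tumour, dtype=bool)
        n = len(self.sample_ids)
        if self.W.shape != (n, 2) or len(self.is_tumour) != n:
            raise ValueError("W, sample_ids and is_tumour sizes disagree")
        if not np.all(self.W[:, 0] == 1.0):
            raise ValueError("first design column must be all ones")
        lam = self.W[:, 1]
        if np.any(lam[~self.is_tumour] != 0.0):
            raise ValueError("healthy rows must have purity 0")
        if ((lam < 0) | (lam > 1)).any():
            raise ValueError("purities must lie in [0, 1]")
        if np.linalg.matrix_rank(self.W) < 2:
            raise ValueError("design is rank deficient: all purities are 0")

    @property
    def n(self) -> int:
        return len(self.sample_ids)


def _purity_lookup(purities) -> dict[str, float]:
    if isinstance(purities, dict):
        return {str(k): float(v) for k, v in purities.items()}
    if isinstance(purities, pd.DataFrame):
        return dict(zip(purities["sample_id"].astype(str), purities["alpha_tumour"]))
    out = {}
    for p in purities:
        if not isinstance(p, PurityEstimate):
            raise TypeError(f"cannot interpret purity entry of type {type(p).__name__}")
        out[p.sample_id] = p.alpha_tumour
    return out


def build_design(meta: pd.DataFrame, purities) -> PurityDesign:
    """Assemble W from sample metadata and tumour-sample purity estimates.

    ``purities`` may be a dict ``sample_id -> lambda``, a purity table
    (DataFrame with ``sample_id``/``alpha_tumour``) or a list of
    :class:`PurityEstimate`.  Every cancer-group sample needs an estimate;
    healthy samples need none and get lambda = 0.
    """
    lookup = _purity_lookup(purities)
    sample_ids = list(meta["sample_id"])
    is_tumour = (meta["group"] == "cancer").to_numpy()
    lam = np.zeros(len(sample_ids))
    for k, (sid, tum) in enumerate(zip(sample_ids, is_tumour)):
        if tum:
            if sid not in lookup:
                raise ValueError(f"tumour sample {sid!r} has no purity estimate")
            lam[k] = lookup[sid]
    W = np.column_stack([np.ones(len(sample_ids)), lam])
    return PurityDesign(W=W, sample_ids=sample_ids, is_tumour=is_tumour)


@dataclass
class CorrectedDEResult:
    """Per-miRNA fit: baseline m, tumour shift mu, Wald test of mu = 0."""

    mirna_id: str
    m_hat: float
    mu_hat: float
    se_mu: float
    wald_stat: float
    pvalue: float
    log2fc: float
    fdr: float = float("nan")


def fit_corrected(
    Z, design: PurityDesign, mirna_id: str = "miRNA", ols: bool = False
) -> CorrectedDEResult:
    """Fit Z = W beta + e for one miRNA and Wald-test the tumour effect.

    ``Z`` is the per-sample expression vector on the log2(CPM+1) scale, in
    design row order.  Unless ``ols`` is set, one feasible-GLS pass is run:
    residual variances of an initial OLS fit are pooled within the healthy
    and tumour groups and used as a diagonal covariance.  ``log2fc`` is
    mu_hat, the effect extrapolated to purity 1.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.shape != (design.n,):
        raise ValueError(f"expression vector length {Z.shape} != design rows {design.n}")
    if not np.isfinite(Z).all():
        raise ValueError("expression vector contains non-finite values")
    W = design.W
    beta, *_ = np.linalg.lstsq(W, Z, rcond=None)
    if ols:
        sigma2 = np.ones(design.n)
    else:
        resid = Z - W @ beta
        sigma2 = np.ones(design.n)
        for sel in (design.is_tumour, ~design.is_tumour):
            if sel.sum() > 1:
                # per-group residual variance; floor avoids zero weights on
                # degenerate (noiseless) inputs
                sigma2[sel] = max(
                    float((resid[sel] ** 2).sum() / max(sel.sum() - 1, 1)), 1e-12
                )
    Wt_Sinv = W.T / sigma2
    normal = Wt_Sinv @ W
    if np.linalg.cond(normal) > 1e12:
        raise np.linalg.LinAlgError("W' Sigma^-1 W is singular")
    cov = np.linalg.inv(normal)
    beta = cov @ (Wt_Sinv @ Z)
    if ols:
        # homoscedastic: scale the unweighted covariance by residual variance
        resid = Z - W @ beta
        s2 = float((resid**2).sum() / max(design.n - 2, 1))
        cov = cov * s2
    se_mu = float(np.sqrt(cov[1, 1]))
    mu_hat = float(beta[1])
    wald = mu_hat / se_mu if se_mu > 0 else 0.0
    pval = float(2.0 * stats.norm.sf(abs(wald)))
    return CorrectedDEResult(
        mirna_id=mirna_id,
        m_hat=float(beta[0]),
        mu_hat=mu_hat,
        se_mu=se_mu,
        wald_stat=float(wald),
        pvalue=pval,
        log2fc=mu_hat,
    )


def corrected_de_table(
    counts: CountMatrix,
    meta: pd.DataFrame,
    purities,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    ols: bool = False,
) -> pd.DataFrame:
    """Purity-corrected DE over a whole matrix, BH-adjusted jointly.

    Accepts raw counts (CPM-normalized internally) or a CPM matrix.
    Returns one row per miRNA with a ``significant`` flag: FDR below
    ``fdr_threshold`` and |log2FC| above ``lfc_threshold``, both strict.
    Per-miRNA failures are logged and reported as NA rows, not fatal.
    """
    meta = check_samples_match(counts, meta)
    cpm = counts if counts.scale == CPM else cpm_normalize(counts)
    design = build_design(meta, purities)
    order = [cpm.sample_ids.index(s) for s in design.sample_ids]
    log_expr = np.log2(cpm.values.to_numpy(dtype=float)[:, order] + 1.0)

    rows = []
    for mirna, z in zip(cpm.mirna_ids, log_expr):
        try:
            rows.append(fit_corrected(z, design, mirna_id=mirna, ols=ols))
        except (ValueError, np.linalg.LinAlgError) as err:
            logger.warning("corrected fit failed for %s: %s", mirna, err)
            rows.append(
                CorrectedDEResult(
                    mirna_id=mirna,
                    m_hat=float("nan"),
                    mu_hat=float("nan"),
                    se_mu=float("nan"),
                    wald_stat=float("nan"),
                    pvalue=float("nan"),
                    log2fc=float("nan"),
                )
            )
    table = pd.DataFrame(
        {
            "mirna_id": [r.mirna_id for r in rows],
            "m_hat": [r.m_hat for r in rows],
            "mu_hat": [r.mu_hat for r in rows],
            "se_mu": [r.se_mu for r in rows],
            "wald_stat": [r.wald_stat for r in rows],
            "pvalue": [r.pvalue for r in rows],
            "log2fc": [r.log2fc for r in rows],
        }
    )
    ok = table["pvalue"].notna()
    fdr = np.full(len(table), np.nan)
    if ok.any():
        fdr[ok.to_numpy()] = bh_adjust(table.loc[ok, "pvalue"].to_numpy())
    table["fdr"] = fdr
    table["significant"] = (table["fdr"] < fdr_threshold) & (
        table["log2fc"].abs() > lfc_threshold
    )
    return table
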