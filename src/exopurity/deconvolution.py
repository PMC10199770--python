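"""Simplex-constrained least-squares purity estimation and null classification.

The mixture model is T = E a + e: an observed serum-exosome CPM profile T
over the signature miRNAs is a convex combination of the cancer-exosome and
healthy-exosome reference columns of E, with purity vector
a = (a_tumour, a_healthy) constrained to the probability simplex
(a >= 0, a_tumour + a_healthy = 1).  The estimate is the quadratic program

    min ||E a - T||^2   s.t.  1' a = 1,  a >= 0,

solved exactly by enumerating active sets of the KKT system (the problem
has two variables, so there are three candidate sets).  For two components
the solution also has a closed form,

    a_tumour = clip( (E1 - E2)'(T - E2) / ||E1 - E2||^2, 0, 1 ),

which is kept as an independent reference for testing.

Tumour/normal classification compares an observed purity against an
empirical null distribution of purities predicted for healthy-derived
samples, with the add-one (permutation-style) p-value estimator
p = (1 + #{null >= observed}) / (1 + n), so p is never exactly 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from exopurity.data_io import CPM, CountMatrix
from exopurity.signature import SignatureProfile

logger = logging.getLogger(__name__)

_SUM_TOL = 1e-8
_NEG_TOL = 1e-10
_RIDGE = 1e-10
_COND_LIMIT = 1e12


@dataclass
class PurityEstimate:
    """Estimated composition of one sample: tumour and healthy fractions sum to 1."""

    sample_id: str
    alpha_tumour: float
    alpha_healthy: float
    residual_norm: float

    def __post_init__(self) -> None:
        if abs(self.alpha_tumour + self.alpha_healthy - 1.0) > _SUM_TOL:
            raise ValueError("purity components must sum to 1")
        if self.alpha_tumour < -_NEG_TOL or self.alpha_healthy < -_NEG_TOL:
            raise ValueError("purity components must be non-negative")
        if self.residual_norm < 0:
            raise ValueError("residual norm must be non-negative")


def closed_form_tumour_purity(T: np.ndarray, e_cancer: np.ndarray, e_healthy: np.ndarray) -> float:
    """Two-component closed form: project T onto the segment [E_healthy, E_cancer]."""
    d = np.asarray(e_cancer, float) - np.asarray(e_healthy, float)
    denom = float(d @ d)
    if denom == 0.0:
        raise ValueError("cancer and healthy profiles are identical (unidentifiable)")
    return float(np.clip(d @ (np.asarray(T, float) - e_healthy) / denom, 0.0, 1.0))


def _solve_simplex_qp(H: np.ndarray, f: np.ndarray) -> np.ndarray:
    """min 1/2 a'Ha + f'a  s.t.  sum(a) = 1, a >= 0, by active-set enumeration.

    For each non-empty candidate set of free variables, solve the equality-
    constrained KKT system with the complementary variables pinned at zero
    and accept the first primal- and dual-feasible solution (unique by
    convexity).  H is ridge-regularized when near-singular.
    """
    k = H.shape[0]
    if np.linalg.cond(H) > _COND_LIMIT:
        H = H + _RIDGE * np.eye(k)
    best = None
    best_obj = np.inf
    for size in range(k, 0, -1):
        for free in combinations(range(k), size):
            free = list(free)
            kkt = np.zeros((size + 1, size + 1))
            kkt[:size, :size] = H[np.ix_(free, free)]
            kkt[:size, size] = 1.0
            kkt[size, :size] = 1.0
            rhs = np.zeros(size + 1)
            rhs[:size] = -f[free]
            rhs[size] = 1.0
            try:
                sol = np.linalg.solve(kkt, rhs)
            except np.linalg.LinAlgError:
                continue
            a = np.zeros(k)
            a[free] = sol[:size]
            lam = sol[size]
            if (a[free] < -_NEG_TOL).any():
                continue
            # dual feasibility of the pinned variables: gradient + lambda >= 0
            grad = H @ a + f
            fixed = [i for i in range(k) if i not in free]
            if fixed and (grad[fixed] + lam < -1e-7 * max(1.0, abs(lam))).any():
                continue
            obj = 0.5 * a @ H @ a + f @ a
            if obj < best_obj - 1e-15:
                best, best_obj = a, obj
    if best is None:  # pragma: no cover - convex QP on the simplex always has a solution
        raise RuntimeError("simplex QP failed to find a feasible solution")
    best = np.clip(best, 0.0, None)
    return best / best.sum()


def estimate_purity(
    T: np.ndarray, signature: SignatureProfile, sample_id: str = "sample"
) -> PurityEstimate:
    """Deconvolve one CPM profile over the signature miRNAs.

    ``T`` must be aligned to ``signature.mirna_ids`` (same order, same
    length).  Returns the simplex-constrained least-squares purity and the
    residual norm ||E a - T||.
    """
    T = np.asarray(T, dtype=float)
    if T.ndim != 1 or len(T) != signature.m:
        raise ValueError(
            f"profile length {T.shape} does not match signature size {signature.m}"
        )
    if (T < 0).any():
        raise ValueError("expression profile must be non-negative")
    if np.array_equal(signature.e_cancer, signature.e_healthy):
        raise ValueError("cancer and healthy profiles are identical (unidentifiable)")
    E = signature.E
    a = _solve_simplex_qp(E.T @ E, -(E.T @ T))
    resid = float(np.linalg.norm(E @ a - T))
    return PurityEstimate(
        sample_id=sample_id,
        alpha_tumour=float(a[0]),
        alpha_healthy=float(a[1]),
        residual_norm=resid,
    )


def estimate_purity_matrix(
    cpm: CountMatrix, signature: SignatureProfile, allow_partial: bool = False
) -> list[PurityEstimate]:
    """Deconvolve every sample (column) of a CPM matrix.

    Signature miRNAs absent from the matrix are an error unless
    ``allow_partial`` is set, in which case the signature is restricted to
    the shared set (logged).
    """
    if cpm.scale != CPM:
        raise ValueError("estimate_purity_matrix expects a CPM matrix")
    present = set(cpm.mirna_ids)
    missing = [m for m in signature.mirna_ids if m not in present]
    if missing and not allow_partial:
        raise ValueError(f"signature miRNA(s) missing from matrix: {missing}")
    shared = [m for m in signature.mirna_ids if m in present]
    if len(shared) < 2:
        raise ValueError("fewer than 2 signature miRNAs present in the matrix")
    if missing:
        logger.warning(
            "restricting signature to %d of %d miRNAs present in the matrix",
            len(shared),
            signature.m,
        )
        keep = [signature.mirna_ids.index(m) for m in shared]
        signature = SignatureProfile(shared, signature.E[keep], signature.provenance)
    sub = cpm.values.loc[shared]
    return [
        estimate_purity(sub[s].to_numpy(dtype=float), signature, sample_id=s)
        for s in cpm.sample_ids
    ]


def purity_frame(estimates: list[PurityEstimate]) -> pd.DataFrame:
    """Tabulate purity estimates (column layout of the purity TSV)."""
    return pd.DataFrame(
        {
            "sample_id": [e.sample_id for e in estimates],
            "alpha_tumour": [e.alpha_tumour for e in estimates],
            "alpha_healthy": [e.alpha_healthy for e in estimates],
            "residual_norm": [e.residual_norm for e in estimates],
        }
    )


@dataclass
class NullDistribution:
    """Sorted tumour purities of healthy-derived samples: the empirical null."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if len(self.values) == 0:
            raise ValueError("null distribution needs at least one value")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("null purities must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.values)


def build_null(healthy_purities) -> NullDistribution:
    """Build the empirical null from healthy-derived purity estimates (>= 10 values)."""
    values = np.asarray(list(healthy_purities), dtype=float)
    if len(values) == 0:
        raise ValueError("no healthy purity values supplied")
    if len(values) < 10:
        raise ValueError(f"need >=10 healthy purities to form a null, got {len(values)}")
    if len(values) < 20:
        warnings.warn(
            f"null distribution built from only {len(values)} values; "
            "p-values will be coarse",
            stacklevel=2,
        )
    return NullDistribution(values)


@dataclass
class ClassificationResult:
    sample_id: str
    tumour_purity: float
    p_value: float
    label: str


def classify(
    purity: PurityEstimate | float,
    null: NullDistribution,
    alpha_level: float = 0.05,
    sample_id: str | None = None,
) -> ClassificationResult:
    """Label a sample tumour/normal against the healthy-derived null.

    p = (1 + #{null >= observed}) / (1 + n); the sample is called ``tumour``
    when p < ``alpha_level``.
    """
    if isinstance(purity, PurityEstimate):
        observed = purity.alpha_tumour
        sid = sample_id or purity.sample_id
    else:
        observed = float(purity)
        sid = sample_id or "sample"
    n_ge = int((null.values >= observed).sum())
    p = (1 + n_ge) / (1 + null.n)
    return ClassificationResult(
        sample_id=sid,
        tumour_purity=observed,
        p_value=p,
        label="tumour" if p < alpha_level else "normal",
    )
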