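"""Benchmark metrics and evaluation protocols for the purity model.

Implements the performance measures used to score the deconvolution —
Pearson correlation and mean absolute error between planted and predicted
purity, and precision/recall/specificity/F1 for tumour-vs-normal calls —
plus the two evaluation protocols: the purity-recovery benchmark over a
purity grid at several Gaussian noise levels, and stratified splitting of a
cohort into a held-out part and cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import nan

import numpy as np
import pandas as pd
from scipy import stats

from exopurity.data_io import CountMatrix
from exopurity.deconvolution import estimate_purity_matrix
from exopurity.signature import SignatureProfile
from exopurity.simulate import MixtureDesign, simulate_cohort

LABELS = ("tumour", "normal")


def pearson(x, y) -> float:
    """Sample Pearson correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson needs two equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("pearson needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("pearson undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def mae(x, y) -> float:
    """Mean absolute error between paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("mae needs equal-length vectors")
    if x.size == 0:
        raise ValueError("mae needs at least one pair")
    return float(np.mean(np.abs(x - y)))


@dataclass
class ConfusionMetrics:
    """Binary tumour/normal confusion counts and derived rates.

    Undefined ratios (zero denominator) are NaN, never silently 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    specificity: float
    f1: float


def confusion_metrics(truth, predicted) -> ConfusionMetrics:
    """Score tumour/normal label vectors ('tumour' is the positive class)."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("label vectors differ in length")
    for lab in (*truth, *predicted):
        if lab not in LABELS:
            raise ValueError(f"unknown label {lab!r}; expected one of {LABELS}")
    tp = sum(t == "tumour" and p == "tumour" for t, p in zip(truth, predicted))
    fp = sum(t == "normal" and p == "tumour" for t, p in zip(truth, predicted))
    tn = sum(t == "normal" and p == "normal" for t, p in zip(truth, predicted))
    fn = sum(t == "tumour" and p == "normal" for t, p in zip(truth, predicted))
    precision = tp / (tp + fp) if tp + fp else nan
    recall = tp / (tp + fn) if tp + fn else nan
    specificity = tn / (tn + fp) if tn + fp else nan
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision == precision and recall == recall and precision + recall > 0
        else nan
    )
    return ConfusionMetrics(tp, fp, tn, fn, precision, recall, specificity, f1)


def run_recovery_benchmark(
    signature: SignatureProfile,
    cancer_sources: CountMatrix,
    healthy_sources: CountMatrix,
    grid,
    sigmas=(0.0, 1.0, 3.0, 5.0, 7.0, 9.0),
    seed: int = 0,
    source_mode: str = "mean",
) -> dict:
    """Purity-recovery benchmark: simulate, deconvolve, score per noise level.

    For each Gaussian noise SD in ``sigmas`` the grid of purities is
    simulated from the source matrices, every mixture is deconvolved with
    ``signature``, and Pearson r plus MAE against the planted purities are
    recorded.  Deterministic given ``seed``.
    """
    grid = np.asarray(grid, dtype=float)
    per_sigma = {}
    for k, sigma in enumerate(sigmas):
        design = MixtureDesign(
            purities=grid, noise_sd=float(sigma), seed=seed + k, source_mode=source_mode
        )
        mixtures, truth = simulate_cohort(cancer_sources, healthy_sources, design)
        mixtures = mixtures.subset_mirnas(
            [m for m in mixtures.mirna_ids if m in set(signature.mirna_ids)]
        )
        estimates = estimate_purity_matrix(mixtures, signature)
        predicted = np.array([e.alpha_tumour for e in estimates])
        per_sigma[float(sigma)] = {
            "pearson_r": pearson(truth, predicted),
            "mae": mae(truth, predicted),
        }
    return {
        "per_sigma": per_sigma,
        "n_samples": int(len(grid)),
        "config": {
            "signature_size": signature.m,
            "sigmas": [float(s) for s in sigmas],
            "seed": int(seed),
            "source_mode": source_mode,
            "grid_lo": float(grid.min()),
            "grid_hi": float(grid.max()),
        },
    }


def split_cohort(
    meta: pd.DataFrame, n_parts: int = 5, n_folds: int = 3, seed: int = 0
) -> tuple[list[str], list[list[str]]]:
    """Stratified split into a held-out part plus cross-validation folds.

    Samples are partitioned into ``n_parts`` parts, stratified by group
    (and by cancer_type when present); the first part is held out and the
    remaining samples are folded ``n_folds`` ways, again stratified.
    Returns (held_out_ids, folds).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    strata_cols = ["group"]
    if meta["cancer_type"].notna().any():
        strata_cols.append("cancer_type")

    def partition(ids: list[str], k: int) -> list[list[str]]:
        ids = list(ids)
        rng.shuffle(ids)
        return [ids[i::k] for i in range(k)]

    parts: list[list[str]] = [[] for _ in range(n_parts)]
    for _, stratum in meta.groupby(strata_cols, dropna=False):
        ids = list(stratum["sample_id"])
        if len(ids) < n_parts:
            raise ValueError(
                f"stratum of size {len(ids)} cannot be split into {n_parts} parts"
            )
        for i, chunk in enumerate(partition(ids, n_parts)):
            parts[i].extend(chunk)
    held_out = sorted(parts[0])
    remaining_ids = sorted(set(meta["sample_id"]) - set(held_out))
    remaining = meta[meta["sample_id"].isin(remaining_ids)]
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for _, stratum in remaining.groupby(strata_cols, dropna=False):
        for i, chunk in enumerate(partition(list(stratum["sample_id"]), n_folds)):
            folds[i].extend(chunk)
    return held_out, [sorted(f) for f in folds]
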