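"""Cross-validated decoding accuracy over all 7-train / 3-test subset splits.

Trials are grouped once (seeded) into 10 subsets of equal size, stratified by
class by default. Every way of holding out 3 of the 10 subsets is evaluated —
C(10,3) = 120 separations — and the mean of the 120 correct rates is the
session accuracy; their spread is the accuracy SD. Each subset sits on the
test side in C(9,2) = 36 separations, so every trial is tested exactly 36
times. The run-wise variant applies the identical scheme to each run's
trials alone (40 trials -> subsets of 4) with a smaller filter bank.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import EpochSet, CLASSES
from .csp import (ClassCovariances, class_covariances, classify_accuracy,
                  csp_features, csp_filters, flda_train, trial_covariances,
                  SpatialFilterBank)

__all__ = [
    "SubsetAssignment",
    "CVResult",
    "make_subsets",
    "enumerate_separations",
    "cross_validated_accuracy",
    "run_wise_accuracy",
]


@dataclass
class SubsetAssignment:
    subset_id: np.ndarray  # per-trial, 0..k-1
    k: int
    seed: object
    stratified: bool

    def __post_init__(self):
        sizes = np.bincount(self.subset_id, minlength=self.k)
        if sizes.max() - sizes.min() > 1:
            raise ValueError(f"subset sizes differ by more than 1: {sizes}")


@dataclass
class CVResult:
    """Per-separation correct rates with their mean and SD (percent)."""

    per_separation_accuracy: np.ndarray  # in [0, 1]
    mean_accuracy: float                 # percent
    accuracy_sd: float                   # percent, population SD over separations
    m_filters: int
    seed: object
    n_trials: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "separation": np.arange(len(self.per_separation_accuracy)),
            "accuracy": self.per_separation_accuracy,
        })

    def summary(self) -> dict:
        return {"mean_accuracy": self.mean_accuracy,
                "accuracy_sd": self.accuracy_sd,
                "n_separations": int(len(self.per_separation_accuracy)),
                "m_filters": self.m_filters,
                "n_trials": self.n_trials}


def make_subsets(epochs: EpochSet, k: int = 10, stratified: bool = True,
                 seed=0) -> SubsetAssignment:
    """Seeded random partition of trials into k subsets of equal size (±1).

    With stratification the per-class counts in each subset are equal (±1),
    guaranteeing both classes appear in every training fold.
    """
    n = epochs.n_trials
    if k > n:
        raise ValueError(f"cannot split {n} trials into {k} subsets")
    rng = np.random.default_rng(seed)
    subset_id = np.empty(n, dtype=int)
    if stratified:
        # deal each class's shuffled trials round-robin; rotate the starting
        # subset between classes so totals stay balanced when counts % k != 0
        offset = 0
        for c in CLASSES:
            idx = np.flatnonzero(epochs.labels == c)
            rng.shuffle(idx)
            subset_id[idx] = (np.arange(len(idx)) + offset) % k
            offset += len(idx)
    else:
        idx = rng.permutation(n)
        subset_id[idx] = np.arange(n) % k
    return SubsetAssignment(subset_id=subset_id, k=k, seed=seed,
                            stratified=stratified)


def enumerate_separations(k: int = 10, n_test: int = 3
                          ) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All (train_subsets, test_subsets) pairs, lexicographic in the test side."""
    if not (0 < n_test < k):
        raise ValueError(f"n_test must be in (0, {k}), got {n_test}")
    out = []
    for test in combinations(range(k), n_test):
        train = tuple(s for s in range(k) if s not in test)
        out.append((train, test))
    return out


def cross_validated_accuracy(
    epochs: EpochSet,
    m_filters: int = 10,
    k: int = 10,
    n_test: int = 3,
    stratified: bool = True,
    seed=0,
    normalization: str = "trace_per_trial",
    ridge: float = 0.0,
) -> CVResult:
    """Session accuracy: CSP + Fisher LDA over every k-choose-n_test split.

    For each separation a fresh filter bank (``m_filters`` filters) and LDA
    line are fit on the 7 training subsets and scored on the 3 test subsets.
    Per-trial covariances are computed once and reused across separations
    (the per-fold fit only ever needs covariance averages and the identity
    var(w^T X) = w^T C w).
    """
    assignment = make_subsets(epochs, k=k, stratified=stratified, seed=seed)
    separations = enumerate_separations(k=k, n_test=n_test)

    covs_raw = trial_covariances(epochs)
    traces = np.trace(covs_raw, axis1=1, axis2=2)
    if normalization == "trace_per_trial":
        covs_norm = covs_raw / traces[:, None, None]
    elif normalization == "pooled":
        covs_norm = covs_raw
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    labels = epochs.labels
    class_masks = {c: labels == c for c in CLASSES}

    rates = np.empty(len(separations))
    for i, (train, test) in enumerate(separations):
        train_mask = np.isin(assignment.subset_id, train)
        test_mask = ~train_mask
        counts = {}
        for c in CLASSES:
            m = train_mask & class_masks[c]
            counts[c] = int(m.sum())
            if counts[c] < 2:
                raise ValueError(
                    f"training fold {i} has {counts[c]} trial(s) of class "
                    f"{c!r}; enable stratified subsets")
        covs = ClassCovariances(
            cov_left=covs_norm[train_mask & class_masks["left"]].mean(axis=0),
            cov_right=covs_norm[train_mask & class_masks["right"]].mean(axis=0),
            n_trials_per_class=counts, normalization=normalization)
        bank = csp_filters(covs, m=m_filters, ridge=ridge)
        W = bank.filters
        feats = np.log(np.einsum("fc,icd,fd->if", W, covs_raw, W))
        model = flda_train(feats[train_mask], labels[train_mask], ridge=ridge)
        rates[i] = classify_accuracy(model, feats[test_mask], labels[test_mask])

    return CVResult(per_separation_accuracy=rates,
                    mean_accuracy=float(rates.mean() * 100.0),
                    accuracy_sd=float(rates.std(ddof=0) * 100.0),
                    m_filters=m_filters, seed=seed, n_trials=epochs.n_trials)


def run_wise_accuracy(
    epochs: EpochSet,
    m_filters: int = 6,
    k: int = 10,
    n_test: int = 3,
    stratified: bool = True,
    seed=0,
    **kwargs,
) -> list[CVResult]:
    """Apply the same cross-validation independently to each run's trials."""
    results = []
    for run in epochs.runs():
        sub = epochs.select(epochs.run_index == run)
        counts = sub.class_counts()
        missing = [c for c in CLASSES if counts[c] == 0]
        if missing:
            raise ValueError(f"run {run} has no trials of class {missing}")
        results.append(cross_validated_accuracy(
            sub, m_filters=m_filters, k=k, n_test=n_test,
            stratified=stratified, seed=[_as_int(seed), run], **kwargs))
    return results


def _as_int(seed) -> int:
    if isinstance(seed, (list, tuple, np.ndarray)):
        return int(seed[0])
    return int(seed)
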