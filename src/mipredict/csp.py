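"""Common Spatial Patterns and Fisher linear discriminant classification.

CSP solves the generalized eigenproblem

    sigma_left w = lambda (sigma_left + sigma_right) w

so each eigenvalue lambda in [0, 1] is the fraction of (composite-normalized)
variance a filter captures for the left class. Filters from both ends of the
spectrum are kept — the m/2 with the largest lambda (high left-class
variance) and the m/2 with the smallest (high right-class variance). Under
the composite normalization W (sigma_left + sigma_right) W^T = I.

Features are the log of the per-trial variance of each filtered projection;
classification is Fisher LDA: w ∝ S_w^{-1} (mu_left − mu_right) with the
threshold at the midpoint of the projected class means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .preprocess import EpochSet, CLASSES

__all__ = [
    "ClassCovariances",
    "SpatialFilterBank",
    "LDAModel",
    "trial_covariances",
    "class_covariances",
    "csp_filters",
    "csp_features",
    "flda_train",
    "classify",
    "classify_accuracy",
]

_SYM_TOL = 1e-8


@dataclass
class ClassCovariances:
    cov_left: np.ndarray
    cov_right: np.ndarray
    n_trials_per_class: dict[str, int]
    normalization: str = "trace_per_trial"

    def __post_init__(self):
        for name, c in (("cov_left", self.cov_left), ("cov_right", self.cov_right)):
            if c.ndim != 2 or c.shape[0] != c.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(c, c.T, atol=_SYM_TOL * max(1.0, np.abs(c).max())):
                raise ValueError(f"{name} is not symmetric")


@dataclass
class SpatialFilterBank:
    """m spatial filters (rows of W) with their left-class variance ratios."""

    filters: np.ndarray      # m x channels
    eigenvalues: np.ndarray  # m values in [0, 1]
    m: int

    def __post_init__(self):
        if self.filters.shape[0] != self.m or len(self.eigenvalues) != self.m:
            raise ValueError("filter/eigenvalue count mismatch with m")
        if self.m % 2 != 0:
            raise ValueError("m must be even")

    def to_json_dict(self) -> dict:
        return {"m": self.m,
                "shape": list(self.filters.shape),
                "filters": self.filters.ravel().tolist(),
                "eigenvalues": self.eigenvalues.tolist()}

    @classmethod
    def from_json_dict(cls, d: dict) -> "SpatialFilterBank":
        W = np.array(d["filters"], dtype=float).reshape(d["shape"])
        return cls(W, np.array(d["eigenvalues"], dtype=float), int(d["m"]))


@dataclass
class LDAModel:
    weights: np.ndarray
    bias: float
    class_order: tuple[str, str] = CLASSES

    def __post_init__(self):
        if np.linalg.norm(self.weights) == 0:
            raise ValueError("degenerate LDA model: zero weight vector")

    def to_json_dict(self) -> dict:
        return {"weights": self.weights.tolist(), "bias": self.bias,
                "class_order": list(self.class_order)}

    @classmethod
    def from_json_dict(cls, d: dict) -> "LDAModel":
        return cls(np.array(d["weights"], dtype=float), float(d["bias"]),
                   tuple(d["class_order"]))


def trial_covariances(epochs: EpochSet) -> np.ndarray:
    """Per-trial channel covariance (demeaned, ddof=1): trials x ch x ch.

    The building block shared by covariance averaging and the log-variance
    feature shortcut var(w^T X) = w^T C w.
    """
    X = epochs.epochs - epochs.epochs.mean(axis=2, keepdims=True)
    T = X.shape[2]
    if T < 2:
        raise ValueError("epochs must have at least 2 samples")
    return np.einsum("ict,idt->icd", X, X) / (T - 1)


def class_covariances(epochs: EpochSet,
                      normalization: str = "trace_per_trial") -> ClassCovariances:
    """Average per-trial covariances per class.

    With the default normalization each trial's covariance is divided by its
    trace before averaging, making the estimate robust to trial-to-trial
    amplitude differences (standard CSP practice).
    """
    if epochs.n_channels < 2:
        raise ValueError("need at least 2 channels")
    counts = epochs.class_counts()
    for c in CLASSES:
        if counts[c] < 2:
            raise ValueError(f"need >= 2 trials for class {c!r}, got {counts[c]}")
    covs = trial_covariances(epochs)
    if normalization == "trace_per_trial":
        covs = covs / np.trace(covs, axis1=1, axis2=2)[:, None, None]
    elif normalization != "pooled":
        raise ValueError(f"unknown normalization {normalization!r}")
    out = {}
    for c in CLASSES:
        avg = covs[epochs.labels == c].mean(axis=0)
        out[c] = 0.5 * (avg + avg.T)
    return ClassCovariances(cov_left=out["left"], cov_right=out["right"],
                            n_trials_per_class=counts,
                            normalization=normalization)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Make the first coefficient of nonneglible magnitude positive, per filter."""
    out = W.copy()
    for i, row in enumerate(out):
        nz = np.flatnonzero(np.abs(row) > 1e-12 * np.abs(row).max())
        if len(nz) and row[nz[0]] < 0:
            out[i] = -row
    return out


def csp_filters(covs: ClassCovariances, m: int = 10,
                ridge: float = 0.0) -> SpatialFilterBank:
    """Extract the m most discriminative CSP filters (m/2 from each end).

    ``ridge`` adds eps * trace/channels to the composite covariance diagonal
    when it is (near-)singular.
    """
    if m % 2 != 0 or m <= 0:
        raise ValueError(f"m must be a positive even number, got {m}")
    n_ch = covs.cov_left.shape[0]
    if m > n_ch:
        raise ValueError(f"m={m} exceeds channel count {n_ch}")
    composite = covs.cov_left + covs.cov_right
    if ridge > 0:
        composite = composite + ridge * np.trace(composite) / n_ch * np.eye(n_ch)
    try:
        evals, evecs = linalg.eigh(covs.cov_left, composite)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "composite covariance is singular; pass ridge > 0 (e.g. 1e-6) "
            "to regularize") from exc
    if not np.all(np.isfinite(evals)):
        raise np.linalg.LinAlgError(
            "eigen-decomposition produced non-finite eigenvalues; pass "
            "ridge > 0 to regularize")
    order = np.argsort(evals)[::-1]  # descending lambda
    half = m // 2
    keep = np.concatenate([order[:half], order[-half:]])
    W = _fix_signs(evecs[:, keep].T)
    return SpatialFilterBank(filters=W,
                             eigenvalues=np.clip(evals[keep], 0.0, 1.0), m=m)


def csp_features(epochs: EpochSet, bank: SpatialFilterBank,
                 _covs: np.ndarray | None = None) -> np.ndarray:
    """Log-variance features, trials x m.

    ``_covs`` optionally reuses precomputed per-trial covariances, since
    var(w^T X) = w^T C w (exact identity, not an approximation).
    """
    if bank.filters.shape[1] != epochs.n_channels:
        raise ValueError(
            f"filter bank expects {bank.filters.shape[1]} channels, "
            f"epochs have {epochs.n_channels}")
    covs = trial_covariances(epochs) if _covs is None else _covs
    W = bank.filters
    var = np.einsum("fc,icd,fd->if", W, covs, W)
    if np.any(var <= 0):
        raise ValueError("zero-variance projection: log-feature undefined")
    return np.log(var)


def flda_train(features: np.ndarray, labels: np.ndarray,
               ridge: float = 0.0) -> LDAModel:
    """Fisher LDA: w ∝ S_w^{-1}(mu_left − mu_right), midpoint threshold."""
    labels = np.asarray(labels)
    masks = {c: labels == c for c in CLASSES}
    for c in CLASSES:
        if masks[c].sum() < 2:
            raise ValueError(f"need >= 2 training trials for class {c!r}")
    mu = {c: features[masks[c]].mean(axis=0) for c in CLASSES}
    Sw = np.zeros((features.shape[1],) * 2)
    for c in CLASSES:
        d = features[masks[c]] - mu[c]
        Sw += d.T @ d
    if ridge > 0:
        Sw = Sw + ridge * np.trace(Sw) / Sw.shape[0] * np.eye(Sw.shape[0])
    delta = mu["left"] - mu["right"]
    try:
        w = linalg.solve(Sw, delta, assume_a="sym")
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "within-class scatter is singular; pass ridge > 0") from exc
    if not np.all(np.isfinite(w)) or np.linalg.norm(w) < 1e-12 * max(
            1.0, np.linalg.norm(delta)):
        raise ValueError(
            "degenerate discriminant (identical class means or singular "
            "scatter)")
    b = float(w @ (mu["left"] + mu["right"]) / 2.0)
    return LDAModel(weights=w, bias=b)


def classify(model: LDAModel, features: np.ndarray) -> np.ndarray:
    """Predicted labels; a score exactly on the boundary goes to class_order[0]."""
    scores = features @ model.weights - model.bias
    first, second = model.class_order
    return np.where(scores >= 0.0, first, second)


def classify_accuracy(model: LDAModel, features: np.ndarray,
                      labels: np.ndarray) -> float:
    """Correct rate: correctly classified trials / total trials, in [0, 1]."""
    if len(features) == 0:
        raise ValueError("empty feature set")
    if features.shape[1] != len(model.weights):
        raise ValueError("feature dimension does not match model")
    return float(np.mean(classify(model, features) == np.asarray(labels)))
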