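"""Correlation, permutation significance, FDR, rank-sum, RMSE, evolution.

Significance of a Pearson correlation is assessed non-parametrically: one of
the two vectors (by convention the accuracy vector) is shuffled 2,500 times
and the two-sided p-value is the add-one fraction of shuffles whose |r|
reaches the observed one — so p can never be exactly zero and its floor is
1/(n_perm + 1). Families of correlations are corrected with the
Benjamini–Hochberg step-up rule at q = 0.1. Group comparisons use the
two-sided Wilcoxon rank-sum test, exact for small tie-free groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "FdrResult",
    "RankSumResult",
    "EvolutionSeries",
    "DegenerateDataError",
    "pearson",
    "permutation_pvalue",
    "fdr_correct",
    "ranksum_test",
    "rmse",
    "describe",
    "count_below",
    "evolution_analysis",
    "permutation_r_thresholds",
]


class DegenerateDataError(ValueError):
    """A statistic is undefined on the given input (e.g. zero variance)."""


def _check_pair(x, y, min_n: int = 3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors, got "
                         f"{x.shape} and {y.shape}")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} observations, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError(
            "constant input vector: correlation undefined")
    return x, y


@dataclass
class CorrelationResult:
    r: float
    p_perm: float
    n_perm: int
    n: int
    seed: object

    def as_dict(self) -> dict:
        return {"r": self.r, "p_perm": self.p_perm, "n_perm": self.n_perm,
                "n": self.n, "seed": self.seed}


@dataclass
class FdrResult:
    raw_p: np.ndarray
    adjusted_p: np.ndarray
    rejected: np.ndarray
    q: float
    method: str = "bh"


@dataclass
class RankSumResult:
    p: float
    statistic: float
    method: str  # "exact" or "normal_approx"


@dataclass
class EvolutionSeries:
    """Prediction-vs-accuracy agreement across task stages.

    Stage 0 is the pre-task prediction; stages 1..n_runs the per-run ones.
    ``threshold_05``/``threshold_01`` are the |r| values a correlation must
    exceed to reach p = 0.05 / 0.01 under the permutation null at this n.
    """

    stages: list[str]
    r: np.ndarray
    p_perm: np.ndarray
    rmse: np.ndarray
    threshold_05: float
    threshold_01: float
    n: int
    n_perm: int
    seed: object

    def to_records(self) -> list[dict]:
        return [
            {"stage": s, "r": float(r), "p_perm": float(p), "rmse": float(e)}
            for s, r, p, e in zip(self.stages, self.r, self.p_perm, self.rmse)
        ]


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _check_pair(x, y)
    return float(np.corrcoef(x, y)[0, 1])


def _perm_r_distribution(x: np.ndarray, y: np.ndarray, n_perm: int,
                         rng: np.random.Generator) -> np.ndarray:
    """|r| under shuffles of y; vectorized over permutations."""
    xc = (x - x.mean()) / (x.std() * np.sqrt(len(x)))
    yc = (y - y.mean()) / (y.std() * np.sqrt(len(y)))
    perms = np.array([rng.permutation(len(y)) for _ in range(n_perm)])
    return np.abs(yc[perms] @ xc)


def permutation_pvalue(x, y, n_perm: int = 2500, seed=0) -> CorrelationResult:
    """Two-sided permutation test of a Pearson correlation.

    ``y`` is the shuffled vector (pass the accuracy there to match the
    shuffle-the-performance convention); by symmetry of r the null
    distribution is identical either way. p = (1 + #{|r_perm| >= |r_obs|})
    / (n_perm + 1).
    """
    x, y = _check_pair(x, y)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    null = _perm_r_distribution(x, y, n_perm, rng)
    b = int(np.sum(null >= abs(r_obs) - 1e-12))
    p = (1 + b) / (n_perm + 1)
    return CorrelationResult(r=r_obs, p_perm=float(p), n_perm=n_perm,
                             n=len(x), seed=seed)


def permutation_r_thresholds(accuracy, n_perm: int = 2500, seed=0,
                             levels=(0.05, 0.01)) -> tuple[float, ...]:
    """|r| needed to reach each significance level at this sample size.

    Estimated as upper quantiles of the null |r| distribution obtained by
    correlating the accuracy vector with shuffles of itself.
    """
    acc = np.asarray(accuracy, dtype=float)
    if np.ptp(acc) == 0:
        raise DegenerateDataError("constant accuracy vector")
    rng = np.random.default_rng(seed)
    null = _perm_r_distribution(acc, acc.copy(), n_perm, rng)
    return tuple(float(np.quantile(null, 1 - lev)) for lev in levels)


def fdr_correct(pvalues, q: float = 0.1, method: str = "bh") -> FdrResult:
    """Benjamini–Hochberg (or Benjamini–Yekutieli) step-up correction."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError(f"p-values must lie in [0, 1]: {p}")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if sm_method is None:
        raise ValueError(f"method must be 'bh' or 'by', got {method!r}")
    rejected, adjusted, _, _ = multipletests(p, alpha=q, method=sm_method)
    return FdrResult(raw_p=p, adjusted_p=adjusted, rejected=rejected, q=q,
                     method=method)


def ranksum_test(a, b) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Exact enumeration when both groups have <= 10 observations and there are
    no ties; otherwise the normal approximation with tie-corrected variance
    (no continuity correction, so identical groups give p = 1 exactly).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if tie_free and len(a) <= 10 and len(b) <= 10:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return RankSumResult(p=float(res.pvalue), statistic=float(res.statistic),
                             method="exact")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=False)
    return RankSumResult(p=float(res.pvalue), statistic=float(res.statistic),
                         method="normal_approx")


def rmse(predicted, actual) -> float:
    """Root mean square error, in the units of the inputs (here percent)."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.sqrt(np.mean((p - a) ** 2)))


def describe(x) -> dict:
    """Mean, median and sample standard deviation (n − 1 denominator)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return {"mean": float(x.mean()),
            "median": float(np.median(x)),
            "sd": float(x.std(ddof=1)) if x.size > 1 else 0.0}


def count_below(x, threshold: float = 60.0) -> int:
    """Count of values strictly below the threshold (chance-level rule)."""
    return int(np.sum(np.asarray(x, dtype=float) < threshold))


def evolution_analysis(
    predictions_by_stage: Mapping[str, Sequence[float]],
    accuracy: Sequence[float],
    n_perm: int = 2500,
    seed=0,
) -> EvolutionSeries:
    """Correlation and RMSE of each stage's predictions with session accuracy.

    ``predictions_by_stage`` maps ordered stage labels (e.g. ``pre-task``,
    ``run1``…``run5``) to per-subject prediction vectors; the same
    session-wise accuracy vector is used at every stage. Also returns the
    permutation |r| thresholds at p = 0.05 and p = 0.01 for this n.
    """
    acc = np.asarray(accuracy, dtype=float)
    stages = list(predictions_by_stage)
    missing = [s for s in stages
               if predictions_by_stage[s] is None
               or len(predictions_by_stage[s]) != len(acc)]
    if missing:
        raise ValueError(f"missing or mismatched predictions for stage(s) "
                         f"{missing}")
    rs, ps, errs = [], [], []
    for i, s in enumerate(stages):
        pred = np.asarray(predictions_by_stage[s], dtype=float)
        res = permutation_pvalue(pred, acc, n_perm=n_perm, seed=[_seed_int(seed), i])
        rs.append(res.r)
        ps.append(res.p_perm)
        errs.append(rmse(pred, acc))
    t05, t01 = permutation_r_thresholds(acc, n_perm=n_perm,
                                        seed=[_seed_int(seed), len(stages)])
    return EvolutionSeries(stages=stages, r=np.array(rs), p_perm=np.array(ps),
                           rmse=np.array(errs), threshold_05=t05,
                           threshold_01=t01, n=len(acc), n_perm=n_perm,
                           seed=seed)


def _seed_int(seed) -> int:
    if isinstance(seed, (list, tuple, np.ndarray)):
        return int(seed[0])
    return int(seed)
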