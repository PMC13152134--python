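"""AUC estimation and DeLong variance, confidence intervals, and tests.

The AUC is computed as the Mann-Whitney statistic: the probability that a
randomly chosen positive scores above a randomly chosen negative, with ties
counted 1/2. Its variance is estimated nonparametrically from DeLong's
structural components (per-positive and per-negative placement values),
giving Wald-type confidence intervals and z-tests for AUC differences —
paired (two score vectors on one sample) or unpaired (disjoint samples).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "RocResult",
    "UndefinedAucError",
    "DegenerateVarianceWarning",
    "auc_mann_whitney",
    "delong_ci",
    "delong_test_unpaired",
    "delong_test_paired",
]


class UndefinedAucError(ValueError):
    """AUC (or its variance) is undefined for the given sample."""


class DegenerateVarianceWarning(UserWarning):
    """A variance estimate is exactly zero; downstream quantities degenerate."""


@dataclass(frozen=True)
class RocResult:
    """AUC with its DeLong variance and confidence interval."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    level: float = 0.95


def _split_scores(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedAucError(
            f"AUC undefined: need both classes (n_pos={len(pos)}, n_neg={len(neg)})"
        )
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values via midranks.

    ``V10[i]`` is the fraction of negatives a positive beats (ties = 1/2);
    ``V01[j]`` the fraction of positives the j-th negative is beaten by.
    """
    m, n = len(pos), len(neg)
    ranks_all = rankdata(np.concatenate([pos, neg]))
    v10 = (ranks_all[:m] - rankdata(pos)) / n
    v01 = 1.0 - (ranks_all[m:] - rankdata(neg)) / m
    return v10, v01


def _auc_from_ranksum(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC via the rank-sum identity.

    The numerator (#{pos > neg} + 1/2 #{ties}) is a half-integer computed
    exactly, so the single division reproduces exhaustive pair counting
    bit-for-bit; averaging the per-positive placements does not.
    """
    m, n = len(pos), len(neg)
    ranks_all = rankdata(np.concatenate([pos, neg]))
    return float((ranks_all[:m].sum() - m * (m + 1) / 2) / (m * n))


def auc_mann_whitney(scores, labels) -> float:
    """Mann-Whitney AUC with the 1/2 tie convention."""
    pos, neg = _split_scores(scores, labels)
    return _auc_from_ranksum(pos, neg)


def delong_ci(scores, labels, level: float = 0.95) -> RocResult:
    """AUC with DeLong variance and a normal-approximation CI truncated to [0, 1].

    Zero-variance cases (e.g. perfect separation) return a point CI with a
    :class:`DegenerateVarianceWarning` rather than failing — they genuinely
    occur in desk-scale audits.
    """
    pos, neg = _split_scores(scores, labels)
    m, n = len(pos), len(neg)
    if m < 2 or n < 2:
        raise UndefinedAucError(
            f"DeLong variance undefined for n_pos={m}, n_neg={n} (need >= 2 each)"
        )
    v10, v01 = _placements(pos, neg)
    auc = _auc_from_ranksum(pos, neg)
    variance = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    if variance <= 0:
        warnings.warn(
            "DeLong variance is zero; returning a point confidence interval",
            DegenerateVarianceWarning,
            stacklevel=2,
        )
        variance = 0.0
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(variance)
    return RocResult(
        auc=auc,
        variance=variance,
        ci_low=float(max(0.0, auc - half)),
        ci_high=float(min(1.0, auc + half)),
        n_pos=m,
        n_neg=n,
        level=level,
    )


_ALTERNATIVES = ("greater", "less", "two_sided")


def _p_from_z(z: float, alternative: str) -> float:
    if alternative == "greater":
        return float(norm.sf(z))
    if alternative == "less":
        return float(norm.cdf(z))
    return float(2 * norm.sf(abs(z)))


def _degenerate_p(auc1: float, auc2: float, alternative: str) -> float:
    warnings.warn(
        "zero variance in AUC comparison; p-value is degenerate",
        DegenerateVarianceWarning,
        stacklevel=3,
    )
    if np.isclose(auc1, auc2):
        return 1.0
    if alternative == "greater":
        return 0.0 if auc1 > auc2 else 1.0
    if alternative == "less":
        return 0.0 if auc1 < auc2 else 1.0
    return 0.0


def delong_test_unpaired(
    r1: RocResult, r2: RocResult, alternative: str = "greater"
) -> float:
    """DeLong z-test for AUCs estimated on disjoint samples.

    ``alternative='greater'`` tests AUC1 > AUC2.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    var_sum = r1.variance + r2.variance
    if var_sum <= 0:
        return _degenerate_p(r1.auc, r2.auc, alternative)
    z = (r1.auc - r2.auc) / np.sqrt(var_sum)
    return _p_from_z(float(z), alternative)


def delong_test_paired(
    scores1, scores2, labels, alternative: str = "two_sided"
) -> float:
    """DeLong test for two score vectors evaluated on the same labelled sample.

    The variance of the AUC difference uses the covariance of the two sets of
    placement values, so concordant scores are not penalised twice.
    """
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")
    pos1, neg1 = _split_scores(scores1, labels)
    pos2, neg2 = _split_scores(scores2, labels)
    m, n = len(pos1), len(neg1)
    if m < 2 or n < 2:
        raise UndefinedAucError(
            f"DeLong variance undefined for n_pos={m}, n_neg={n} (need >= 2 each)"
        )
    v10_1, v01_1 = _placements(pos1, neg1)
    v10_2, v01_2 = _placements(pos2, neg2)
    auc1, auc2 = float(v10_1.mean()), float(v10_2.mean())
    s10 = np.cov(v10_1, v10_2, ddof=1)
    s01 = np.cov(v01_1, v01_2, ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    var_diff += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    var_diff = max(0.0, float(var_diff))
    if var_diff <= 0:
        return _degenerate_p(auc1, auc2, alternative)
    z = (auc1 - auc2) / np.sqrt(var_diff)
    return _p_from_z(float(z), alternative)
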