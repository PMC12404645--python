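"""Representational similarity analysis.

RDMs summarise the representational geometry of a signal space as the
K x K matrix of pairwise condition dissimilarities: 1 - Pearson's r for
model feature patterns, pairwise decoding accuracy for brain data.  RDMs
from different spaces (EEG time points, fMRI ROIs, model layers) are
compared by Spearman correlation of their lower triangles; noise ceilings
bound the attainable correlation given inter-subject variability, and
commonality analysis partitions the variance of a target RDM shared
between two predictor RDMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "rdm_from_features",
    "lower_triangle",
    "rdm_correlate",
    "CeilingPair",
    "noise_ceiling",
    "commonality",
    "commonality_decomposition",
]


def rdm_from_features(features: np.ndarray) -> np.ndarray:
    """1 - Pearson dissimilarity matrix of item feature patterns.

    ``features`` is items x dimensions.  The diagonal is undefined and
    returned as NaN.  Raises if any item has a constant feature vector
    (its correlations, hence dissimilarities, would be undefined).
    """
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] < 2:
        raise ValueError("features must be items x dimensions with >= 2 dimensions")
    if np.any(features.std(axis=1) == 0):
        bad = np.flatnonzero(features.std(axis=1) == 0)
        raise ValueError(
            f"constant feature vector for item(s) {bad.tolist()}: "
            "1-Pearson dissimilarity undefined"
        )
    rdm = 1.0 - np.corrcoef(features)
    np.fill_diagonal(rdm, np.nan)
    return rdm


def lower_triangle(rdm: np.ndarray) -> np.ndarray:
    """Vectorized lower triangle of a square RDM, diagonal excluded."""
    rdm = np.asarray(rdm, dtype=float)
    if rdm.ndim != 2 or rdm.shape[0] != rdm.shape[1]:
        raise ValueError("rdm must be square")
    i, j = np.tril_indices(rdm.shape[0], k=-1)
    return rdm[i, j]


def rdm_correlate(a: np.ndarray, b: np.ndarray, method: str = "spearman") -> float:
    """Correlate two RDMs on their lower triangles (diagonal excluded)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("RDMs must have the same shape")
    if a.shape[0] < 4:
        warnings.warn(
            f"only {a.shape[0]} conditions -> "
            f"{a.shape[0] * (a.shape[0] - 1) // 2} pairs; correlation unstable",
            stacklevel=2,
        )
    va, vb = lower_triangle(a), lower_triangle(b)
    if method == "spearman":
        r = stats.spearmanr(va, vb).statistic
    elif method == "pearson":
        r = stats.pearsonr(va, vb).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r)


@dataclass(frozen=True)
class CeilingPair:
    """Lower and upper noise-ceiling bounds (correlation units)."""

    lower: float
    upper: float


def noise_ceiling(
    subject_rdms: np.ndarray, method: str = "spearman"
) -> CeilingPair:
    """Noise-ceiling bounds for group RSA.

    Lower bound: mean over subjects of the correlation between each
    subject's RDM and the average RDM of all *other* subjects.  Upper
    bound: same with the average over *all* subjects (self included).
    """
    subject_rdms = np.asarray(subject_rdms, float)
    if subject_rdms.ndim != 3 or subject_rdms.shape[0] < 3:
        raise ValueError("need >= 3 subject RDMs (subjects x K x K)")
    n = subject_rdms.shape[0]
    grand = subject_rdms.mean(axis=0)
    lower = np.empty(n)
    upper = np.empty(n)
    for s in range(n):
        others = (grand * n - subject_rdms[s]) / (n - 1)
        lower[s] = rdm_correlate(subject_rdms[s], others, method)
        upper[s] = rdm_correlate(subject_rdms[s], grand, method)
    return CeilingPair(lower=float(lower.mean()), upper=float(upper.mean()))


def _rank_vectors(*rdms: np.ndarray) -> list[np.ndarray]:
    return [stats.rankdata(lower_triangle(r)) for r in rdms]


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """Coefficient of determination of an OLS fit with intercept."""
    X1 = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(X1, y, rcond=None)
    resid = y - X1 @ coef
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("target RDM has zero rank variance")
    return float(1.0 - np.sum(resid**2) / tss)


def commonality_decomposition(
    target: np.ndarray, predictor_a: np.ndarray, predictor_b: np.ndarray
) -> dict[str, float]:
    """Two-predictor variance partitioning of a target RDM.

    All three RDMs are vectorized (lower triangle) and rank-transformed.
    With R2(x) the coefficient of determination of the target regressed
    on predictor set x::

        common   = R2(a) + R2(b) - R2(a, b)
        unique_a = R2(a, b) - R2(b)
        unique_b = R2(a, b) - R2(a)

    so that ``common + unique_a + unique_b = R2(a, b)`` identically.  The
    commonality coefficient may be negative (suppression).
    """
    t, a, b = _rank_vectors(target, predictor_a, predictor_b)
    if not (len(t) == len(a) == len(b)):
        raise ValueError("RDMs must have matching condition counts")
    ra = np.corrcoef(a, b)[0, 1]
    if abs(ra) > 0.999:
        warnings.warn(
            f"predictors nearly collinear (|r| = {abs(ra):.4f}); "
            "commonality unstable",
            stacklevel=2,
        )
    r2_a = _r2(t, a[:, None])
    r2_b = _r2(t, b[:, None])
    r2_full = _r2(t, np.column_stack([a, b]))
    common = r2_a + r2_b - r2_full
    return {
        "common": common,
        "unique_a": r2_full - r2_b,
        "unique_b": r2_full - r2_a,
        "r2_a": r2_a,
        "r2_b": r2_b,
        "r2_full": r2_full,
    }


def commonality(
    target: np.ndarray, predictor_a: np.ndarray, predictor_b: np.ndarray
) -> float:
    """Shared variance of the target RDM explained by both predictors."""
    return commonality_decomposition(target, predictor_a, predictor_b)["common"]
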