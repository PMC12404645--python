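"""Group-level resampling inference.

All tests are distribution-free: the null distribution is generated by
randomly flipping the sign of each participant's effect (valid under the
null hypothesis that the group effect is symmetric around zero), the
identity flip is always included so p-values are bounded below by
1/n_perm, and family-wise error over contiguous grids (time courses,
time x time or time x frequency matrices, volumes) is controlled by
cluster-based inference on the permutation distribution of the maximum
supra-threshold cluster size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "sign_perm_test",
    "cluster_inference",
    "fdr_bh",
    "bootstrap_peak_ci",
    "peak_shift_test",
    "hedges_g",
]


def _sign_flips(
    n_perm: int, n_subjects: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, n_subjects) sign matrix; row 0 is the identity flip."""
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_subjects))
    signs[0] = 1.0
    return signs


def _tail_stat(means: np.ndarray, tail: str) -> np.ndarray:
    if tail == "right":
        return means
    if tail == "left":
        return -means
    if tail == "two":
        return np.abs(means)
    raise ValueError(f"tail must be 'right', 'left' or 'two', got {tail!r}")


def sign_perm_test(
    subject_values: np.ndarray,
    n_perm: int = 10000,
    tail: str = "right",
    rng: np.random.Generator | int | None = None,
):
    """Sign-permutation test of the group mean against zero.

    ``subject_values`` is ``(n_subjects,)`` or ``(n_subjects, *grid)``;
    each subject's data are multiplied by a random +/-1 and the group
    mean recomputed for ``n_perm`` permutations (the observed sample is
    included as one of them, so ``p >= 1/n_perm``).  Returns a scalar p
    or a p-map over the grid.
    """
    rng = np.random.default_rng(rng)
    values = np.asarray(subject_values, float)
    if values.shape[0] < 2:
        raise ValueError("need >= 2 subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value grid", stacklevel=2)
    flat = values.reshape(values.shape[0], -1)
    signs = _sign_flips(n_perm, values.shape[0], rng)
    perm_means = signs @ flat / values.shape[0]  # (n_perm, V)
    stat = _tail_stat(perm_means, tail)
    p = (stat >= stat[0]).mean(axis=0)
    return float(p[0]) if values.ndim == 1 else p.reshape(values.shape[1:])


@dataclass
class StatResult:
    """Cluster-inference output.

    ``point_p`` is the per-point permutation p-map, ``cluster_labels``
    the integer labelling of supra-threshold clusters (0 = background),
    ``cluster_p`` maps cluster id to its family-wise p, and ``sig_mask``
    marks points in clusters surviving the cluster threshold.
    """

    stat_map: np.ndarray
    point_p: np.ndarray
    cluster_labels: np.ndarray
    cluster_p: dict[int, float]
    sig_mask: np.ndarray
    max_cluster_null: np.ndarray = field(repr=False, default=None)


def _orthogonal_structure(ndim: int) -> np.ndarray:
    """Adjacency with orthogonal neighbours only (2/4/6 in 1/2/3-D)."""
    return ndimage.generate_binary_structure(ndim, 1)


def cluster_inference(
    effect_maps: np.ndarray,
    cdt: float = 0.005,
    alpha: float = 0.05,
    n_perm: int = 1000,
    tail: str = "right",
    rng: np.random.Generator | int | None = None,
) -> StatResult:
    """Cluster-size-based family-wise inference on a 1/2/3-D grid.

    For the observed data and every sign permutation, a per-point p-map
    is computed from the permutation distribution at that point, points
    with p < ``cdt`` (cluster definition threshold) are grouped into
    clusters by orthogonal adjacency, and clusters are scored by size.
    The null distribution of the *maximum* cluster size across the grid
    yields each observed cluster's family-wise p; clusters with
    p < ``alpha`` are significant.
    """
    rng = np.random.default_rng(rng)
    maps = np.asarray(effect_maps, float)
    if maps.ndim < 2 or maps.ndim > 4:
        raise ValueError("effect_maps must be subjects x 1/2/3-D grid")
    n_sub = maps.shape[0]
    if n_sub < 2:
        raise ValueError("need >= 2 subjects")
    grid_shape = maps.shape[1:]
    flat = maps.reshape(n_sub, -1)

    signs = _sign_flips(n_perm, n_sub, rng)
    perm_means = signs @ flat / n_sub  # (n_perm, V)
    stat = _tail_stat(perm_means, tail)
    # p of every permutation sample at every point within the pointwise null:
    # p_j(v) = #{i : stat_i(v) >= stat_j(v)} / n_perm, ties counted inclusively
    p_all = np.empty_like(stat)
    for v in range(stat.shape[1]):
        col = np.sort(stat[:, v])
        p_all[:, v] = 1.0 - np.searchsorted(col, stat[:, v], side="left") / n_perm

    supra = p_all < cdt  # (n_perm, V)
    structure = _orthogonal_structure(len(grid_shape))
    max_null = np.zeros(n_perm)
    for i in range(n_perm):
        labels, n_clusters = ndimage.label(
            supra[i].reshape(grid_shape), structure=structure
        )
        if n_clusters:
            sizes = np.bincount(labels.ravel())[1:]
            max_null[i] = sizes.max()

    obs_labels, n_obs = ndimage.label(
        supra[0].reshape(grid_shape), structure=structure
    )
    cluster_p: dict[int, float] = {}
    sig = np.zeros(grid_shape, bool)
    for c in range(1, n_obs + 1):
        size = int((obs_labels == c).sum())
        p = float((max_null >= size).mean())
        cluster_p[c] = p
        if p < alpha:
            sig |= obs_labels == c
    return StatResult(
        stat_map=flat.mean(axis=0).reshape(grid_shape),
        point_p=p_all[0].reshape(grid_shape),
        cluster_labels=obs_labels,
        cluster_p=cluster_p,
        sig_mask=sig,
        max_cluster_null=max_null,
    )


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        return np.zeros(pvals.shape, bool)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvals.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(pvals.shape)


def bootstrap_peak_ci(
    subject_curves: np.ndarray,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
    coords: np.ndarray | None = None,
    ci: float = 95.0,
) -> tuple[float, float]:
    """Bootstrap confidence interval of the group-mean curve's peak.

    Participants are resampled with replacement ``n_boot`` times; for
    each bootstrap sample the argmax of the mean curve is recorded (ties
    broken toward the earliest coordinate), and the interval spans the
    (100-ci)/2 and (100+ci)/2 percentiles of that distribution, reported
    in ``coords`` units (curve indices if coords is None).
    """
    rng = np.random.default_rng(rng)
    curves = np.asarray(subject_curves, float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise ValueError("need >= 2 subjects of curves (subjects x points)")
    n_sub, n_pts = curves.shape
    if coords is None:
        coords = np.arange(n_pts, dtype=float)
    coords = np.asarray(coords, float)
    if np.ptp(curves.mean(axis=0)) == 0:
        warnings.warn(
            "flat group-mean curve: peak undefined, CI spans the full domain",
            stacklevel=2,
        )
        return float(coords[0]), float(coords[-1])
    idx = rng.integers(0, n_sub, size=(n_boot, n_sub))
    boot_means = curves[idx].mean(axis=1)  # (n_boot, n_pts)
    peaks = coords[np.argmax(boot_means, axis=1)]  # argmax -> earliest tie
    lo, hi = np.percentile(peaks, [(100 - ci) / 2, (100 + ci) / 2])
    return float(lo), float(hi)


def hedges_g(diff: np.ndarray) -> float:
    """Hedges' g for paired differences (small-sample-corrected d_z)."""
    diff = np.asarray(diff, float)
    n = diff.size
    sd = diff.std(ddof=1)
    if sd == 0:
        return 0.0
    d = diff.mean() / sd
    correction = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    return float(d * correction)


def peak_shift_test(
    cond_a: np.ndarray,
    cond_b: np.ndarray,
    n_perm: int = 10000,
    rng: np.random.Generator | int | None = None,
    coords: np.ndarray | None = None,
) -> tuple[float, float]:
    """Two-tailed permutation test of a paired peak difference + Hedges' g.

    ``cond_a``/``cond_b`` are per-subject peak values ``(n_subjects,)``
    or per-subject curves ``(n_subjects, n_points)``, in which case each
    subject's peak coordinate (argmax, earliest tie) is extracted first.
    The null reassigns condition labels within each participant, which
    for the mean difference is a sign flip of the paired differences.
    Returns ``(p_two_tailed, hedges_g)``.
    """
    rng = np.random.default_rng(rng)
    a = np.asarray(cond_a, float)
    b = np.asarray(cond_b, float)
    if a.shape != b.shape:
        raise ValueError("conditions must be paired (same shape)")
    if a.ndim == 2:
        if coords is None:
            coords = np.arange(a.shape[1], dtype=float)
        coords = np.asarray(coords, float)
        a = coords[np.argmax(a, axis=1)]
        b = coords[np.argmax(b, axis=1)]
    if a.size < 3:
        raise ValueError("need >= 3 subjects")
    diff = a - b
    p = sign_perm_test(diff, n_perm=n_perm, tail="two", rng=rng)
    return float(p), hedges_g(diff)
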