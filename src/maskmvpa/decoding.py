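"""Pairwise linear-SVM decoding over time, time x time, time x frequency,
ROIs and searchlight spheres, within and across masking conditions.

Every analysis follows the same core recipe: trials of each condition
cell are randomly averaged into a small number of pseudo-trials to raise
SNR, a linear support vector machine is trained to discriminate one pair
of object conditions with leave-one-pseudo-trial-out cross-validation,
and the fold-averaged percent-correct values are arranged into a K x K
accuracy matrix (symmetric, diagonal undefined) that doubles as a neural
RDM.  The whole procedure is repeated with fresh random pseudo-trial
assignments and averaged.

Cross-condition decoding trains on pseudo-trials from one masking
condition and tests on the held-out pseudo-trial index of the other,
averaging both train/test directions: preserved accuracy across
conditions indicates shared representational geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "AccuracyMatrix",
    "TimecourseResult",
    "TGM",
    "SearchlightMap",
    "bin_pseudotrials",
    "pairwise_accuracy",
    "decode_timecourse",
    "temporal_generalization",
    "feature_array",
    "timefreq_decode",
    "roi_decode",
    "searchlight_decode",
    "aggregate_pairs",
]

CHANCE = 50.0


def _new_svm() -> SVC:
    # libsvm-backed linear maximum-margin classifier, fixed C, no scaling:
    # features are expected to be noise-normalized upstream
    return SVC(kernel="linear", C=1.0)


@dataclass
class AccuracyMatrix:
    """K x K pairwise percent-correct matrix; diagonal undefined (NaN)."""

    values: np.ndarray
    conditions: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        k = self.values.shape[0]
        if self.values.shape != (k, k):
            raise ValueError("values must be square")

    @property
    def grand_mean(self) -> float:
        """Mean over off-diagonal cells only."""
        i, j = np.tril_indices(self.values.shape[0], k=-1)
        return float(np.nanmean(self.values[i, j]))

    def as_rdm(self) -> np.ndarray:
        """The matrix itself: decoding accuracy is the neural dissimilarity."""
        return self.values.copy()


@dataclass
class TimecourseResult:
    """Per-time-point accuracy matrices from time-resolved decoding."""

    matrices: np.ndarray  # (n_times, K, K)
    time_ms: np.ndarray
    conditions: np.ndarray
    scheme: str

    def grand_average(self) -> np.ndarray:
        """Grand-average decoding accuracy time course (percent)."""
        i, j = np.tril_indices(self.matrices.shape[1], k=-1)
        return np.nanmean(self.matrices[:, i, j], axis=1)

    def matrix_at(self, t_ms: float) -> AccuracyMatrix:
        idx = int(np.argmin(np.abs(self.time_ms - t_ms)))
        return AccuracyMatrix(self.matrices[idx], self.conditions)


@dataclass
class TGM:
    """Temporal generalization matrix: train time x test time accuracy."""

    values: np.ndarray  # (n_times, n_times) grand-average percent
    time_ms: np.ndarray
    symmetrized: bool = False

    def symmetrize(self) -> "TGM":
        """Average both train/test directions (the directions carry no
        interpretable meaning)."""
        return TGM(
            values=(self.values + self.values.T) / 2.0,
            time_ms=self.time_ms.copy(),
            symmetrized=True,
        )


@dataclass
class SearchlightMap:
    """Per-voxel grand-average accuracy; NaN outside the brain mask."""

    values: np.ndarray  # 3-D
    radius: float
    mask: np.ndarray


def bin_pseudotrials(
    trials: np.ndarray, n_bins: int = 4, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Randomly group trials into ``n_bins`` equal bins and average.

    ``trials`` is ``(n_trials, ...)``.  Bin size is ``n_trials // n_bins``;
    surplus trials are dropped uniformly at random.
    """
    trials = np.asarray(trials, float)
    n = trials.shape[0]
    if n < n_bins:
        raise ValueError(f"{n} trials cannot fill {n_bins} pseudo-trial bins")
    if rng is None:
        rng = np.random.default_rng()
    per_bin = n // n_bins
    order = rng.permutation(n)[: n_bins * per_bin]
    return trials[order].reshape((n_bins, per_bin) + trials.shape[1:]).mean(axis=1)


def pairwise_accuracy(pseudo_a: np.ndarray, pseudo_b: np.ndarray) -> float:
    """Leave-one-pseudo-trial-out SVM accuracy for one condition pair.

    ``pseudo_a``/``pseudo_b`` are ``(n_bins, n_features)``.  Each fold
    trains on the remaining pseudo-trials of both classes and tests on
    the held-out pseudo-trial of each class; returns percent correct.
    """
    pseudo_a = np.atleast_2d(np.asarray(pseudo_a, float))
    pseudo_b = np.atleast_2d(np.asarray(pseudo_b, float))
    if pseudo_a.shape != pseudo_b.shape:
        raise ValueError("classes must have equal pseudo-trial counts")
    n_bins = pseudo_a.shape[0]
    if n_bins < 2:
        raise ValueError("need >= 2 pseudo-trials per class for leave-one-out")
    clf = _new_svm()
    y = np.repeat([0, 1], n_bins - 1)
    correct = 0
    for fold in range(n_bins):
        keep = np.arange(n_bins) != fold
        clf.fit(np.vstack([pseudo_a[keep], pseudo_b[keep]]), y)
        pred = clf.predict(np.vstack([pseudo_a[fold], pseudo_b[fold]]))
        correct += int(pred[0] == 0) + int(pred[1] == 1)
    return 100.0 * correct / (2 * n_bins)


def _group_cells(data, object_label, mask_label):
    """dict (mask, object) -> trial feature array (n, F, T)."""
    cells: dict[tuple[str, int], np.ndarray] = {}
    objects = np.unique(object_label)
    for mask in np.unique(mask_label):
        sel_m = mask_label == mask
        for obj in objects:
            idx = np.flatnonzero(sel_m & (object_label == obj))
            if idx.size:
                cells[(str(mask), int(obj))] = data[idx]
    return cells, objects


def _parse_scheme(scheme: str, masks: np.ndarray) -> tuple[str, list]:
    masks = [str(m) for m in masks]
    if scheme == "cross":
        if len(masks) < 2:
            raise ValueError("cross-condition decoding needs two mask conditions")
        return "cross", [(masks[0], masks[1]), (masks[1], masks[0])]
    if scheme.startswith("within-"):
        mask = scheme[len("within-") :]
        if mask not in masks:
            raise ValueError(f"mask condition {mask!r} not present in the data")
        return "within", [(mask, mask)]
    raise ValueError(f"unknown scheme {scheme!r}; use 'within-<mask>' or 'cross'")


def _decode_core(
    data: np.ndarray,
    object_label: np.ndarray,
    mask_label: np.ndarray,
    scheme: str,
    n_reps: int,
    rng: np.random.Generator,
    n_bins: int,
    generalize: bool,
) -> np.ndarray:
    """Shared engine for time-resolved and time-generalization decoding.

    Returns ``(T, K, K)`` accuracy (time-resolved) or ``(T, T, K, K)``
    (generalization).  Pseudo-trial binning is re-drawn independently per
    repetition and, for cross-decoding, per direction.
    """
    cells, objects = _group_cells(data, object_label, mask_label)
    _, directions = _parse_scheme(scheme, np.unique(mask_label))
    k = objects.size
    n_t = data.shape[2]
    shape = (n_t, n_t, k, k) if generalize else (n_t, k, k)
    acc = np.zeros(shape)
    clf = _new_svm()
    y_train = np.repeat([0, 1], n_bins - 1)
    pairs = list(combinations(range(k), 2))

    for _ in range(n_reps):
        for train_mask, test_mask in directions:
            pseudo_train = np.stack(
                [bin_pseudotrials(cells[(train_mask, int(o))], n_bins, rng)
                 for o in objects]
            )  # (K, n_bins, F, T)
            if test_mask == train_mask:
                pseudo_test = pseudo_train
            else:
                pseudo_test = np.stack(
                    [bin_pseudotrials(cells[(test_mask, int(o))], n_bins, rng)
                     for o in objects]
                )
            for ia, ib in pairs:
                for fold in range(n_bins):
                    keep = np.arange(n_bins) != fold
                    tr_a = pseudo_train[ia][keep]
                    tr_b = pseudo_train[ib][keep]
                    te = np.stack([pseudo_test[ia][fold], pseudo_test[ib][fold]])
                    for t in range(n_t):
                        clf.fit(
                            np.vstack([tr_a[..., t], tr_b[..., t]]), y_train
                        )
                        if generalize:
                            # one prediction pass over every test time point
                            flat = np.concatenate(
                                [te[0].T, te[1].T]
                            )  # (2*n_t, F)
                            pred = clf.predict(flat)
                            hits = (pred[:n_t] == 0).astype(float) + (
                                pred[n_t:] == 1
                            ).astype(float)
                            acc[t, :, ia, ib] += hits / 2.0
                        else:
                            pred = clf.predict(te[..., t])
                            acc[t, ia, ib] += (
                                int(pred[0] == 0) + int(pred[1] == 1)
                            ) / 2.0
    acc *= 100.0 / (n_reps * len(directions) * n_bins)
    # mirror to full symmetric matrices with undefined diagonal
    acc = acc + np.swapaxes(acc, -1, -2)
    diag = np.arange(k)
    acc[..., diag, diag] = np.nan
    return acc


def decode_timecourse(
    epochs,
    scheme: str,
    n_reps: int = 100,
    rng: np.random.Generator | int | None = None,
    n_bins: int = 4,
) -> TimecourseResult:
    """Time-resolved pairwise object decoding.

    ``scheme`` is ``'within-<mask>'`` (train and test inside one masking
    condition) or ``'cross'`` (train on one condition, test on the other,
    averaged over both directions).  Returns one accuracy matrix per time
    point, averaged over ``n_reps`` random pseudo-trial assignments.
    """
    rng = np.random.default_rng(rng)
    matrices = _decode_core(
        epochs.data, epochs.object_label, epochs.mask_label,
        scheme, n_reps, rng, n_bins, generalize=False,
    )
    return TimecourseResult(
        matrices=matrices,
        time_ms=epochs.time_ms.copy(),
        conditions=np.unique(epochs.object_label),
        scheme=scheme,
    )


def temporal_generalization(
    epochs,
    scheme: str,
    n_reps: int = 100,
    rng: np.random.Generator | int | None = None,
    n_bins: int = 4,
) -> TGM:
    """Train at each time point, test at every time point.

    Returns the symmetrized grand-average temporal generalization matrix;
    its diagonal equals the time-resolved decoding result up to
    resampling error.
    """
    rng = np.random.default_rng(rng)
    acc = _decode_core(
        epochs.data, epochs.object_label, epochs.mask_label,
        scheme, n_reps, rng, n_bins, generalize=True,
    )
    i, j = np.tril_indices(acc.shape[-1], k=-1)
    grand = np.nanmean(acc[:, :, i, j], axis=2)
    return TGM(values=grand, time_ms=epochs.time_ms.copy()).symmetrize()


def feature_array(tfr, feature: str) -> np.ndarray:
    """Decoding features from a TFR set: ``(trials, n_features, freqs, times)``.

    ``'power'`` gives the per-channel coefficient magnitudes
    (n_channels features); ``'phase'`` the concatenated unit-normalized
    cosine and sine components (2 x n_channels features, e.g. 128 for a
    64-channel montage).  Undefined phases (zero power) become 0.
    """
    if feature == "power":
        feats = tfr.power  # (trials, channels, freqs, times)
    elif feature == "phase":
        cos, sin = tfr.phase_pair
        feats = np.concatenate([cos, sin], axis=1)
    else:
        raise ValueError(f"feature must be 'power' or 'phase', got {feature!r}")
    return np.nan_to_num(feats)


def timefreq_decode(
    tfr,
    feature: str,
    scheme: str,
    n_reps: int = 100,
    rng: np.random.Generator | int | None = None,
    n_bins: int = 4,
    return_matrices: bool = False,
):
    """Time-frequency-resolved decoding from power or phase features.

    ``feature='power'`` decodes from the per-channel coefficient
    magnitudes (n_channels features); ``feature='phase'`` decodes from
    the concatenated unit-normalized cosine and sine components
    (2 x n_channels features).  Returns the grand-average
    frequency x time accuracy map (and the full per-pair matrices if
    requested).
    """
    rng = np.random.default_rng(rng)
    feats = feature_array(tfr, feature)

    n_freqs = tfr.freqs_hz.size
    k = np.unique(tfr.object_label).size
    n_t = tfr.time_ms.size
    matrices = np.empty((n_freqs, n_t, k, k))
    for fi in range(n_freqs):
        matrices[fi] = _decode_core(
            feats[:, :, fi, :], tfr.object_label, tfr.mask_label,
            scheme, n_reps, rng, n_bins, generalize=False,
        )
    i, j = np.tril_indices(k, k=-1)
    amap = np.nanmean(matrices[:, :, i, j], axis=2)
    if return_matrices:
        return amap, matrices
    return amap


def roi_decode(
    betas: np.ndarray,
    condition_label: np.ndarray,
    n_pseudoruns: int = 4,
    rng: np.random.Generator | int | None = None,
) -> AccuracyMatrix:
    """Leave-one-pseudo-run-out pairwise decoding of fMRI patterns.

    ``betas`` is ``(n_runs, n_rows, n_voxels)`` with ``condition_label``
    labelling the row axis (repeated presentations of a condition within
    a run are averaged first).  Runs are randomly grouped into
    ``n_pseudoruns`` bins and averaged into pseudo-run patterns; each
    cross-validation fold holds out one pseudo-run.
    """
    rng = np.random.default_rng(rng)
    betas = np.asarray(betas, float)
    if betas.ndim != 3:
        raise ValueError("betas must be runs x rows x voxels")
    n_runs = betas.shape[0]
    if n_runs % n_pseudoruns != 0:
        raise ValueError(
            f"{n_runs} runs are not divisible into {n_pseudoruns} pseudo-runs"
        )
    condition_label = np.asarray(condition_label)
    conditions = np.unique(condition_label)
    k = conditions.size
    # average presentations within run, then runs within pseudo-run bin
    cond_means = np.stack(
        [betas[:, condition_label == c].mean(axis=1) for c in conditions], axis=1
    )  # (runs, K, voxels)
    order = rng.permutation(n_runs).reshape(n_pseudoruns, -1)
    pseudo = cond_means[order].mean(axis=1)  # (P, K, voxels)

    values = np.full((k, k), np.nan)
    for ia, ib in combinations(range(k), 2):
        acc = pairwise_accuracy_pseudoruns(pseudo[:, ia], pseudo[:, ib])
        values[ia, ib] = values[ib, ia] = acc
    return AccuracyMatrix(values=values, conditions=conditions)


def pairwise_accuracy_pseudoruns(pa: np.ndarray, pb: np.ndarray) -> float:
    """Alias of :func:`pairwise_accuracy` named for the fMRI use case."""
    return pairwise_accuracy(pa, pb)


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer voxel offsets with Euclidean norm <= radius (center included)."""
    r = int(np.floor(radius))
    grid = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(grid, grid, grid, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def searchlight_decode(
    volume_betas: np.ndarray,
    condition_label: np.ndarray,
    mask: np.ndarray,
    radius: float = 4.0,
    n_pseudoruns: int = 4,
    rng: np.random.Generator | int | None = None,
) -> SearchlightMap:
    """Volumetric searchlight decoding.

    For every voxel inside ``mask`` a sphere of the given radius (voxel
    units, truncated at mask and volume edges) is extracted and the
    ROI-style pairwise decoding run on its voxels; the grand-average
    accuracy is written to the center voxel.
    """
    rng = np.random.default_rng(rng)
    volume_betas = np.asarray(volume_betas, float)
    if volume_betas.ndim != 5:
        raise ValueError("volume_betas must be runs x rows x nx x ny x nz")
    mask = np.asarray(mask, bool)
    if mask.shape != volume_betas.shape[2:]:
        raise ValueError("brain mask shape must match the volume grid")
    offsets = sphere_offsets(radius)
    shape = np.array(mask.shape)
    values = np.full(mask.shape, np.nan)
    for center in np.argwhere(mask):
        vox = center + offsets
        ok = np.all((vox >= 0) & (vox < shape), axis=1)
        vox = vox[ok]
        vox = vox[mask[vox[:, 0], vox[:, 1], vox[:, 2]]]
        if vox.size == 0:
            continue
        betas = volume_betas[:, :, vox[:, 0], vox[:, 1], vox[:, 2]]
        result = roi_decode(betas, condition_label, n_pseudoruns, rng)
        values[tuple(center)] = result.grand_mean
    return SearchlightMap(values=values, radius=radius, mask=mask)


def aggregate_pairs(matrix: AccuracyMatrix, pair_mask: np.ndarray) -> float:
    """Mean accuracy over a selected subset of condition pairs.

    ``pair_mask`` is a symmetric boolean K x K matrix with an empty
    diagonal; used e.g. to average only across-category cells when
    probing decoding across a categorical boundary.
    """
    pair_mask = np.asarray(pair_mask, bool)
    if pair_mask.shape != matrix.values.shape:
        raise ValueError("pair_mask shape must match the accuracy matrix")
    if not np.array_equal(pair_mask, pair_mask.T):
        raise ValueError("pair_mask must be symmetric")
    if np.any(np.diag(pair_mask)):
        raise ValueError("pair_mask must exclude the diagonal")
    if not pair_mask.any():
        raise ValueError("pair_mask selects no cells")
    return float(np.nanmean(matrix.values[pair_mask]))
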