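"""Epoch container, baseline correction and multivariate noise normalization.

The :class:`EpochSet` is the EEG substrate of the pipeline: a
``trials x channels x times`` array with per-trial object and mask labels.
:func:`mnn_whiten` implements multivariate noise normalization — whitening
by the inverse square root of the shrinkage-regularized within-condition
error covariance — which equalises channel noise and decorrelates sensors
before decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.covariance import LedoitWolf

__all__ = ["EpochSet", "baseline_correct", "mnn_whiten", "error_covariance"]


@dataclass
class EpochSet:
    """Labeled epoch data: ``data[trial, channel, time]``.

    ``object_label`` holds integer object identities (0..K-1) and
    ``mask_label`` the masking-condition label per trial.  ``time_ms``
    must be strictly increasing and aligned with the last data axis.
    """

    data: np.ndarray
    object_label: np.ndarray
    mask_label: np.ndarray
    time_ms: np.ndarray
    channel_ids: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.object_label = np.asarray(self.object_label)
        self.mask_label = np.asarray(self.mask_label)
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.channel_ids = np.asarray(self.channel_ids)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x times")
        n_trials, n_channels, n_times = self.data.shape
        if self.object_label.shape != (n_trials,):
            raise ValueError("object_label must align with the trial axis")
        if self.mask_label.shape != (n_trials,):
            raise ValueError("mask_label must align with the trial axis")
        if self.time_ms.shape != (n_times,):
            raise ValueError("time_ms must align with the time axis")
        if self.channel_ids.shape != (n_channels,):
            raise ValueError("channel_ids must align with the channel axis")
        if n_times > 1 and not np.all(np.diff(self.time_ms) > 0):
            raise ValueError("time_ms must be strictly increasing")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite samples")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def sfreq(self) -> float:
        """Sampling rate in Hz inferred from the time grid."""
        return 1000.0 / float(self.time_ms[1] - self.time_ms[0])

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(),
            self.object_label.copy(),
            self.mask_label.copy(),
            self.time_ms.copy(),
            self.channel_ids.copy(),
        )

    def select(self, mask: np.ndarray) -> "EpochSet":
        """Subset of trials given a boolean or index array over trials."""
        return replace(
            self,
            data=self.data[mask],
            object_label=self.object_label[mask],
            mask_label=self.mask_label[mask],
        )

    def crop(self, tmin_ms: float, tmax_ms: float) -> "EpochSet":
        """Restrict the epoch to ``tmin_ms <= t <= tmax_ms``."""
        keep = (self.time_ms >= tmin_ms) & (self.time_ms <= tmax_ms)
        if not keep.any():
            raise ValueError("crop window excludes every sample")
        return replace(self, data=self.data[:, :, keep], time_ms=self.time_ms[keep])


def baseline_correct(
    epochs: EpochSet, window: tuple[float, float] = (-200.0, 0.0)
) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``window`` (ms).

    The window is half-open, ``[start, stop)``, so the conventional
    pre-stimulus baseline ``(-200, 0)`` excludes the stimulus-onset
    sample.  Returns a corrected copy.
    """
    start, stop = window
    sel = (epochs.time_ms >= start) & (epochs.time_ms < stop)
    if not sel.any():
        raise ValueError(
            f"baseline window [{start}, {stop}) contains no samples of the epoch"
        )
    base = epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    out = epochs.copy()
    out.data = epochs.data - base
    return out


def error_covariance(epochs: EpochSet) -> np.ndarray:
    """Shrinkage-regularized within-condition error covariance.

    Residuals are computed per condition cell (object x mask) and time
    point by removing the cell mean, pooled over cells and time points,
    and fed to the Ledoit-Wolf analytic-shrinkage estimator, which keeps
    the estimate well conditioned even for rank-deficient sensor data.
    """
    cells = _cell_index(epochs)
    resid = np.empty_like(epochs.data)
    for idx in cells:
        if idx.size < 2:
            raise ValueError(
                "every condition cell needs >= 2 trials to estimate residuals"
            )
        resid[idx] = epochs.data[idx] - epochs.data[idx].mean(axis=0)
    # stack (trial, time) samples: averaging per-time covariances equals
    # one pooled estimate on the stacked residuals
    samples = resid.transpose(0, 2, 1).reshape(-1, epochs.n_channels)
    lw = LedoitWolf(assume_centered=True).fit(samples)
    return lw.covariance_


def mnn_whiten(epochs: EpochSet, return_whitener: bool = False):
    """Multivariate noise normalization of an epoch set.

    Multiplies the channel dimension by ``Sigma^{-1/2}``, the inverse
    matrix square root of the shrinkage error covariance from
    :func:`error_covariance`.  One whitening matrix is computed from all
    trials of the set (both masking conditions pooled) so that within- and
    cross-condition analyses share a single transform.
    """
    sigma = error_covariance(epochs)
    evals, evecs = np.linalg.eigh(sigma)
    if np.any(evals <= 0):  # shrinkage should preclude this
        raise np.linalg.LinAlgError("error covariance is not positive definite")
    whitener = (evecs / np.sqrt(evals)) @ evecs.T
    out = epochs.copy()
    out.data = np.einsum("ij,tjs->tis", whitener, epochs.data)
    if return_whitener:
        return out, whitener
    return out


def _cell_index(epochs: EpochSet) -> list[np.ndarray]:
    """Trial indices per (object, mask) condition cell."""
    cells = []
    for mask in np.unique(epochs.mask_label):
        in_mask = epochs.mask_label == mask
        for obj in np.unique(epochs.object_label[in_mask]):
            cells.append(np.flatnonzero(in_mask & (epochs.object_label == obj)))
    return cells
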