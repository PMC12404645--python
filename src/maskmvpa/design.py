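"""Experimental design and generative ground-truth descriptions.

A :class:`DesignSpec` captures the factorial layout of a backward-masking
experiment: K object identities crossed with two masking conditions (an
*early* mask that curtails recurrent processing and a *late* mask that
leaves it intact), recorded either as EEG epochs or as run-wise fMRI
responses.  A :class:`GroundTruth` describes the generative model the
synthetic-data module uses to emulate such recordings: a transient
feedforward component, a sustained "recurrent" component whose amplitude
depends on the masking condition, an optional stimulus-locked oscillatory
component, and spatially correlated Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DesignSpec",
    "FeedforwardComponent",
    "RecurrentComponent",
    "OscillatoryComponent",
    "NoiseModel",
    "GroundTruth",
    "default_roi_geometry",
]


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design of one masking experiment.

    Defaults reproduce the reference design: 24 objects x 2 masking
    conditions, 53 EEG trials per cell on 64 channels with epochs from
    -200 ms to 800 ms in 10 ms steps, and 12 fMRI runs with 2
    presentations of every condition per run.
    """

    n_objects: int = 24
    mask_conditions: tuple[str, ...] = ("early", "late")
    trials_per_cell: int = 53
    n_channels: int = 64
    tmin_ms: float = -200.0
    tmax_ms: float = 800.0
    tstep_ms: float = 10.0
    n_runs: int = 12
    presentations_per_run: int = 2
    n_subjects: int = 10

    def __post_init__(self) -> None:
        if self.n_objects < 2:
            raise ValueError("n_objects must be >= 2")
        if self.trials_per_cell < 4:
            raise ValueError(
                "trials_per_cell must be >= 4 to support 4 pseudo-trial bins"
            )
        if self.tstep_ms <= 0 or self.tmax_ms <= self.tmin_ms:
            raise ValueError("time grid must be strictly increasing")
        if len(self.mask_conditions) < 1:
            raise ValueError("at least one mask condition required")
        if len(set(self.mask_conditions)) != len(self.mask_conditions):
            raise ValueError("mask condition labels must be unique")

    @property
    def time_ms(self) -> np.ndarray:
        """Epoch sample times in milliseconds (inclusive of both ends)."""
        n = int(round((self.tmax_ms - self.tmin_ms) / self.tstep_ms)) + 1
        return self.tmin_ms + self.tstep_ms * np.arange(n)

    @property
    def n_times(self) -> int:
        return self.time_ms.size

    @property
    def n_masks(self) -> int:
        return len(self.mask_conditions)

    @property
    def trials_per_subject(self) -> int:
        """Total EEG trials per subject (objects x masks x trials/cell)."""
        return self.n_objects * self.n_masks * self.trials_per_cell

    @property
    def betas_per_run(self) -> int:
        """Condition betas per fMRI run (objects x masks x presentations)."""
        return self.n_objects * self.n_masks * self.presentations_per_run


@dataclass(frozen=True)
class FeedforwardComponent:
    """Transient, mask-independent response component.

    Gaussian temporal envelope centred at ``peak_ms`` with the given full
    width at half maximum; models the initial feedforward sweep.
    """

    peak_ms: float = 120.0
    fwhm_ms: float = 80.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def envelope(self, time_ms: np.ndarray) -> np.ndarray:
        sigma = self.fwhm_ms / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((time_ms - self.peak_ms) / sigma) ** 2)


@dataclass(frozen=True)
class RecurrentComponent:
    """Sustained component whose amplitude depends on the masking condition.

    A smooth sigmoidal onset at ``onset_ms`` followed by a plateau of
    ``plateau_ms`` and a symmetric offset.  ``amplitude_by_mask`` encodes
    the core manipulation: an early mask truncates recurrent activity
    (small amplitude) while a late mask leaves it intact.
    """

    onset_ms: float = 150.0
    plateau_ms: float = 400.0
    amplitude_by_mask: dict[str, float] = field(
        default_factory=lambda: {"early": 0.2, "late": 1.0}
    )
    rise_ms: float = 40.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitude_by_mask.values()):
            raise ValueError("amplitudes must be >= 0")

    def envelope(self, time_ms: np.ndarray) -> np.ndarray:
        rise = 1.0 / (1.0 + np.exp(-(time_ms - self.onset_ms) / self.rise_ms))
        fall = 1.0 / (
            1.0
            + np.exp((time_ms - self.onset_ms - self.plateau_ms) / self.rise_ms)
        )
        return rise * fall


@dataclass(frozen=True)
class OscillatoryComponent:
    """Stimulus-locked oscillation with object-dependent phase.

    Each object carries its own phase offset, so a classifier trained at
    one post-stimulus time and tested half a cycle later sees the object
    code with its sign flipped — the construction behind below-chance
    off-diagonal temporal generalization.  Off by default (amplitude 0).
    """

    freq_hz: float = 10.0
    amplitude: float = 0.0
    phase_by_object: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.phase_by_object is not None:
            p = np.asarray(self.phase_by_object, dtype=float)
            if np.any(p < 0) or np.any(p >= 2 * np.pi):
                raise ValueError("phases must lie in [0, 2*pi)")

    def phases(self, n_objects: int) -> np.ndarray:
        if self.phase_by_object is not None:
            p = np.asarray(self.phase_by_object, dtype=float)
            if p.size != n_objects:
                raise ValueError("phase_by_object length must equal n_objects")
            return p
        return 2.0 * np.pi * np.arange(n_objects) / n_objects


@dataclass(frozen=True)
class NoiseModel:
    """Temporally white, spatially correlated Gaussian sensor noise.

    Channel covariance is exponential in channel index with correlation
    length ``corr_length`` (channels); ``scale`` is the per-channel
    standard deviation.  ``corr_length = 0`` gives white noise.
    """

    scale: float = 1.0
    corr_length: float = 5.0

    def __post_init__(self) -> None:
        if self.scale < 0 or self.corr_length < 0:
            raise ValueError("noise parameters must be >= 0")

    def channel_cov(self, n_channels: int) -> np.ndarray:
        idx = np.arange(n_channels)
        if self.corr_length == 0:
            corr = np.eye(n_channels)
        else:
            corr = np.exp(-np.abs(idx[:, None] - idx[None, :]) / self.corr_length)
        return (self.scale**2) * corr

    def mixing(self, n_channels: int) -> np.ndarray:
        """Cholesky factor L with L @ L.T = channel covariance."""
        cov = self.channel_cov(n_channels)
        # jitter guards the Cholesky against numerically semidefinite input
        return np.linalg.cholesky(cov + 1e-12 * np.eye(n_channels))


def default_roi_geometry(n_layers: int) -> dict[str, dict[str, int]]:
    """Per-ROI, per-mask model-layer assignment.

    EVC tracks an early layer regardless of masking; LOC tracks a mid
    layer under an early mask and the deepest layer under a late mask,
    emulating a recurrence-driven shift toward high-complexity features.
    """
    early_layer = min(1, n_layers - 1)
    mid_layer = n_layers // 2
    return {
        "EVC": {"early": early_layer, "late": early_layer},
        "LOC": {"early": mid_layer, "late": n_layers - 1},
    }


@dataclass(frozen=True)
class GroundTruth:
    """Generative model behind the synthetic recordings.

    ``signal_scale`` multiplies every condition-specific component; zero
    yields null data that should decode at chance.
    ``cross_condition_overlap`` in [0, 1] interpolates between identical
    representational geometry across masking conditions (1) and fully
    orthogonal geometries (0).  ``subject_jitter`` is the standard
    deviation of per-subject deviations from the population-level
    condition patterns, which makes group statistics and noise ceilings
    meaningful.
    """

    feedforward: FeedforwardComponent = field(default_factory=FeedforwardComponent)
    recurrent: RecurrentComponent = field(default_factory=RecurrentComponent)
    oscillatory: OscillatoryComponent = field(default_factory=OscillatoryComponent)
    noise: NoiseModel = field(default_factory=NoiseModel)
    signal_scale: float = 1.0
    cross_condition_overlap: float = 1.0
    subject_jitter: float = 0.3
    roi_geometry: dict[str, dict[str, int]] | None = None

    def __post_init__(self) -> None:
        if self.signal_scale < 0:
            raise ValueError("signal_scale must be >= 0")
        if not 0.0 <= self.cross_condition_overlap <= 1.0:
            raise ValueError("cross_condition_overlap must lie in [0, 1]")
        if self.subject_jitter < 0:
            raise ValueError("subject_jitter must be >= 0")
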