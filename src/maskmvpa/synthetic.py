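"""Synthetic EEG, fMRI and model-RDM generation.

None of the original recordings are required anywhere in the pipeline:
this module fabricates datasets with the statistical structure the
analyses assume — a transient feedforward component, a sustained
masking-dependent "recurrent" component, an optional phase-coded
oscillation, layer-graded model representational geometries, and run-wise
fMRI response patterns whose geometry is tied to designated model layers.
Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignSpec, GroundTruth, default_roi_geometry
from .glm import HRFFamily
from .preprocess import EpochSet
from .rsa import rdm_from_features

__all__ = [
    "ModelRDMSet",
    "make_model_rdms",
    "simulate_eeg_dataset",
    "FMRIDataset",
    "simulate_fmri_dataset",
    "simulate_fmri_timeseries",
]


@dataclass(frozen=True)
class ModelRDMSet:
    """Ordered per-layer RDMs standing in for the geometry of a deep net.

    Layer ``l`` mixes two latent feature bases with weight ``alpha[l]`` on
    the first: ``alpha`` descends from 1 (layer 1 = basis A) to 0 (deepest
    layer = basis B), so adjacent layers correlate more than distant ones.
    The latent item-feature matrices are retained so that downstream
    simulators can build voxel patterns with a geometry matched to any
    mixture of layers.
    """

    rdms: np.ndarray  # (n_layers, K, K), diagonal NaN
    alpha: np.ndarray  # (n_layers,) weight on basis A
    basis_a: np.ndarray  # (K, n_features) latent features of basis A
    basis_b: np.ndarray  # (K, n_features)

    @property
    def n_layers(self) -> int:
        return self.rdms.shape[0]

    @property
    def n_items(self) -> int:
        return self.rdms.shape[1]

    def features_for_alpha(self, alpha: float) -> np.ndarray:
        """Item features whose 1-Pearson RDM interpolates the two bases."""
        return np.hstack(
            [np.sqrt(alpha) * self.basis_a, np.sqrt(1.0 - alpha) * self.basis_b]
        )


def make_model_rdms(
    n_layers: int, seed: int | np.random.Generator, n_items: int = 24,
    n_features: int = 100,
) -> ModelRDMSet:
    """Build a layer-graded model RDM set.

    Two independent random feature bases define two (near-orthogonal)
    endpoint RDMs via the 1-Pearson dissimilarity; layer ``l`` uses the
    convex mixture with weight ``alpha_l = 1 - l/(n_layers-1)`` on basis
    A, so representational geometry shifts smoothly with depth.
    """
    if n_layers < 2:
        raise ValueError("n_layers must be >= 2")
    rng = np.random.default_rng(seed)
    basis_a = rng.standard_normal((n_items, n_features))
    basis_b = rng.standard_normal((n_items, n_features))
    alpha = np.linspace(1.0, 0.0, n_layers)
    rdm_a = rdm_from_features(basis_a)
    rdm_b = rdm_from_features(basis_b)
    rdms = alpha[:, None, None] * rdm_a + (1.0 - alpha)[:, None, None] * rdm_b
    return ModelRDMSet(rdms=rdms, alpha=alpha, basis_a=basis_a, basis_b=basis_b)


def _condition_patterns(
    design: DesignSpec, truth: GroundTruth, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Population-level channel patterns per component.

    Per mask condition, each object's recurrent pattern is a spherical
    interpolation between a shared geometry and a mask-specific orthogonal
    one, controlled by ``truth.cross_condition_overlap``: overlap 1 gives
    identical geometry in both masking conditions, overlap 0 gives fully
    orthogonal geometries (cross-condition decoding at chance).
    """
    k, c = design.n_objects, design.n_channels
    ff = rng.standard_normal((k, c))
    shared = rng.standard_normal((k, c))
    w = truth.cross_condition_overlap
    rec = {}
    for m, mask in enumerate(design.mask_conditions):
        specific = rng.standard_normal((k, c))
        rec[mask] = np.sqrt(w) * shared + np.sqrt(1.0 - w) * specific
    osc = rng.standard_normal((k, c))
    return {"feedforward": ff, "osc": osc, **{f"rec_{m}": v for m, v in rec.items()}}


def simulate_eeg_dataset(
    design: DesignSpec,
    truth: GroundTruth,
    seed: int | np.random.Generator,
    n_subjects: int | None = None,
) -> list[EpochSet]:
    """Simulate per-subject EEG epoch sets.

    Each trial is the sum of the feedforward transient, the
    masking-dependent recurrent component, the optional phase-coded
    oscillation — each multiplying an object-specific channel pattern —
    plus spatially correlated Gaussian noise.  Trial order is randomised
    per subject; labels are balanced by construction
    (``n_objects x n_masks x trials_per_cell`` trials each).
    """
    rng = np.random.default_rng(seed)
    if n_subjects is None:
        n_subjects = design.n_subjects
    time = design.time_ms
    env_ff = truth.feedforward.envelope(time)
    env_rec = truth.recurrent.envelope(time)
    phases = truth.oscillatory.phases(design.n_objects)
    carrier = 2.0 * np.pi * truth.oscillatory.freq_hz * time / 1000.0
    post = (time >= 0).astype(float)  # oscillation is stimulus-locked
    mixing = truth.noise.mixing(design.n_channels)
    pop = _condition_patterns(design, truth, rng)
    channel_ids = np.array([f"ch{i:02d}" for i in range(design.n_channels)])

    subjects = []
    for _ in range(n_subjects):
        pats = {
            key: val + truth.subject_jitter * rng.standard_normal(val.shape)
            for key, val in pop.items()
        }
        n_trials = design.trials_per_subject
        data = np.empty((n_trials, design.n_channels, time.size))
        obj_label = np.empty(n_trials, dtype=int)
        mask_label = np.empty(n_trials, dtype=object)
        t = 0
        for mask in design.mask_conditions:
            amp_rec = truth.recurrent.amplitude_by_mask.get(mask, 0.0)
            for obj in range(design.n_objects):
                osc_wave = np.cos(carrier + phases[obj]) * post
                signal = truth.signal_scale * (
                    truth.feedforward.amplitude * pats["feedforward"][obj][:, None] * env_ff
                    + amp_rec * pats[f"rec_{mask}"][obj][:, None] * env_rec
                    + truth.oscillatory.amplitude * pats["osc"][obj][:, None] * osc_wave
                )
                n = design.trials_per_cell
                noise = mixing @ rng.standard_normal((n, design.n_channels, time.size))
                data[t : t + n] = signal + noise
                obj_label[t : t + n] = obj
                mask_label[t : t + n] = mask
                t += n
        order = rng.permutation(n_trials)
        subjects.append(
            EpochSet(
                data=data[order],
                object_label=obj_label[order],
                mask_label=mask_label[order].astype(str),
                time_ms=time.copy(),
                channel_ids=channel_ids.copy(),
            )
        )
    return subjects


@dataclass
class FMRIDataset:
    """Run-wise fMRI responses for one subject.

    ``roi_betas[roi]`` has shape ``(n_runs, betas_per_run, n_voxels)``
    where the beta axis enumerates object x mask x presentation.
    ``volume_betas`` is a small 4-D+run array ``(n_runs, betas_per_run,
    nx, ny, nz)`` with an aligned boolean ``brain_mask``; informative
    voxel patterns are planted inside ``signal_box`` (slices into the
    volume grid).
    """

    roi_betas: dict[str, np.ndarray]
    object_label: np.ndarray  # (betas_per_run,)
    mask_label: np.ndarray  # (betas_per_run,)
    volume_betas: np.ndarray | None = None
    brain_mask: np.ndarray | None = None
    signal_box: tuple[slice, slice, slice] | None = None


def simulate_fmri_dataset(
    design: DesignSpec,
    truth: GroundTruth,
    model_rdms: ModelRDMSet,
    seed: int | np.random.Generator,
    n_subjects: int | None = None,
    n_voxels: int = 80,
    noise_scale: float | None = None,
    volume_shape: tuple[int, int, int] | None = None,
    readout: str = "random",
) -> list[FMRIDataset]:
    """Simulate per-subject, per-ROI run-wise beta patterns.

    ROI geometry follows ``truth.roi_geometry`` (default:
    :func:`~maskmvpa.design.default_roi_geometry`), which assigns each ROI
    and masking condition a model layer; the noiseless voxel patterns are
    a random linear read-out of that layer's latent features, so the
    noiseless pattern RDM correlates maximally with the assigned layer.
    When ``volume_shape`` is given, a small 3-D volume is also produced
    with the first ROI's patterns planted in one corner box and pure
    noise elsewhere (the searchlight fixture).

    ``readout='random'`` projects latent features to voxels with a
    random Gaussian map (finite-voxel sampling distorts the geometry
    slightly); ``readout='orthonormal'`` uses an orthonormal map
    (requires ``n_voxels`` >= latent dimension) that preserves pattern
    inner products exactly — use it for noiseless geometry oracles.
    """
    rng = np.random.default_rng(seed)
    if n_subjects is None:
        n_subjects = design.n_subjects
    geometry = truth.roi_geometry or default_roi_geometry(model_rdms.n_layers)
    if not geometry:
        raise ValueError("truth.roi_geometry must name at least one ROI")
    for roi, by_mask in geometry.items():
        for mask, layer in by_mask.items():
            if not 0 <= layer < model_rdms.n_layers:
                raise ValueError(
                    f"roi_geometry[{roi!r}][{mask!r}]={layer} outside the model layers"
                )
    if model_rdms.n_items != design.n_objects:
        raise ValueError("model RDM item count must equal design.n_objects")
    if noise_scale is None:
        noise_scale = truth.noise.scale

    p = design.presentations_per_run
    object_label = np.repeat(
        np.tile(np.arange(design.n_objects), design.n_masks), p
    )
    mask_label = np.repeat(np.asarray(design.mask_conditions, dtype=object),
                           design.n_objects * p).astype(str)

    datasets = []
    for _ in range(n_subjects):
        roi_betas = {}
        first_patterns = None
        for roi, by_mask in geometry.items():
            # per-mask noiseless voxel patterns from the assigned layer
            patterns = np.empty((design.n_masks, design.n_objects, n_voxels))
            for m, mask in enumerate(design.mask_conditions):
                alpha = float(model_rdms.alpha[by_mask[mask]])
                feats = model_rdms.features_for_alpha(alpha)
                n_feat = feats.shape[1]
                if readout == "orthonormal":
                    if n_voxels < n_feat:
                        raise ValueError(
                            f"orthonormal readout needs n_voxels >= {n_feat}"
                        )
                    q, _ = np.linalg.qr(rng.standard_normal((n_voxels, n_feat)))
                    proj = q.T  # (n_feat, n_voxels), rows orthonormal
                elif readout == "random":
                    proj = rng.standard_normal((n_feat, n_voxels)) / np.sqrt(n_feat)
                else:
                    raise ValueError(f"unknown readout {readout!r}")
                pat = feats @ proj
                pat += truth.subject_jitter * rng.standard_normal(pat.shape)
                patterns[m] = truth.signal_scale * pat
            if first_patterns is None:
                first_patterns = patterns
            betas = np.empty((design.n_runs, design.betas_per_run, n_voxels))
            for run in range(design.n_runs):
                clean = np.repeat(patterns.reshape(-1, n_voxels), p, axis=0)
                betas[run] = clean + noise_scale * rng.standard_normal(clean.shape)
            roi_betas[roi] = betas

        volume = brain = box = None
        if volume_shape is not None:
            nx, ny, nz = volume_shape
            side = max(2, min(nx, ny, nz) // 3)
            box = (slice(0, side), slice(0, side), slice(0, side))
            n_box = side**3
            if n_box > n_voxels:
                raise ValueError("volume signal box larger than n_voxels")
            brain = np.ones(volume_shape, dtype=bool)
            volume = noise_scale * rng.standard_normal(
                (design.n_runs, design.betas_per_run) + volume_shape
            )
            clean = np.repeat(
                first_patterns.reshape(-1, n_voxels)[:, :n_box], p, axis=0
            )
            volume[(slice(None), slice(None)) + box] += clean.reshape(
                design.betas_per_run, side, side, side
            )
        datasets.append(
            FMRIDataset(
                roi_betas=roi_betas,
                object_label=object_label.copy(),
                mask_label=mask_label.copy(),
                volume_betas=volume,
                brain_mask=brain,
                signal_box=box,
            )
        )
    return datasets


def simulate_fmri_timeseries(
    n_voxels: int,
    hrf_index_per_voxel: np.ndarray,
    seed: int | np.random.Generator,
    family: HRFFamily | None = None,
    n_conditions: int = 4,
    events_per_condition: int = 8,
    tr_s: float = 2.0,
    n_scans: int = 200,
    amplitude: float | np.ndarray = 1.0,
    noise_scale: float = 0.1,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate voxel time series from an event design and per-voxel HRFs.

    Each voxel's series is the convolution of the condition event trains
    with the voxel's assigned HRF kernel, scaled by per-condition
    amplitudes, plus white noise.  Returns ``(series, events)`` where
    ``series`` is ``(n_voxels, n_scans)`` and ``events`` a BIDS-style
    table with columns onset, duration, condition.
    """
    rng = np.random.default_rng(seed)
    if family is None:
        family = HRFFamily()
    hrf_index_per_voxel = np.asarray(hrf_index_per_voxel, dtype=int)
    if hrf_index_per_voxel.shape != (n_voxels,):
        raise ValueError("hrf_index_per_voxel must have one entry per voxel")
    if np.any(hrf_index_per_voxel < 0) or np.any(
        hrf_index_per_voxel >= family.n_kernels
    ):
        raise ValueError("HRF indices outside the family")
    amplitude = np.broadcast_to(np.asarray(amplitude, float), (n_conditions,))

    n_events = n_conditions * events_per_condition
    if n_events > 0:
        onsets_scan = rng.choice(
            np.arange(2, n_scans - int(30 / tr_s)), size=n_events, replace=False
        )
        onsets_scan.sort()
        conditions = rng.permutation(np.repeat(np.arange(n_conditions),
                                               events_per_condition))
    else:
        onsets_scan = np.array([], dtype=int)
        conditions = np.array([], dtype=int)
    events = pd.DataFrame(
        {
            "onset": onsets_scan * tr_s,
            "duration": np.full(onsets_scan.size, tr_s / 2),
            "condition": [f"cond{c}" for c in conditions],
        }
    )

    # condition regressors on the scan grid, one per condition, per HRF
    series = np.empty((n_voxels, n_scans))
    trains = np.zeros((n_conditions, n_scans))
    for scan, cond in zip(onsets_scan, conditions):
        trains[cond, scan] += 1.0
    for k in np.unique(hrf_index_per_voxel):
        kernel = family.kernel_on_grid(k, tr_s)
        reg = np.array(
            [np.convolve(tr, kernel)[:n_scans] for tr in trains]
        )
        clean = amplitude @ reg
        vox = hrf_index_per_voxel == k
        series[vox] = clean + noise_scale * rng.standard_normal(
            (int(vox.sum()), n_scans)
        )
    return series, events
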