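"""Complex Morlet time-frequency decomposition.

The wavelet bank spans 4-100 Hz in 50 logarithmically spaced steps, with
the temporal full width at half maximum (FWHM) of the Gaussian envelope
scheduled log-linearly from 500 ms at the lowest frequency down to 20 ms
at the highest.  By the Fourier uncertainty relation this corresponds to
a spectral FWHM (measured on the power spectrum) of

    FWHM_f = 4 ln 2 / (pi * FWHM_t * sqrt(2)),

i.e. about 1 Hz at 4 Hz and about 31 Hz at 100 Hz.  Convolving epochs
with the bank yields complex coefficients whose magnitude is the power
feature and whose unit-normalized real/imaginary parts are the two phase
features used for phase decoding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .preprocess import EpochSet

__all__ = [
    "WaveletBank",
    "TFRSet",
    "build_wavelet_bank",
    "tfr_transform",
    "measure_fwhm",
    "spectral_fwhm",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
_KERNEL_HALF_WIDTH_SIGMAS = 3.0


@dataclass(frozen=True)
class WaveletBank:
    """Bank of Gaussian-enveloped complex exponentials.

    ``kernels[i]`` is sampled at ``sfreq`` on a symmetric grid of
    +/- 3 envelope standard deviations and normalized to unit energy
    (L2 integral 1 in seconds), so the expected power of white-noise
    input is constant across frequencies.
    """

    freqs_hz: np.ndarray
    temporal_fwhm_ms: np.ndarray
    sfreq: float
    kernels: list[np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.freqs_hz) > 0):
            raise ValueError("freqs_hz must be strictly increasing")
        if not np.all(np.diff(self.temporal_fwhm_ms) < 0):
            raise ValueError("temporal FWHM must strictly decrease with frequency")

    @property
    def n_freqs(self) -> int:
        return self.freqs_hz.size

    @property
    def max_kernel_samples(self) -> int:
        return max(k.size for k in self.kernels)

    def kernel_times_s(self, index: int) -> np.ndarray:
        n = self.kernels[index].size
        half = (n - 1) // 2
        return (np.arange(n) - half) / self.sfreq


def build_wavelet_bank(
    f_min: float = 4.0,
    f_max: float = 100.0,
    n: int = 50,
    fwhm_max_ms: float = 500.0,
    fwhm_min_ms: float = 20.0,
    sfreq: float = 500.0,
) -> WaveletBank:
    """Construct the default Morlet bank.

    Frequencies and temporal FWHMs are both log-spaced; the widest
    envelope is assigned to the lowest frequency.  A warning is issued
    for any kernel whose envelope FWHM is shorter than one oscillation
    cycle (the kernel is still built).
    """
    if not 0 < f_min < f_max:
        raise ValueError("need 0 < f_min < f_max")
    if n < 2:
        raise ValueError("n must be >= 2")
    freqs = np.geomspace(f_min, f_max, n)
    fwhm_ms = np.geomspace(fwhm_max_ms, fwhm_min_ms, n)
    kernels = []
    for f, fw in zip(freqs, fwhm_ms):
        if fw / 1000.0 < 1.0 / f:
            warnings.warn(
                f"{f:.1f} Hz kernel envelope FWHM {fw:.0f} ms is shorter than "
                "one cycle",
                stacklevel=2,
            )
        sigma_s = fw / 1000.0 * _FWHM_TO_SIGMA
        half = int(np.ceil(_KERNEL_HALF_WIDTH_SIGMAS * sigma_s * sfreq))
        t = np.arange(-half, half + 1) / sfreq
        envelope = np.exp(-0.5 * (t / sigma_s) ** 2)
        kernel = envelope * np.exp(2j * np.pi * f * t)
        # unit energy: white-noise expected power is then flat across the bank
        kernel /= np.sqrt(np.sum(np.abs(kernel) ** 2) / sfreq)
        kernels.append(kernel)
    return WaveletBank(
        freqs_hz=freqs, temporal_fwhm_ms=fwhm_ms, sfreq=sfreq, kernels=kernels
    )


@dataclass
class TFRSet:
    """Trial x channel x frequency x time complex wavelet coefficients."""

    coeffs: np.ndarray
    freqs_hz: np.ndarray
    time_ms: np.ndarray
    object_label: np.ndarray
    mask_label: np.ndarray
    channel_ids: np.ndarray

    @property
    def power(self) -> np.ndarray:
        """Amplitude |coefficient| (non-negative)."""
        return np.abs(self.coeffs)

    @property
    def phase_pair(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit-normalized (cos, sin) of the coefficient phase.

        Undefined (NaN) wherever power is zero.
        """
        mag = np.abs(self.coeffs)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(mag > 0, self.coeffs / mag, complex(np.nan, np.nan))
        return unit.real, unit.imag

    def crop(self, tmin_ms: float, tmax_ms: float) -> "TFRSet":
        keep = (self.time_ms >= tmin_ms) & (self.time_ms <= tmax_ms)
        if not keep.any():
            raise ValueError("crop window excludes every sample")
        return TFRSet(
            coeffs=self.coeffs[..., keep],
            freqs_hz=self.freqs_hz,
            time_ms=self.time_ms[keep],
            object_label=self.object_label,
            mask_label=self.mask_label,
            channel_ids=self.channel_ids,
        )


def tfr_transform(
    epochs: EpochSet,
    bank: WaveletBank,
    downsample_ms: float = 20.0,
    pad: bool = False,
) -> TFRSet:
    """Convolve every trial and channel with the wavelet bank.

    The epoch sampling rate must match the bank's.  Because convolution
    smears edge effects over half a kernel length, the epoch must be at
    least as long as the widest kernel; generate epochs longer than the
    window of interest (e.g. -600...1200 ms for a -200...800 ms analysis)
    and crop after the transform.  With ``pad=True`` short epochs are
    reflect-padded instead of rejected.  The output time axis keeps every
    ``downsample_ms / native-step``-th sample.
    """
    if abs(epochs.sfreq - bank.sfreq) > 1e-6:
        raise ValueError(
            f"epoch sampling rate {epochs.sfreq:.1f} Hz does not match "
            f"bank sampling rate {bank.sfreq:.1f} Hz"
        )
    n_pad = 0
    data = epochs.data
    if epochs.n_times < bank.max_kernel_samples:
        if not pad:
            raise ValueError(
                f"epoch ({epochs.n_times} samples) shorter than the widest "
                f"kernel ({bank.max_kernel_samples} samples); generate longer "
                "epochs or pass pad=True"
            )
        n_pad = bank.max_kernel_samples // 2
        data = np.pad(data, ((0, 0), (0, 0), (n_pad, n_pad)), mode="reflect")

    step_ms = float(epochs.time_ms[1] - epochs.time_ms[0])
    keep_every = int(round(downsample_ms / step_ms))
    if abs(keep_every * step_ms - downsample_ms) > 1e-9 or keep_every < 1:
        raise ValueError(
            f"downsample interval {downsample_ms} ms is not a multiple of the "
            f"native step {step_ms} ms"
        )

    n_trials, n_channels, _ = epochs.data.shape
    out_time = epochs.time_ms[::keep_every]
    coeffs = np.empty(
        (n_trials, n_channels, bank.n_freqs, out_time.size), dtype=complex
    )
    flat = data.reshape(-1, data.shape[-1])
    for fi, kernel in enumerate(bank.kernels):
        conv = fftconvolve(flat, kernel[None, :] / bank.sfreq, mode="same")
        if n_pad:
            conv = conv[:, n_pad:-n_pad]
        coeffs[:, :, fi, :] = conv[:, ::keep_every].reshape(
            n_trials, n_channels, -1
        )
    return TFRSet(
        coeffs=coeffs,
        freqs_hz=bank.freqs_hz.copy(),
        time_ms=out_time.copy(),
        object_label=epochs.object_label.copy(),
        mask_label=epochs.mask_label.copy(),
        channel_ids=epochs.channel_ids.copy(),
    )


def measure_fwhm(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a single-peaked curve.

    Crossings of the half-maximum level are located by linear
    interpolation between neighbouring samples on each side of the peak.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    peak = int(np.argmax(y))
    half = y[peak] / 2.0
    if y[0] > half or y[-1] > half:
        raise ValueError("curve does not fall below half maximum at both ends")

    def cross(lo: int, hi: int, step: int) -> float:
        for i in range(lo, hi, step):
            if (y[i] - half) * (y[i + step] - half) <= 0 and y[i + step] != y[i]:
                frac = (half - y[i]) / (y[i + step] - y[i])
                return x[i] + frac * (x[i + step] - x[i])
        raise ValueError("no half-maximum crossing found")

    left = cross(peak, 0, -1)
    right = cross(peak, len(y) - 1, 1)
    return abs(right - left)


def spectral_fwhm(bank: WaveletBank, index: int, n_fft: int = 2**16) -> float:
    """FWHM (Hz) of a kernel's power spectrum, measured numerically."""
    kernel = bank.kernels[index]
    spec = np.abs(np.fft.fft(kernel, n=n_fft)) ** 2
    freqs = np.fft.fftfreq(n_fft, d=1.0 / bank.sfreq)
    pos = freqs >= 0
    return measure_fwhm(freqs[pos], spec[pos])
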