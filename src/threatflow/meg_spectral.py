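"""MEG epoch conditioning, multitaper spectra, and individual alpha frequency.

Epochs are trial x sensor x time arrays of the 2 s preceding each probe.
Conditioning: per-trial demean/detrend, zero-phase 90 Hz low-pass, 60 Hz
notch, decimation to 300 Hz. Muscle-artifact screening runs on the raw
(pre-decimation) data in the 110-140 Hz band.

Spectra use orthonormal discrete prolate spheroidal (Slepian) tapers; power
is scaled so the spectrum sums to the signal variance (Parseval). The survey
spectrum (1-20 Hz) uses a single taper; band power around the individual
alpha frequency (IAF) uses two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.signal.windows import dpss

__all__ = [
    "SensorEpochs",
    "Spectrum",
    "SubjectSpectralProfile",
    "preprocess_epochs",
    "detect_muscle_artifacts",
    "dpss_tapers",
    "mtm_spectrum",
    "detect_iaf",
    "iaf_band_power",
]

MUSCLE_BAND_HZ = (110.0, 140.0)
ALPHA_BAND_HZ = (8.0, 12.0)


@dataclass
class SensorEpochs:
    """Trial x sensor x time array with per-trial condition labels."""

    epochs: np.ndarray
    fs_hz: float
    conditions: np.ndarray  # 'safe' / 'threat' per trial
    sensor_positions: np.ndarray | None = None
    reject: np.ndarray | None = None
    subject_id: str = ""

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, float)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be trial x sensor x time")
        self.conditions = np.asarray(self.conditions)
        if self.conditions.shape[0] != self.epochs.shape[0]:
            raise ValueError("one condition label per trial required")
        if self.reject is None:
            self.reject = np.zeros(self.epochs.shape[0], bool)
        else:
            self.reject = np.asarray(self.reject, bool)

    @property
    def n_trials(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.epochs.shape[1]

    def kept(self, condition: str | None = None) -> np.ndarray:
        """Indices of non-rejected trials, optionally within one condition."""
        keep = ~self.reject
        if condition is not None:
            keep &= self.conditions == condition
        return np.flatnonzero(keep)


@dataclass
class Spectrum:
    frequencies: np.ndarray  # Hz
    power: np.ndarray  # trial x sensor x freq
    n_tapers: int

    def mean_over(self, trials: np.ndarray | None = None) -> np.ndarray:
        """Trial- and sensor-averaged spectrum (optionally on a trial subset)."""
        p = self.power if trials is None else self.power[trials]
        return p.mean(axis=(0, 1))


@dataclass
class SubjectSpectralProfile:
    """Detected IAF (or the fallback flag) and the +/-1 Hz analysis band."""

    iaf_hz: float | None
    fallback: bool = False

    @property
    def band(self) -> tuple[float, float]:
        if self.iaf_hz is None:
            raise ValueError("profile unresolved: no IAF and no fallback applied")
        return (self.iaf_hz - 1.0, self.iaf_hz + 1.0)

    def resolved(self, cohort_mean_iaf: float) -> "SubjectSpectralProfile":
        """Substitute the cohort-mean IAF when no in-band peak was found."""
        if self.iaf_hz is not None:
            return self
        return SubjectSpectralProfile(iaf_hz=cohort_mean_iaf, fallback=True)


def preprocess_epochs(
    raw: SensorEpochs,
    lowpass_hz: float = 90.0,
    notch_hz: float = 60.0,
    target_fs_hz: float = 300.0,
    min_length_s: float = 2.0,
) -> SensorEpochs:
    """Demean, detrend, low-pass, notch, and decimate each trial."""
    fs = raw.fs_hz
    if fs < 2 * lowpass_hz + 1:
        raise ValueError("input sampling rate too low for the requested low-pass")
    n_time = raw.epochs.shape[2]
    if n_time < min_length_s * fs:
        raise ValueError(
            f"trials are {n_time / fs:.3f} s, shorter than {min_length_s} s"
        )
    q = fs / target_fs_hz
    if abs(q - round(q)) > 1e-9:
        raise ValueError("fs must be an integer multiple of the target rate")
    q = int(round(q))

    x = _linear_detrend(raw.epochs)
    sos_lp = signal.butter(4, lowpass_hz / (fs / 2), btype="low", output="sos")
    b, a = signal.iirnotch(notch_hz, Q=5.0, fs=fs)
    sos = np.vstack([sos_lp, signal.tf2sos(b, a)])
    shape = x.shape
    x = signal.sosfiltfilt(sos, x.reshape(-1, shape[-1]), axis=-1).reshape(shape)
    x = x[..., ::q]
    return SensorEpochs(
        epochs=x, fs_hz=fs / q, conditions=raw.conditions,
        sensor_positions=raw.sensor_positions, reject=raw.reject.copy(),
        subject_id=raw.subject_id,
    )


def _linear_detrend(x: np.ndarray) -> np.ndarray:
    """Closed-form demean + linear detrend along the last axis."""
    n = x.shape[-1]
    t = np.arange(n) - (n - 1) / 2.0
    x = x - x.mean(axis=-1, keepdims=True)
    slope = (x @ t) / (t @ t)
    return x - slope[..., None] * t


def detect_muscle_artifacts(
    raw: SensorEpochs,
    band_hz: tuple[float, float] = MUSCLE_BAND_HZ,
    z_threshold: float = 5.0,
    smooth_s: float = 0.02,
) -> np.ndarray:
    """Flag trials with high-band (muscle) bursts.

    The raw data are band-passed, rectified, and smoothed; the envelope is
    z-scored per sensor across all trials and samples, the z values are
    accumulated over sensors (sum / sqrt(n_sensors), so broad-band bursts
    that hit many sensors stand out against per-sensor noise), and a trial
    is flagged when the accumulated z exceeds ``z_threshold`` anywhere.
    """
    fs = raw.fs_hz
    nyq = fs / 2
    if band_hz[1] >= nyq:
        raise ValueError("muscle band exceeds Nyquist; pass pre-decimation data")
    sos = signal.butter(
        4, [band_hz[0] / nyq, band_hz[1] / nyq], btype="bandpass", output="sos"
    )
    shape = raw.epochs.shape
    filt = signal.sosfiltfilt(
        sos, raw.epochs.reshape(-1, shape[-1]), axis=-1
    ).reshape(shape)
    env = np.abs(filt)
    w = max(int(round(smooth_s * fs)), 1)
    env = ndimage_uniform(env, w)
    mu = env.mean(axis=(0, 2), keepdims=True)
    sd = env.std(axis=(0, 2), keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    z = ((env - mu) / sd).sum(axis=1) / np.sqrt(shape[1])  # trial x time
    return (z > z_threshold).any(axis=-1)


def ndimage_uniform(x: np.ndarray, size: int) -> np.ndarray:
    """Moving average along the last axis (uniform filter, reflected edges)."""
    from scipy.ndimage import uniform_filter1d

    return uniform_filter1d(x, size=size, axis=-1, mode="reflect")


def dpss_tapers(n_samples: int, nw: float, k: int) -> np.ndarray:
    """K orthonormal Slepian tapers with time-bandwidth product NW."""
    if k < 1:
        raise ValueError("need at least one taper")
    if k > 2 * nw - 1 + 1e-9:
        raise ValueError(f"K={k} tapers exceed the 2NW-1={2 * nw - 1:.1f} limit")
    tapers = dpss(n_samples, nw, Kmax=k)
    tapers = np.atleast_2d(tapers)
    # enforce exact unit energy (scipy returns eigenvectors; re-normalize)
    tapers = tapers / np.linalg.norm(tapers, axis=1, keepdims=True)
    return tapers


def mtm_spectrum(
    epochs: SensorEpochs,
    fmin: float = 1.0,
    fmax: float = 20.0,
    n_tapers: int = 1,
    half_bandwidth_hz: float | None = None,
) -> Spectrum:
    """Multitaper power spectrum per trial and sensor on [fmin, fmax].

    Power is averaged over tapers and scaled so that summing the (one-sided)
    spectrum over all frequencies recovers the tapered signal variance.
    """
    x = epochs.epochs
    n = x.shape[-1]
    fs = epochs.fs_hz
    t_len = n / fs
    if half_bandwidth_hz is None:
        nw = (n_tapers + 1) / 2.0
    else:
        nw = half_bandwidth_hz * t_len
    tapers = dpss_tapers(n, nw, n_tapers)

    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sel = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    if not sel.any():
        raise ValueError("no frequency bins inside the requested window")
    # trial x sensor x taper x freq
    tapered = x[:, :, None, :] * tapers[None, None, :, :]
    coef = np.fft.rfft(tapered, axis=-1)
    power = (np.abs(coef) ** 2) / n
    scale = np.full(freqs.size, 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power = (power * scale).mean(axis=2)  # average tapers
    return Spectrum(freqs[sel], power[..., sel], n_tapers)


def detect_iaf(
    mean_spectrum: np.ndarray,
    frequencies: np.ndarray,
    band: tuple[float, float] = ALPHA_BAND_HZ,
) -> SubjectSpectralProfile:
    """Largest strict local maximum of the averaged spectrum; IAF if in band.

    A local maximum must exceed both immediate neighbours. If the largest one
    falls outside [8, 12] Hz — or no local maximum exists — the profile comes
    back unresolved and the caller substitutes the cohort-mean IAF.
    """
    p = np.asarray(mean_spectrum, float)
    f = np.asarray(frequencies, float)
    if p.shape != f.shape or p.ndim != 1:
        raise ValueError("spectrum and frequency grid must be 1-D and aligned")
    interior = np.arange(1, p.size - 1)
    is_max = (p[interior] > p[interior - 1]) & (p[interior] > p[interior + 1])
    peaks = interior[is_max]
    if peaks.size == 0:
        return SubjectSpectralProfile(iaf_hz=None, fallback=True)
    best = peaks[np.argmax(p[peaks])]
    f_peak = float(f[best])
    if band[0] <= f_peak <= band[1]:
        return SubjectSpectralProfile(iaf_hz=f_peak, fallback=False)
    return SubjectSpectralProfile(iaf_hz=None, fallback=True)


def iaf_band_power(
    epochs: SensorEpochs,
    profile: SubjectSpectralProfile,
    n_tapers: int = 2,
    grid_limits: tuple[float, float] = (1.0, 20.0),
) -> np.ndarray:
    """Mean multitaper power in [IAF-1, IAF+1] Hz, per trial and sensor."""
    lo, hi = profile.band
    if lo < grid_limits[0] or hi > grid_limits[1]:
        raise ValueError(
            f"IAF band [{lo}, {hi}] Hz exceeds the [{grid_limits[0]}, "
            f"{grid_limits[1]}] Hz analysis grid"
        )
    spec = mtm_spectrum(epochs, fmin=lo, fmax=hi, n_tapers=n_tapers)
    return spec.power.mean(axis=-1)
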