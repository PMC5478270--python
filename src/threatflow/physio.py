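"""Startle-EMG scoring and continuous anxiety-rating summaries.

Scoring chain per probe: band-pass filter the raw EMG, full-wave rectify,
smooth with a 20 ms time constant, then take the peak of the smoothed signal
in the 20-100 ms post-onset window. Peaks (and ratings) are z-scored and
rescaled to T-scores within subject before condition averaging.

Note on the band edges: a 30-500 Hz pass band is not realizable at the 600 Hz
sampling rate used here (Nyquist = 300 Hz), so the filter is a 30 Hz high-pass
combined with a low-pass just below Nyquist.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "EmgTrace",
    "ConditionSummary",
    "bandpass_rectify_smooth",
    "score_startle",
    "score_all_probes",
    "to_t_scores",
    "condition_summary",
]

SCORE_WINDOW_MS = (20.0, 100.0)


@dataclass
class EmgTrace:
    """Raw EMG samples with probe onsets and per-probe condition labels."""

    samples: np.ndarray
    fs_hz: float
    probe_onsets: np.ndarray  # sample indices, strictly increasing
    conditions: np.ndarray  # 'safe' / 'threat' per probe
    habituation: np.ndarray | None = None  # bool per probe

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        self.probe_onsets = np.asarray(self.probe_onsets, int)
        self.conditions = np.asarray(self.conditions)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if np.any(np.diff(self.probe_onsets) <= 0):
            raise ValueError("probe onsets must be strictly increasing")
        if self.probe_onsets.shape != self.conditions.shape:
            raise ValueError("one condition label per probe required")
        if self.habituation is None:
            self.habituation = np.zeros(self.probe_onsets.size, bool)
        else:
            self.habituation = np.asarray(self.habituation, bool)


def bandpass_rectify_smooth(
    x: np.ndarray,
    fs_hz: float,
    highpass_hz: float = 30.0,
    tau_ms: float = 20.0,
    smoother: str = "exp",
) -> np.ndarray:
    """Filter, rectify and smooth an EMG series; returns the envelope.

    The band-pass is applied zero-phase (forward-backward Butterworth) so the
    envelope peak latency is unbiased. Smoothing is a single-pole RC filter
    with the given time constant; ``smoother='boxcar'`` substitutes a moving
    average of the same length.
    """
    x = np.asarray(x, float)
    nyq = fs_hz / 2.0
    sos = signal.butter(4, [highpass_hz / nyq, 0.99], btype="bandpass", output="sos")
    filt = signal.sosfiltfilt(sos, x)
    rect = np.abs(filt)
    if smoother == "exp":
        alpha = 1.0 - np.exp(-1.0 / (tau_ms * 1e-3 * fs_hz))
        return signal.lfilter([alpha], [1.0, alpha - 1.0], rect)
    if smoother == "boxcar":
        w = max(int(round(tau_ms * 1e-3 * fs_hz)), 1)
        return np.convolve(rect, np.ones(w) / w, mode="same")
    raise ValueError(f"unknown smoother {smoother!r}")


def score_startle(trace: EmgTrace, probe_index: int, smoother: str = "exp") -> float:
    """Peak of the smoothed rectified EMG 20-100 ms after one probe onset."""
    env = bandpass_rectify_smooth(trace.samples, trace.fs_hz, smoother=smoother)
    return _peak_in_window(env, trace, probe_index)


def score_all_probes(trace: EmgTrace, smoother: str = "exp") -> np.ndarray:
    """Vector of raw peak magnitudes, one per probe (envelope computed once)."""
    env = bandpass_rectify_smooth(trace.samples, trace.fs_hz, smoother=smoother)
    return np.array(
        [_peak_in_window(env, trace, i) for i in range(trace.probe_onsets.size)]
    )


def _peak_in_window(env: np.ndarray, trace: EmgTrace, probe_index: int) -> float:
    onset = int(trace.probe_onsets[probe_index])
    lo = onset + int(round(SCORE_WINDOW_MS[0] * 1e-3 * trace.fs_hz))
    hi = onset + int(round(SCORE_WINDOW_MS[1] * 1e-3 * trace.fs_hz))
    if hi >= env.size:
        raise ValueError(
            f"scoring window for probe {probe_index} extends past the trace end"
        )
    return float(env[lo : hi + 1].max())


def to_t_scores(values) -> np.ndarray:
    """Within-subject T-scores: 50 + 10 * (x - mean) / sample SD."""
    x = np.asarray(values, float)
    if x.size < 2:
        raise ValueError("need at least 2 values to standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-scores undefined")
    return 50.0 + 10.0 * (x - x.mean()) / sd


@dataclass
class ConditionSummary:
    """One subject's condition means on the T-score scale."""

    startle_safe_t: float | None = None
    startle_threat_t: float | None = None
    aps: float | None = None
    rating_safe_t: float | None = None
    rating_threat_t: float | None = None
    rating_diff: float | None = None
    n_scored: dict = field(default_factory=dict)


def condition_summary(
    peaks=None,
    conditions=None,
    habituation=None,
    rating_values=None,
    rating_conditions=None,
) -> ConditionSummary:
    """T-score startle peaks and/or ratings within subject and average by condition.

    Habituation probes are excluded before normalization. Both conditions must
    be represented in every supplied measure.
    """
    out = ConditionSummary()
    if peaks is not None:
        peaks = np.asarray(peaks, float)
        conditions = np.asarray(conditions)
        keep = (
            ~np.asarray(habituation, bool)
            if habituation is not None
            else np.ones(peaks.size, bool)
        )
        safe_m, threat_m, n = _t_condition_means(peaks[keep], conditions[keep])
        out.startle_safe_t, out.startle_threat_t = safe_m, threat_m
        out.aps = threat_m - safe_m
        out.n_scored["startle"] = n
    if rating_values is not None:
        safe_m, threat_m, n = _t_condition_means(
            np.asarray(rating_values, float), np.asarray(rating_conditions)
        )
        out.rating_safe_t, out.rating_threat_t = safe_m, threat_m
        out.rating_diff = threat_m - safe_m
        out.n_scored["rating"] = n
    return out


def _t_condition_means(values, conditions):
    for cond in ("safe", "threat"):
        if not np.any(conditions == cond):
            raise ValueError(f"no scored samples in condition {cond!r}")
    t = to_t_scores(values)
    return (
        float(t[conditions == "safe"].mean()),
        float(t[conditions == "threat"].mean()),
        int(values.size),
    )


def summary_table(summaries: dict[str, ConditionSummary]) -> pd.DataFrame:
    """Stack per-subject summaries into a tidy frame (one row per subject)."""
    rows = []
    for subject, s in summaries.items():
        rows.append(
            {
                "subject": subject,
                "startle_safe_t": s.startle_safe_t,
                "startle_threat_t": s.startle_threat_t,
                "aps": s.aps,
                "rating_safe_t": s.rating_safe_t,
                "rating_threat_t": s.rating_threat_t,
                "rating_diff": s.rating_diff,
            }
        )
    return pd.DataFrame(rows)
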