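"""Synthetic startle-EMG traces and continuous anxiety ratings.

Each probe gets a band-limited blink burst whose rectified-and-smoothed
envelope peaks at a known latency inside the 20-100 ms scoring window; threat
probes are scaled by ``threat_multiplier``. Ratings live on a 0-255 hue
scale: per-probe samples (MEG mode) or per-frame samples (fMRI mode), with a
condition shift of ``rating_effect``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..physio import EmgTrace
from .types import BlockSchedule, GroundTruth

__all__ = ["EmgSimConfig", "make_emg_session", "make_rating_series"]

# mean of |sin| over a cycle: rectified-sine DC level used to calibrate peaks
RECTIFIED_SINE_MEAN = 2.0 / np.pi


@dataclass
class EmgSimConfig:
    fs_hz: float = 600.0
    blink_latency_ms: tuple = (40.0, 80.0)
    blink_width_ms: float = 40.0
    blink_amp_scale: float = 1.0
    carrier_hz: float = 80.0
    threat_multiplier: float = 2.0
    noise_sigma: float = 0.02
    amp_jitter: float = 0.1  # lognormal sigma of per-probe amplitude
    rating_base: float = 60.0
    rating_effect: float = 100.0
    rating_noise: float = 8.0
    rating_subject_sigma: float = 15.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.blink_latency_ms
        if lo < 20.0 or hi > 100.0 or lo > hi:
            raise ValueError(
                "blink latency range must sit inside the 20-100 ms scoring window"
            )
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")


def make_emg_session(
    cfg: EmgSimConfig,
    schedules: list[BlockSchedule],
    rng=None,
    subject_offset: float | None = None,
    subject_gain: float = 1.0,
):
    """Build one subject's concatenated EMG trace, rating table, ground truth.

    ``schedules`` must carry probes (MEG mode). ``subject_gain`` scales both
    the startle potentiation (threat_multiplier - 1) and the rating effect,
    so cohorts built with varying gains carry correlated subject-level
    anxiety variance. Returns ``(EmgTrace, ratings_frame, GroundTruth)``.
    """
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    if not any(sc.probe_times.size for sc in schedules):
        raise ValueError("schedules carry no probes; EMG needs probe onsets")
    fs = cfg.fs_hz
    gap_s = 5.0
    onsets, conditions, habituation = [], [], []
    chunks = []
    t_offset = 0.0
    for sc in schedules:
        run_end = float(sc.probe_times[-1]) + 1.0
        n = int(round((run_end + gap_s) * fs))
        chunks.append(np.zeros(n))
        onsets.extend(((sc.probe_times + t_offset) * fs).round().astype(int))
        conditions.extend(sc.probe_conditions)
        habituation.extend(sc.habituation)
        t_offset += run_end + gap_s
    samples = np.concatenate(chunks)
    onsets = np.asarray(onsets, int)
    conditions = np.asarray(conditions)
    habituation = np.asarray(habituation, bool)

    width = int(round(cfg.blink_width_ms * 1e-3 * fs))
    # the scorer smooths with a 20 ms RC filter, which attenuates a burst of
    # this width; pre-compensate so the scored peak lands on the drawn amp
    alpha = 1.0 - np.exp(-1.0 / (20e-3 * fs))
    from scipy.signal import lfilter

    env_gain = float(
        lfilter([alpha], [1.0, alpha - 1.0], np.hanning(width)).max()
    )
    true_amp = np.empty(onsets.size)
    if subject_offset is None:
        subject_offset = float(rng.normal(0.0, cfg.rating_subject_sigma))
    eff_mult = 1.0 + (cfg.threat_multiplier - 1.0) * subject_gain
    eff_rating = cfg.rating_effect * subject_gain
    for i, onset in enumerate(onsets):
        latency_ms = rng.uniform(*cfg.blink_latency_ms)
        mult = eff_mult if conditions[i] == "threat" else 1.0
        amp = (
            cfg.blink_amp_scale
            * mult
            * float(np.exp(rng.normal(0.0, cfg.amp_jitter)))
        )
        true_amp[i] = amp
        center = onset + int(round(latency_ms * 1e-3 * fs))
        start = center - width // 2
        env = np.hanning(width)
        tt = np.arange(width) / fs
        carrier = np.sin(2 * np.pi * cfg.carrier_hz * tt + rng.uniform(0, 2 * np.pi))
        # divide by the rectified-carrier mean and the smoother's envelope
        # gain so the scored (smoothed rectified) peak lands near amp
        burst = amp / (RECTIFIED_SINE_MEAN * env_gain) * env * carrier
        sl = slice(max(start, 0), min(start + width, samples.size))
        samples[sl] += burst[: sl.stop - sl.start]
    samples += rng.standard_normal(samples.size) * cfg.noise_sigma

    rating = np.clip(
        cfg.rating_base
        + subject_offset
        + np.where(conditions == "threat", eff_rating, 0.0)
        + rng.normal(0.0, cfg.rating_noise, size=onsets.size),
        0.0,
        255.0,
    )
    ratings = pd.DataFrame(
        {
            "probe": np.arange(onsets.size),
            "onset_sample": onsets,
            "condition": conditions,
            "habituation": habituation,
            "rating": rating,
        }
    )
    trace = EmgTrace(
        samples=samples, fs_hz=fs, probe_onsets=onsets,
        conditions=conditions, habituation=habituation,
    )
    truth = GroundTruth(
        threat_multiplier=cfg.threat_multiplier,
        rating_effect=cfg.rating_effect,
        probe_amplitudes=[true_amp],
    )
    return trace, ratings, truth


def make_rating_series(
    cfg: EmgSimConfig, schedule: BlockSchedule, rng=None,
    subject_offset: float = 0.0,
) -> pd.DataFrame:
    """Per-frame ratings for fMRI mode (sampled once per TR, block-constant mean)."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    cond = schedule.condition_per_frame
    rating = np.clip(
        cfg.rating_base
        + subject_offset
        + np.where(cond == "threat", cfg.rating_effect, 0.0)
        + rng.normal(0.0, cfg.rating_noise, size=cond.size),
        0.0,
        255.0,
    )
    return pd.DataFrame(
        {"frame": np.arange(cond.size), "condition": cond, "rating": rating}
    )
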