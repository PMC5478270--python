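"""Synthetic MEG cohorts: spherical-head dipole sources driving radial sensors.

Sensor signals are leadfield projections of amplitude-modulated alpha
oscillators (one per active source, at each subject's individual alpha
frequency) plus white sensor noise. Threat trials scale the active-source
amplitude by ``alpha_mod``, so the injected sensor-power ratio is
``alpha_mod**2``. A fraction of trials receives 110-140 Hz muscle-band
bursts, recorded in the ground truth for artifact-detection tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from ..dics_source import SourceModel, build_source_grid, sarvas_leadfield
from ..meg_spectral import SensorEpochs
from .types import GroundTruth

__all__ = ["MegSimConfig", "hemisphere_sensors", "make_meg_cohort", "build_default_source_model"]


def hemisphere_sensors(n_sensors: int, radius_m: float, min_z_frac: float = 0.15):
    """Roughly uniform sensor cap on the upper hemisphere, radial orientations."""
    i = np.arange(n_sensors)
    z = min_z_frac + (1.0 - min_z_frac) * (i + 0.5) / n_sensors
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # golden-angle spiral
    r_xy = np.sqrt(1.0 - z**2)
    pos = radius_m * np.column_stack([r_xy * np.cos(phi), r_xy * np.sin(phi), z])
    ori = pos / np.linalg.norm(pos, axis=1, keepdims=True)
    return pos, ori


@dataclass
class MegSimConfig:
    n_subjects: int = 12
    n_runs: int = 4  # only used when emitting probe schedules
    n_sensors: int = 64
    sensor_radius_m: float = 0.12
    sphere_radius_m: float = 0.09
    source_spacing_m: float = 0.02
    active_sources: np.ndarray | None = None  # grid indices; None -> parietal-ish
    iaf_range_hz: tuple = (8.0, 12.0)
    iaf_values: np.ndarray | None = None  # explicit per-subject IAFs
    alpha_mod: float = 0.8
    epoch_length_s: float = 2.0
    fs_hz: float = 600.0
    trials_per_condition: int = 40
    trial_jitter: int = 0  # random per-condition trial deficit (0..jitter)
    artifact_rate: float = 0.0
    artifact_amp: float = 10.0
    noise_sigma: float = 0.5
    source_amp: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.alpha_mod <= 0:
            raise ValueError("alpha_mod must be positive")
        n = self.epoch_length_s * self.fs_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_length_s * fs_hz must be an integer")
        if self.sensor_radius_m <= self.sphere_radius_m:
            raise ValueError("sensors must lie outside the source sphere")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must be a fraction")


def build_default_source_model(cfg: MegSimConfig) -> SourceModel:
    """Grid + tangential fixed orientations + spherical leadfields."""
    positions = build_source_grid(cfg.sphere_radius_m, cfg.source_spacing_m)
    radial = positions / np.linalg.norm(positions, axis=1, keepdims=True)
    # deterministic tangential orientation: radial x z-hat, fall back to x-hat
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (positions.shape[0], 1))
    near_pole = np.abs(radial[:, 2]) > 0.98
    ref[near_pole] = [1.0, 0.0, 0.0]
    tang = np.cross(radial, ref)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    sensor_pos, sensor_ori = hemisphere_sensors(cfg.n_sensors, cfg.sensor_radius_m)
    lead = np.stack(
        [
            sarvas_leadfield(p, o, sensor_pos, sensor_ori,
                             sphere_radius=cfg.sphere_radius_m)
            for p, o in zip(positions, tang)
        ]
    )
    return SourceModel(
        positions=positions, orientations=tang, leadfields=lead,
        sphere_center=np.zeros(3), sphere_radius=cfg.sphere_radius_m,
        grid_spacing=cfg.source_spacing_m,
    )


def default_active_source(model: SourceModel) -> np.ndarray:
    """Single superficial left-parietal-ish grid node."""
    target = np.array([-0.035, -0.02, 0.06])
    return np.array([int(np.argmin(np.linalg.norm(model.positions - target, axis=1)))])


def make_meg_cohort(cfg: MegSimConfig):
    """Generate ``(subject_epochs, source_model, ground_truth)``."""
    rng = np.random.default_rng(cfg.seed)
    model = build_default_source_model(cfg)
    active = (
        default_active_source(model)
        if cfg.active_sources is None
        else np.asarray(cfg.active_sources, int)
    )
    if active.min() < 0 or active.max() >= model.n_sources:
        raise ValueError("active sources outside the grid")
    sensor_pos, _ = hemisphere_sensors(cfg.n_sensors, cfg.sensor_radius_m)

    n_time = int(round(cfg.epoch_length_s * cfg.fs_hz))
    t = np.arange(n_time) / cfg.fs_hz
    L_act = model.leadfields[active]  # (n_active, n_sensors)
    # scale so the signal's sensor RMS is comparable to noise_sigma units
    lead_scale = 1.0 / np.sqrt((L_act**2).mean())

    if cfg.iaf_values is not None:
        iafs = np.asarray(cfg.iaf_values, float)
        if iafs.size != cfg.n_subjects:
            raise ValueError("iaf_values must have one entry per subject")
    else:
        iafs = rng.uniform(*cfg.iaf_range_hz, size=cfg.n_subjects)

    sos_muscle = sp_signal.butter(
        4, [110.0 / (cfg.fs_hz / 2), 140.0 / (cfg.fs_hz / 2)],
        btype="bandpass", output="sos",
    )

    subjects, artifact_flags = [], []
    for s in range(cfg.n_subjects):
        n_per = {
            "safe": cfg.trials_per_condition
            - (int(rng.integers(0, cfg.trial_jitter + 1)) if cfg.trial_jitter else 0),
            "threat": cfg.trials_per_condition
            - (int(rng.integers(0, cfg.trial_jitter + 1)) if cfg.trial_jitter else 0),
        }
        conditions = np.array(
            ["safe"] * n_per["safe"] + ["threat"] * n_per["threat"]
        )
        rng.shuffle(conditions)
        n_trials = conditions.size
        flags = rng.random(n_trials) < cfg.artifact_rate
        amp = cfg.source_amp * np.where(conditions == "threat", cfg.alpha_mod, 1.0)
        phases = rng.uniform(0, 2 * np.pi, size=(n_trials, active.size))
        src = amp[:, None, None] * np.sin(
            2 * np.pi * iafs[s] * t[None, None, :] + phases[:, :, None]
        )  # trial x active x time
        epochs = np.einsum("ns,tsk->tnk", L_act.T * lead_scale, src)
        epochs += rng.standard_normal(epochs.shape) * cfg.noise_sigma
        for tr in np.flatnonzero(flags):
            burst = rng.standard_normal((cfg.n_sensors, n_time))
            burst = sp_signal.sosfiltfilt(sos_muscle, burst, axis=-1)
            w = int(0.3 * cfg.fs_hz)
            start = int(rng.integers(0, n_time - w))
            window = np.zeros(n_time)
            window[start : start + w] = np.hanning(w)
            hit = rng.random(cfg.n_sensors) < 0.25
            epochs[tr, hit] += (
                cfg.artifact_amp * cfg.noise_sigma * burst[hit] * window
            )
        subjects.append(
            SensorEpochs(
                epochs=epochs, fs_hz=cfg.fs_hz, conditions=conditions,
                sensor_positions=sensor_pos, subject_id=f"sub-{s:02d}",
            )
        )
        artifact_flags.append(flags)

    truth = GroundTruth(
        iaf_hz=iafs, alpha_mod=cfg.alpha_mod, active_sources=active,
        artifact_flags=artifact_flags,
    )
    return subjects, model, truth
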