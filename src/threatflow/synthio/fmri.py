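"""Synthetic fMRI cohorts with a known connectivity increase at hub voxels.

Every in-mask voxel time course is

    x_v(t) = a_v(t) * g(t) + b_v * s(t) + e_v(t)

where ``g`` is a cohort-wide latent signal, ``s`` a hub-region latent, and
``e_v`` unit-variance AR(1) noise spatially smoothed within the mask. The
shared-latent weights are solved in closed form from the target correlations:
any two voxels correlate at ``base_rho``; during threat frames the weight of
hub voxels is raised so hub-hub correlation becomes ``base_rho + delta_rho``
exactly. That closed form is the analytic ground truth recovery tests use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from ..fmri_conn import SubjectTimeseries, censor_frames, smooth_within_mask
from .schedule import build_block_schedule
from .types import GroundTruth

__all__ = ["FmriSimConfig", "ellipsoid_mask", "default_hub", "make_fmri_cohort"]


def ellipsoid_mask(grid_shape, semiaxes=None) -> np.ndarray:
    """Boolean ellipsoid centered on the grid (desk-scale grey-matter stand-in)."""
    shape = tuple(grid_shape)
    if semiaxes is None:
        semiaxes = tuple((n - 1) / 2.0 for n in shape)
    center = [(n - 1) / 2.0 for n in shape]
    idx = np.indices(shape)
    q = sum(
        ((idx[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3)
    )
    return q <= 1.0


@dataclass
class FmriSimConfig:
    n_subjects: int = 12
    grid_shape: tuple = (12, 12, 12)
    mask_semiaxes: tuple | None = None
    tr_s: float = 2.0
    run_length_s: float = 490.0
    n_runs: int = 4
    hub_voxels: np.ndarray | None = None  # in-mask indices; None -> default ball
    delta_rho: float = 0.15
    base_rho: float = 0.10
    hub_coherence: float = 0.0  # weight b_v of the hub-region latent
    ar1_phi: float = 0.3
    fwhm_mm: float = 6.0
    voxel_size_mm: float = 3.0
    motion_sigma: float = 0.05
    motion_spike_prob: float = 0.01
    shock_prob: float = 1.0 / 12.0
    start_condition: str = "safe"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.delta_rho < 1.0:
            raise ValueError("delta_rho must be in [0, 1)")
        if not 0.0 <= self.base_rho < 1.0:
            raise ValueError("base_rho must be in [0, 1)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not -1.0 < self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must be in (-1, 1)")
        target = self.base_rho + self.hub_coherence**2 + self.delta_rho
        if target >= 1.0:
            raise ValueError(
                "delta_rho too large: implied latent weights are non-real"
            )

    @property
    def mask(self) -> np.ndarray:
        return ellipsoid_mask(self.grid_shape, self.mask_semiaxes)


def default_hub(mask: np.ndarray, radius_vox: float = 1.6) -> np.ndarray:
    """Compact ball of in-mask voxels offset from the mask center (node ids)."""
    coords = np.argwhere(mask)
    center = coords.mean(axis=0) + np.array([2.0, 2.0, 1.0])
    d = np.linalg.norm(coords - center, axis=1)
    hub = np.flatnonzero(d <= radius_vox)
    if hub.size == 0:
        hub = np.array([int(np.argmin(d))])
    return hub


def _latent_weight(rho: float) -> float:
    return float(np.sqrt(rho / (1.0 - rho)))


def _ar1(rng, shape, phi) -> np.ndarray:
    """AR(1) noise along axis 0 with unit marginal variance."""
    w = rng.standard_normal(shape)
    if phi == 0:
        return w
    e = sp_signal.lfilter([np.sqrt(1 - phi**2)], [1.0, -phi], w, axis=0)
    e[0] = w[0]  # stationary start
    return e


def make_fmri_cohort(cfg: FmriSimConfig):
    """Generate ``(subjects, ground_truth)`` reproducibly from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    mask = cfg.mask
    n_vox = int(mask.sum())
    hub = (
        default_hub(mask)
        if cfg.hub_voxels is None
        else np.asarray(cfg.hub_voxels, int)
    )
    if hub.min() < 0 or hub.max() >= n_vox:
        raise ValueError("hub voxels must index in-mask voxels")

    b = cfg.hub_coherence
    rho_safe_hub = cfg.base_rho + b**2  # hub-hub correlation when safe
    rho_threat_hub = rho_safe_hub + cfg.delta_rho
    a0 = _latent_weight(cfg.base_rho)
    # threat hub weight solves a_T^2 + b^2 = rho_T / (1 - rho_T)
    a_t_sq = rho_threat_hub / (1.0 - rho_threat_hub) - b**2
    if a_t_sq < 0:
        raise ValueError("hub_coherence too large for the requested delta_rho")
    a_t = float(np.sqrt(a_t_sq))

    subjects = []
    for s in range(cfg.n_subjects):
        schedules = build_block_schedule("fmri", cfg, rng)
        labels = np.concatenate([sc.condition_per_frame for sc in schedules])
        run_index = np.concatenate(
            [np.full(sc.frame_times.size, sc.run_index) for sc in schedules]
        )
        n_frames = labels.size
        shock_frames = []
        offset = 0
        for sc in schedules:
            shock_frames.extend(
                offset + np.searchsorted(sc.frame_times, sc.shock_times, "right") - 1
            )
            offset += sc.frame_times.size
        shock_frames = np.asarray(shock_frames, int)

        g = rng.standard_normal(n_frames)
        region = rng.standard_normal(n_frames)
        noise = _ar1(rng, (n_frames, *cfg.grid_shape), cfg.ar1_phi)
        noise = smooth_within_mask(
            noise, mask, fwhm_mm=cfg.fwhm_mm, voxel_size_mm=cfg.voxel_size_mm
        )
        e = noise[:, mask].T  # voxels x frames
        # hub voxels get fresh unsmoothed noise: smoothing correlates
        # neighbours and would break the closed-form hub correlations
        e[hub] = _ar1(rng, (n_frames, hub.size), cfg.ar1_phi).T
        e -= e.mean(axis=1, keepdims=True)
        sd = e.std(axis=1, keepdims=True)
        e /= np.where(sd > 0, sd, 1.0)

        weights = np.full((n_vox, n_frames), a0)
        threat = labels == "threat"
        weights[np.ix_(hub, np.flatnonzero(threat))] = a_t
        data = weights * g[None, :] + e
        if b > 0:
            data[hub] += b * region[None, :]

        motion = np.cumsum(
            rng.standard_normal((n_frames, 6)) * cfg.motion_sigma, axis=0
        )
        spikes = rng.random(n_frames) < cfg.motion_spike_prob
        motion[spikes] += rng.standard_normal((int(spikes.sum()), 6)) * 0.5
        censor = censor_frames(motion)

        subjects.append(
            SubjectTimeseries(
                data=data, mask=mask, labels=labels, censor=censor,
                motion=motion, run_index=run_index,
                subject_id=f"sub-{s:02d}", shock_frames=shock_frames,
            )
        )

    truth = GroundTruth(
        hub_voxels=hub,
        delta_rho=cfg.delta_rho,
        base_rho=cfg.base_rho,
        hub_corr_safe=rho_safe_hub,
        hub_corr_threat=rho_threat_hub,
    )
    return subjects, truth
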