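"""Condition-wise fMRI connectivity: censoring, nuisance regression,
within-mask smoothing, global brain connectivity (GBC) and seed maps.

All per-voxel arrays are ordered by the flattened (C-order) indices of the
in-mask voxels of the 3-D boolean mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy import ndimage

from .stats_core import R_CLIP

__all__ = [
    "SubjectTimeseries",
    "ConnectivityMap",
    "censor_frames",
    "shock_censor",
    "matched_motion_censor",
    "motion_enorm",
    "nuisance_regress",
    "gamma_variate_hrf",
    "smooth_within_mask",
    "gbc_map",
    "whole_brain_gbc",
    "seed_connectivity",
]


@dataclass
class SubjectTimeseries:
    """Masked voxel x frame matrix with frame metadata for one subject.

    data : (n_voxels, n_frames) scaled signal, rows ordered by mask indices
    mask : 3-D boolean volume; ``mask.sum() == n_voxels``
    labels : 'safe' / 'threat' / 'pre' per frame
    censor : True where a frame must not enter correlations
    motion : (n_frames, 6) registration parameters
    run_index : run id per frame (used for per-run detrending / boundaries)
    """

    data: np.ndarray
    mask: np.ndarray
    labels: np.ndarray
    censor: np.ndarray
    motion: np.ndarray
    run_index: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    subject_id: str = ""
    shock_frames: np.ndarray = field(default_factory=lambda: np.array([], int))
    event_frames: np.ndarray = field(default_factory=lambda: np.array([], int))

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.mask = np.asarray(self.mask, bool)
        self.labels = np.asarray(self.labels)
        self.censor = np.asarray(self.censor, bool)
        self.run_index = np.asarray(self.run_index, int)
        n_vox, n_frames = self.data.shape
        if self.mask.sum() != n_vox:
            raise ValueError("mask voxel count does not match data rows")
        for name, arr in (("labels", self.labels), ("censor", self.censor),
                          ("run_index", self.run_index)):
            if arr.shape[0] != n_frames:
                raise ValueError(f"{name} misaligned with frame axis")

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def condition_frames(self, condition: str) -> np.ndarray:
        """Indices of uncensored frames carrying the given label."""
        return np.flatnonzero((self.labels == condition) & ~self.censor)


@dataclass
class ConnectivityMap:
    """Per-in-mask-voxel Fisher-Z values for one subject x condition."""

    values: np.ndarray
    subject_id: str
    condition: str
    kind: str = "gbc"  # or 'seed'
    roi_flags: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if not np.isfinite(self.values).all():
            raise ValueError("connectivity map contains non-finite values")


def motion_enorm(motion: np.ndarray) -> np.ndarray:
    """Euclidean norm of the first difference of the motion parameters.

    First frame gets 0 (no preceding frame to difference against).
    """
    motion = np.asarray(motion, float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("expected a frames x 6 motion table")
    d = np.diff(motion, axis=0, prepend=motion[:1])
    return np.sqrt((d**2).sum(axis=1))


def censor_frames(motion: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Flag frames whose motion-derivative Euclidean norm exceeds ``threshold`` mm."""
    return motion_enorm(motion) > threshold


def shock_censor(
    labels: np.ndarray,
    shock_frames: np.ndarray,
    run_index: np.ndarray | None = None,
    k: int = 10,
    base_censor: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, int]]:
    """Censor each shock frame and the following ``k - 1`` frames within its run.

    Returns the extended censor flags plus the count of newly censored frames
    per condition label.
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if run_index is None:
        run_index = np.zeros(n, int)
    run_index = np.asarray(run_index, int)
    flags = (
        np.zeros(n, bool) if base_censor is None else np.asarray(base_censor, bool).copy()
    )
    new = np.zeros(n, bool)
    for s in np.asarray(shock_frames, int):
        if not 0 <= s < n:
            raise ValueError(f"shock frame {s} outside the session")
        run = run_index[s]
        stop = s + k
        sel = np.arange(s, min(stop, n))
        sel = sel[run_index[sel] == run]
        new[sel] = True
    newly = new & ~flags
    counts = {
        str(c): int(newly[labels == c].sum()) for c in np.unique(labels)
    }
    return flags | new, counts


def matched_motion_censor(
    threat_censored: np.ndarray,
    safe_pool: np.ndarray,
    enorm: np.ndarray,
) -> np.ndarray:
    """Pick one safe frame per censored threat frame, greedily matched on motion.

    Threat frames are visited in order of their motion norm; each takes the
    remaining safe-pool frame with the nearest norm (without replacement), so
    the returned selection has exactly ``len(threat_censored)`` frames.
    """
    threat_censored = np.asarray(threat_censored, int)
    safe_pool = np.asarray(safe_pool, int)
    enorm = np.asarray(enorm, float)
    if safe_pool.size < threat_censored.size:
        raise ValueError(
            f"safe pool ({safe_pool.size}) smaller than the censored threat "
            f"set ({threat_censored.size})"
        )
    order = threat_censored[np.argsort(enorm[threat_censored], kind="stable")]
    remaining = list(safe_pool[np.argsort(enorm[safe_pool], kind="stable")])
    picked = []
    for t in order:
        j = int(np.argmin([abs(enorm[s] - enorm[t]) for s in remaining]))
        picked.append(remaining.pop(j))
    return np.sort(np.array(picked, int))


def gamma_variate_hrf(tr_s: float, duration_s: float = 16.0) -> np.ndarray:
    """Peak-normalized gamma-variate response h(t) ~ t^8.6 * exp(-t / 0.547)."""
    t = np.arange(0, duration_s + tr_s / 2, tr_s)
    h = t**8.6 * np.exp(-t / 0.547)
    peak = h.max()
    if peak == 0:  # TR too coarse to hit the peak region: evaluate densely
        td = np.linspace(0, duration_s, 2048)
        peak = (td**8.6 * np.exp(-td / 0.547)).max()
    return h / peak


def _run_design(
    n_frames: int,
    run_index: np.ndarray,
    motion: np.ndarray,
    event_frames: np.ndarray,
    tr_s: float,
    poly_order: int,
) -> np.ndarray:
    cols = []
    for run in np.unique(run_index):
        sel = run_index == run
        m = sel.sum()
        x = np.linspace(-1, 1, m)
        for order in range(poly_order + 1):
            col = np.zeros(n_frames)
            col[sel] = legendre.legval(x, [0] * order + [1])
            cols.append(col)
    cols.append(motion)
    if event_frames.size:
        stick = np.zeros(n_frames)
        stick[np.asarray(event_frames, int)] = 1.0
        hrf = gamma_variate_hrf(tr_s)
        reg = np.zeros(n_frames)
        for run in np.unique(run_index):
            sel = np.flatnonzero(run_index == run)
            conv = np.convolve(stick[sel], hrf)[: sel.size]
            reg[sel] = conv
        if reg.any():
            cols.append(reg[:, None])
    return np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])


def nuisance_regress(
    ts: SubjectTimeseries,
    tr_s: float = 2.0,
    poly_order: int = 3,
) -> SubjectTimeseries:
    """OLS removal of per-run Legendre drift, motion, and event responses.

    The model is fit on uncensored frames only; residuals are emitted for all
    frames (censored frames never enter later correlations anyway).
    """
    X = _run_design(
        ts.n_frames, ts.run_index, np.asarray(ts.motion, float),
        ts.event_frames, tr_s, poly_order,
    )
    keep = ~ts.censor
    Xk = X[keep]
    rank = np.linalg.matrix_rank(Xk)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix rank deficient on uncensored frames "
            f"(rank {rank} < {X.shape[1]} columns)"
        )
    beta, _, _, _ = np.linalg.lstsq(Xk, ts.data[:, keep].T, rcond=None)
    resid = ts.data - (X @ beta).T
    out = SubjectTimeseries(
        data=resid, mask=ts.mask, labels=ts.labels, censor=ts.censor,
        motion=ts.motion, run_index=ts.run_index, affine=ts.affine,
        subject_id=ts.subject_id, shock_frames=ts.shock_frames,
        event_frames=ts.event_frames,
    )
    return out


def smooth_within_mask(
    volumes: np.ndarray,
    mask: np.ndarray,
    fwhm_mm: float = 6.0,
    voxel_size_mm: float = 3.0,
) -> np.ndarray:
    """Gaussian smoothing restricted to the mask (edge-renormalized).

    The kernel is renormalized over in-mask voxels so no signal bleeds across
    the mask boundary and a constant field is reproduced exactly.

    Parameters
    ----------
    volumes : (..., nx, ny, nz) one volume or a series with leading axes
    """
    mask = np.asarray(mask, bool)
    if fwhm_mm <= 0:
        return np.asarray(volumes, float).copy()
    if fwhm_mm < voxel_size_mm:
        import warnings

        warnings.warn("FWHM below voxel size: smoothing is nearly a no-op")
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    x = np.asarray(volumes, float)
    single = x.ndim == 3
    if single:
        x = x[None]
    lead = x.shape[:-3]
    flat = x.reshape(-1, *mask.shape)
    weight = ndimage.gaussian_filter(mask.astype(float), sigma_vox)
    num = ndimage.gaussian_filter(
        np.where(mask[None], flat, 0.0), sigma=(0, sigma_vox, sigma_vox, sigma_vox)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mask[None], num / weight[None], 0.0)
    out = out.reshape(*lead, *mask.shape)
    return out[0] if single else out


def _condition_block(ts: SubjectTimeseries, condition: str, min_frames: int):
    frames = ts.condition_frames(condition)
    if frames.size < min_frames:
        raise ValueError(
            f"only {frames.size} uncensored frames in condition {condition!r} "
            f"(need >= {min_frames})"
        )
    block = ts.data[:, frames]
    sd = block.std(axis=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant time course in voxel(s) {bad[:5].tolist()}")
    return block


def gbc_map(
    ts: SubjectTimeseries,
    condition: str,
    include_self: bool = False,
    min_frames: int = 10,
) -> ConnectivityMap:
    """Global brain connectivity: per-voxel mean Fisher-Z correlation with
    every other in-mask voxel, over the condition's uncensored frames."""
    block = _condition_block(ts, condition, min_frames)
    n_vox = block.shape[0]
    if n_vox < 2:
        raise ValueError("GBC needs at least 2 in-mask voxels")
    r = np.corrcoef(block)
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    if include_self:
        values = z.mean(axis=1)
    else:
        np.fill_diagonal(z, 0.0)
        values = z.sum(axis=1) / (n_vox - 1)
    return ConnectivityMap(values, ts.subject_id, condition, kind="gbc")


def whole_brain_gbc(cmap: ConnectivityMap) -> float:
    """Unweighted mean of the map over in-mask voxels."""
    return float(cmap.values.mean())


def seed_connectivity(
    ts: SubjectTimeseries,
    roi_voxels: np.ndarray,
    condition: str,
    min_frames: int = 10,
) -> ConnectivityMap:
    """ROI-mean time course correlated with every in-mask voxel (Fisher-Z).

    ``roi_voxels`` indexes rows of ``ts.data``. ROI voxels stay in the output
    and are flagged.
    """
    roi_voxels = np.asarray(roi_voxels, int)
    if roi_voxels.size == 0:
        raise ValueError("empty ROI")
    if roi_voxels.min() < 0 or roi_voxels.max() >= ts.data.shape[0]:
        raise ValueError("ROI indices outside the mask")
    block = _condition_block(ts, condition, min_frames)
    seed = block[roi_voxels].mean(axis=0)
    if seed.std() == 0:
        raise ValueError("constant seed time course")
    seed_c = seed - seed.mean()
    block_c = block - block.mean(axis=1, keepdims=True)
    r = (block_c @ seed_c) / (
        np.linalg.norm(block_c, axis=1) * np.linalg.norm(seed_c)
    )
    z = np.arctanh(np.clip(r, -R_CLIP, R_CLIP))
    flags = np.zeros(ts.data.shape[0], bool)
    flags[roi_voxels] = True
    return ConnectivityMap(z, ts.subject_id, condition, kind="seed", roi_flags=flags)
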