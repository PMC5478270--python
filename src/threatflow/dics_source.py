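"""Spherical-conductor forward model and DICS beamformer.

The forward model is the closed-form magnetic field of a current dipole in a
homogeneous conducting sphere (Sarvas solution), projected onto radial sensor
directions. The inverse model is a frequency-domain beamformer: unit-gain
spatial filters built from the regularized real cross-spectral density of all
trials (the common filter), applied per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meg_spectral import SensorEpochs, dpss_tapers

__all__ = [
    "SourceModel",
    "CsdMatrix",
    "DicsFilters",
    "sarvas_leadfield",
    "build_source_grid",
    "compute_csd",
    "dics_filters",
    "project_source_power",
]

MU0_OVER_4PI = 1e-7  # T*m/A


@dataclass
class SourceModel:
    """Regular dipole grid with fixed orientations and per-source leadfields."""

    positions: np.ndarray  # (n_sources, 3) meters
    orientations: np.ndarray  # (n_sources, 3) unit vectors
    leadfields: np.ndarray  # (n_sources, n_sensors)
    sphere_center: np.ndarray
    sphere_radius: float
    grid_spacing: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.orientations = np.asarray(self.orientations, float)
        self.leadfields = np.asarray(self.leadfields, float)
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("orientations must be unit vectors")

    @property
    def n_sources(self) -> int:
        return self.positions.shape[0]


@dataclass
class CsdMatrix:
    """Hermitian sensor x sensor cross-spectral density for one band."""

    matrix: np.ndarray
    band_hz: tuple[float, float]
    n_terms: int  # trials x tapers x frequencies averaged

    def __post_init__(self):
        m = np.asarray(self.matrix, complex)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("CSD must be square")
        if not np.allclose(m, m.conj().T, atol=1e-10 * max(abs(m).max(), 1.0)):
            raise ValueError("CSD must be Hermitian")
        if np.any(m.diagonal().real < -1e-12):
            raise ValueError("CSD diagonal must be non-negative")
        self.matrix = m


@dataclass
class DicsFilters:
    """Per-source unit-gain sensor weights, with the regularization used."""

    weights: np.ndarray  # (n_sources, n_sensors)
    lam: float


def sarvas_leadfield(
    dipole_pos: np.ndarray,
    moment: np.ndarray,
    sensor_pos: np.ndarray,
    sensor_ori: np.ndarray,
    sphere_center=(0.0, 0.0, 0.0),
    sphere_radius: float | None = None,
) -> np.ndarray:
    """Radial-sensor field of a current dipole in a conducting sphere.

    Returns the projection of the external magnetic field onto each sensor's
    orientation vector, linear in the dipole ``moment``. A dipole at the
    sphere center (or outside the sphere, when ``sphere_radius`` is given) is
    rejected: the forward solution is undefined/invalid there.
    """
    center = np.asarray(sphere_center, float)
    r0 = np.asarray(dipole_pos, float) - center
    q = np.asarray(moment, float)
    rs = np.asarray(sensor_pos, float) - center
    ori = np.asarray(sensor_ori, float)
    r0n = np.linalg.norm(r0)
    if r0n < 1e-12:
        raise ValueError("dipole at the sphere center: leadfield undefined")
    if sphere_radius is not None:
        if r0n >= sphere_radius:
            raise ValueError("dipole must lie strictly inside the sphere")
        if np.any(np.linalg.norm(rs, axis=1) <= sphere_radius):
            raise ValueError("sensors must lie outside the sphere")

    a_vec = rs - r0  # sensor - dipole
    a = np.linalg.norm(a_vec, axis=1)
    r = np.linalg.norm(rs, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("sensor coincides with the dipole")
    ar = np.einsum("ij,ij->i", a_vec, rs)
    F = a * (r * a + r**2 - rs @ r0)
    gradF = (
        (a**2 / r + ar / a + 2 * a + 2 * r)[:, None] * rs
        - (a + 2 * r + ar / a)[:, None] * r0[None, :]
    )
    qxr0 = np.cross(q, r0)
    B = MU0_OVER_4PI / F[:, None] ** 2 * (
        F[:, None] * qxr0[None, :] - (rs @ qxr0)[:, None] * gradF
    )
    return np.einsum("ij,ij->i", B, ori)


def build_source_grid(
    sphere_radius: float,
    spacing: float,
    sphere_center=(0.0, 0.0, 0.0),
    inner_exclusion: float | None = None,
) -> np.ndarray:
    """Regular grid of candidate dipole positions strictly inside the sphere.

    Points closer to the center than ``inner_exclusion`` (default: half a
    grid step) are dropped — the spherical forward solution degenerates there.
    """
    if inner_exclusion is None:
        inner_exclusion = spacing / 2.0
    ticks = np.arange(-sphere_radius, sphere_radius + spacing / 2, spacing)
    gx, gy, gz = np.meshgrid(ticks, ticks, ticks, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    rad = np.linalg.norm(pts, axis=1)
    pts = pts[(rad < sphere_radius - spacing / 4) & (rad > inner_exclusion)]
    return pts + np.asarray(sphere_center, float)


def compute_csd(
    epochs: SensorEpochs,
    band_hz: tuple[float, float],
    n_tapers: int = 2,
    trials: np.ndarray | None = None,
) -> CsdMatrix:
    """Cross-spectral density averaged over trials, tapers, and band bins."""
    if trials is None:
        trials = np.arange(epochs.n_trials)
    trials = np.asarray(trials, int)
    if trials.size == 0:
        raise ValueError("empty trial subset")
    x = epochs.epochs[trials]
    n = x.shape[-1]
    fs = epochs.fs_hz
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    sel = np.flatnonzero((freqs >= band_hz[0] - 1e-9) & (freqs <= band_hz[1] + 1e-9))
    if sel.size == 0:
        raise ValueError("no frequency bins inside the band")
    nw = (n_tapers + 1) / 2.0
    tapers = dpss_tapers(n, nw, n_tapers)
    tapered = x[:, :, None, :] * tapers[None, None, :, :]
    coef = np.fft.rfft(tapered, axis=-1)[..., sel]  # trial x sensor x taper x freq
    coef = np.moveaxis(coef, 1, -1)  # trial x taper x freq x sensor
    flat = coef.reshape(-1, coef.shape[-1])
    csd = (flat[:, :, None] * flat.conj()[:, None, :]).mean(axis=0)
    csd = 0.5 * (csd + csd.conj().T)  # kill rounding asymmetry
    return CsdMatrix(csd, tuple(band_hz), flat.shape[0])


def dics_filters(
    csd_all: CsdMatrix,
    source_model: SourceModel,
    lam: float = 0.05,
) -> DicsFilters:
    """Unit-gain spatial filters from the all-trials (common) CSD.

    The real part of the CSD is regularized with ``lam * trace / n_sensors``
    on the diagonal; each source's filter is
    ``w = (l' C^-1 l)^-1 l' C^-1`` so that ``w @ l == 1``.
    """
    C = csd_all.matrix.real.copy()
    n = C.shape[0]
    C_reg = C + lam * (np.trace(C) / n) * np.eye(n)
    try:
        C_inv = np.linalg.inv(C_reg)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"regularized CSD is singular (lam={lam}); increase lam"
        ) from err
    L = source_model.leadfields  # (n_sources, n_sensors)
    lc = L @ C_inv  # (n_sources, n_sensors)
    gain = np.einsum("sn,sn->s", lc, L)
    if np.any(np.abs(gain) < 1e-30):
        raise np.linalg.LinAlgError("degenerate leadfield: zero projected gain")
    W = lc / gain[:, None]
    return DicsFilters(weights=W, lam=lam)


def project_source_power(filters: DicsFilters, csd_condition: CsdMatrix) -> np.ndarray:
    """Per-source power Re(w C w^H) for one condition's CSD."""
    W = filters.weights
    C = csd_condition.matrix
    if W.shape[1] != C.shape[0]:
        raise ValueError("filter/CSD sensor dimensions do not match")
    power = np.einsum("sn,nm,sm->s", W, C, W.conj()).real
    return power
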