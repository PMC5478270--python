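"""Multiple-comparison machinery for voxel/sensor/source maps.

Two families:

* Monte-Carlo cluster-size thresholds for voxelwise paired t maps, using
  Gaussian random fields colored to a fitted Gaussian-plus-mono-exponential
  spatial autocorrelation model.
* Sign-flip permutation cluster-mass tests for paired sensor/source
  differences (exhaustive when feasible, sampled otherwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, sparse
from scipy import stats as sps
from scipy.sparse.csgraph import connected_components

__all__ = [
    "AcfModel",
    "AdjacencyGraph",
    "Cluster",
    "ClusterResult",
    "estimate_acf",
    "simulate_cluster_threshold",
    "extract_clusters",
    "permutation_cluster_test",
    "sensor_adjacency",
    "grid_adjacency",
    "cluster_overlap",
]


@dataclass(frozen=True)
class AcfModel:
    """Spatial autocorrelation model ACF(r) = a*exp(-r^2/(2 b^2)) + (1-a)*exp(-r/c).

    ``a`` is the Gaussian mixture weight, ``b`` the Gaussian width (mm) and
    ``c`` the exponential decay length (mm). ACF(0) = 1 by construction.
    """

    a: float
    b: float
    c: float

    def __post_init__(self):
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("mixture weight a must be in [0, 1]")
        if self.b < 0 or self.c < 0:
            raise ValueError("length scales must be non-negative")

    def __call__(self, r):
        r = np.asarray(r, float)
        gauss = np.exp(-(r**2) / (2.0 * self.b**2)) if self.b > 0 else (r == 0) * 1.0
        expo = np.exp(-r / self.c) if self.c > 0 else (r == 0) * 1.0
        out = self.a * gauss + (1.0 - self.a) * expo
        return float(out) if out.ndim == 0 else out


@dataclass
class AdjacencyGraph:
    """Symmetric, self-loop-free node adjacency with its geometric origin."""

    matrix: sparse.csr_matrix
    source: str = "unspecified"
    positions: np.ndarray | None = None

    def __post_init__(self):
        m = sparse.csr_matrix(self.matrix)
        if m.shape[0] != m.shape[1]:
            raise ValueError("adjacency must be square")
        if (m != m.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if m.diagonal().any():
            raise ValueError("self-edges are not allowed")
        self.matrix = m

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]


@dataclass
class Cluster:
    nodes: np.ndarray
    size: int
    mass: float
    sign: int
    peak_node: int
    p_corrected: float | None = None


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    forming_threshold: float
    null_max_mass: np.ndarray | None = None
    n_perm: int | None = None
    exhaustive: bool | None = None

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters
                if c.p_corrected is not None and c.p_corrected <= alpha]


# ---------------------------------------------------------------------------
# ACF estimation and Monte-Carlo cluster-size thresholds (fMRI arm)
# ---------------------------------------------------------------------------

def estimate_acf(
    residuals: np.ndarray,
    mask: np.ndarray,
    voxel_size_mm: float = 3.0,
    max_distance_mm: float | None = None,
    n_bins: int = 24,
) -> AcfModel:
    """Fit the mixed Gaussian/exponential ACF to residual spatial correlations.

    Parameters
    ----------
    residuals : (n_frames, nx, ny, nz)
        Residual volumes (after nuisance regression).
    mask : 3-D boolean volume.
    """
    residuals = np.asarray(residuals, float)
    mask = np.asarray(mask, bool)
    if residuals.ndim != 4 or residuals.shape[0] < 2:
        raise ValueError("need >= 2 residual frames shaped (frames, nx, ny, nz)")
    coords = np.argwhere(mask) * voxel_size_mm
    data = residuals[:, mask]  # frames x voxels
    data = data - data.mean(axis=0)
    norms = np.linalg.norm(data, axis=0)
    keep = norms > 0
    data = data[:, keep] / norms[keep]
    coords = coords[keep]
    corr = data.T @ data
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    iu = np.triu_indices(coords.shape[0], k=1)
    d, r = dist[iu], corr[iu]
    if max_distance_mm is None:
        max_distance_mm = min(d.max(), 10 * voxel_size_mm)
    sel = d <= max_distance_mm
    d, r = d[sel], r[sel]
    edges = np.linspace(0, max_distance_mm, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    centers, means, counts = [], [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() < 3:
            continue
        centers.append(d[m].mean())
        means.append(r[m].mean())
        counts.append(m.sum())
    centers = np.array(centers)
    means = np.array(means)
    counts = np.array(counts, float)

    def model(rr, a, b, c):
        return AcfModel(a, max(b, 1e-9), max(c, 1e-9))(rr)

    try:
        popt, _ = optimize.curve_fit(
            model, centers, means,
            p0=[0.5, voxel_size_mm, 2 * voxel_size_mm],
            bounds=([0.0, 1e-3, 1e-3], [1.0, 1e3, 1e3]),
            sigma=1.0 / np.sqrt(counts), maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"ACF fit failed to converge: {err}") from err
    return AcfModel(*popt)


@dataclass
class ClusterThreshold:
    min_cluster_size: int
    null_max_sizes: np.ndarray
    voxel_p: float
    alpha: float


def _spectral_amplitude(shape, acf: AcfModel, voxel_size_mm: float) -> np.ndarray:
    # circulant (wrap-around) distances give an exactly stationary field
    axes = [np.minimum(np.arange(n), n - np.arange(n)) for n in shape]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    dist = np.sqrt(gx**2 + gy**2 + gz**2) * voxel_size_mm
    kernel = acf(dist)
    spectrum = np.fft.fftn(kernel).real
    spectrum = np.clip(spectrum, 0.0, None)
    return np.sqrt(spectrum)


def simulate_cluster_threshold(
    mask: np.ndarray,
    acf: AcfModel,
    voxel_p: float = 0.005,
    n_iter: int = 1000,
    alpha: float = 0.05,
    voxel_size_mm: float = 3.0,
    rng: np.random.Generator | None = None,
) -> ClusterThreshold:
    """Monte-Carlo minimum cluster size under ACF-matched Gaussian noise.

    Per iteration a stationary Gaussian random field with the target ACF is
    synthesized spectrally on the bounding box, masked, thresholded two-sided
    at ``voxel_p``, and the largest face-connected cluster size recorded. The
    returned threshold is the ceil((1 - alpha) * n_iter)-th order statistic of
    those maxima.
    """
    mask = np.asarray(mask, bool)
    if mask.sum() < 2:
        raise ValueError("mask too small for cluster simulation")
    if n_iter < 1:
        raise ValueError("n_iter must be positive")
    rng = np.random.default_rng(rng)
    amp = _spectral_amplitude(mask.shape, acf, voxel_size_mm)
    zc = sps.norm.isf(voxel_p / 2.0)
    structure = ndimage.generate_binary_structure(3, 1)  # face connectivity
    maxima = np.empty(n_iter, int)
    for it in range(n_iter):
        white = rng.standard_normal(mask.shape)
        fld = np.fft.ifftn(np.fft.fftn(white) * amp).real
        vals = fld[mask]
        sd = vals.std()
        if sd == 0:
            maxima[it] = 0
            continue
        fld = (fld - vals.mean()) / sd
        biggest = 0
        for sup in (mask & (fld > zc), mask & (fld < -zc)):
            lab, n = ndimage.label(sup, structure=structure)
            if n:
                sizes = np.bincount(lab.ravel())[1:]
                biggest = max(biggest, int(sizes.max()))
        maxima[it] = biggest
    maxima.sort()
    idx = max(int(np.ceil((1.0 - alpha) * n_iter)), 1)
    return ClusterThreshold(int(maxima[idx - 1]), maxima, voxel_p, alpha)


# ---------------------------------------------------------------------------
# Graph clustering and sign-flip permutation tests (MEG arm + fMRI t maps)
# ---------------------------------------------------------------------------

def _components(adjacency: sparse.csr_matrix, node_mask: np.ndarray):
    """Connected components among the True nodes of ``node_mask``."""
    idx = np.flatnonzero(node_mask)
    if idx.size == 0:
        return []
    sub = adjacency[idx][:, idx]
    n_comp, labels = connected_components(sub, directed=False)
    return [idx[labels == k] for k in range(n_comp)]


def _clusters_from_stat(stat, threshold, adjacency) -> list[Cluster]:
    clusters = []
    for sign in (1, -1):
        sup = (sign * stat) > threshold
        for nodes in _components(adjacency, sup):
            mass = float(stat[nodes].sum())
            peak = int(nodes[np.argmax(sign * stat[nodes])])
            clusters.append(
                Cluster(nodes=np.sort(nodes), size=nodes.size, mass=mass,
                        sign=sign, peak_node=peak)
            )
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def extract_clusters(
    stat_map: np.ndarray,
    df: int,
    voxel_p: float,
    adjacency: AdjacencyGraph,
) -> ClusterResult:
    """Two-sided suprathreshold clusters of a t map on a node graph."""
    stat_map = np.asarray(stat_map, float)
    if df <= 0:
        raise ValueError("df must be positive")
    if stat_map.shape[0] != adjacency.n_nodes:
        raise ValueError("stat map does not align with the adjacency nodes")
    t_crit = sps.t.isf(voxel_p / 2.0, df)
    clusters = _clusters_from_stat(stat_map, t_crit, adjacency.matrix)
    return ClusterResult(clusters, forming_threshold=float(t_crit))


def _one_sample_t(diffs: np.ndarray) -> np.ndarray:
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def permutation_cluster_test(
    diffs: np.ndarray,
    adjacency: AdjacencyGraph,
    n_perm: int = 1000,
    node_p: float = 0.005,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> ClusterResult:
    """Paired-design cluster-mass test via per-subject sign flips.

    ``diffs`` is the subjects x nodes matrix of threat-minus-safe values.
    Observed clusters are formed at the two-sided ``node_p`` threshold; the
    null is the per-permutation maximum absolute cluster mass. All 2**n flips
    are enumerated when that is <= ``n_perm``, otherwise ``n_perm`` random
    flips are drawn (corrected p then uses the +1 correction).
    """
    diffs = np.asarray(diffs, float)
    if diffs.ndim != 2:
        raise ValueError("expected a subjects x nodes matrix")
    n_sub, n_nodes = diffs.shape
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    if n_nodes != adjacency.n_nodes:
        raise ValueError("node count does not match adjacency")
    rng = np.random.default_rng(rng)
    t_crit = float(sps.t.isf(node_p / 2.0, n_sub - 1))
    t_obs = _one_sample_t(diffs)
    clusters = _clusters_from_stat(t_obs, t_crit, adjacency.matrix)

    exhaustive = 2**n_sub <= n_perm
    if exhaustive:
        n_used = 2**n_sub
        bits = (np.arange(n_used)[:, None] >> np.arange(n_sub)) & 1
        signs = 1.0 - 2.0 * bits
    else:
        n_used = n_perm
        signs = rng.choice([-1.0, 1.0], size=(n_used, n_sub))

    ss = (diffs**2).sum(axis=0)  # invariant under sign flips
    means = signs @ diffs / n_sub
    var = (ss - n_sub * means**2) / (n_sub - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_perm = means / np.sqrt(var / n_sub)
    t_perm = np.where(var > 0, t_perm, 0.0)

    null = np.zeros(n_used)
    adj = adjacency.matrix
    for p in range(n_used):
        row = t_perm[p]
        best = 0.0
        for sign in (1, -1):
            for nodes in _components(adj, (sign * row) > t_crit):
                best = max(best, abs(float(row[nodes].sum())))
        null[p] = best

    for c in clusters:
        b = int((null >= abs(c.mass)).sum())
        c.p_corrected = b / n_used if exhaustive else (b + 1) / (n_used + 1)
    return ClusterResult(
        clusters, forming_threshold=t_crit, null_max_mass=null,
        n_perm=n_used, exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# Adjacency builders and overlap counting
# ---------------------------------------------------------------------------

def sensor_adjacency(positions: np.ndarray, radius: float = 0.04) -> AdjacencyGraph:
    """Edges between sensors within ``radius`` (same units as positions)."""
    pos = np.asarray(positions, float)
    if pos.ndim != 2 or pos.shape[0] < 2:
        raise ValueError("need >= 2 sensor positions")
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    off = d + np.eye(pos.shape[0]) * (d.max() + 1.0)
    if off.min() == 0:
        raise ValueError("duplicate sensor positions")
    mat = sparse.csr_matrix((d <= radius) & ~np.eye(pos.shape[0], dtype=bool))
    graph = AdjacencyGraph(mat, source="sensor distance", positions=pos)
    n_comp, _ = connected_components(mat, directed=False)
    if n_comp > 1:
        warnings.warn(f"sensor adjacency graph has {n_comp} disconnected parts")
    return graph


def grid_adjacency(mask: np.ndarray) -> AdjacencyGraph:
    """Face (6-neighbour) adjacency among in-mask voxels, C-order node ids."""
    mask = np.asarray(mask, bool)
    coords = np.argwhere(mask)
    index = -np.ones(mask.shape, int)
    index[mask] = np.arange(coords.shape[0])
    rows, cols = [], []
    for axis in range(3):
        shift = np.zeros(3, int)
        shift[axis] = 1
        nb = coords + shift
        ok = (nb[:, axis] < mask.shape[axis])
        nb = nb[ok]
        src = coords[ok]
        in_mask = mask[tuple(nb.T)]
        a = index[tuple(src[in_mask].T)]
        b = index[tuple(nb[in_mask].T)]
        rows.extend([a, b])
        cols.extend([b, a])
    n = coords.shape[0]
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        mat = sparse.csr_matrix(
            (np.ones(rows.size, bool), (rows, cols)), shape=(n, n)
        )
    else:
        mat = sparse.csr_matrix((n, n), dtype=bool)
    return AdjacencyGraph(mat, source="voxel faces", positions=coords)


def cluster_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> tuple[int, int, int]:
    """(intersection, |a|, |b|) voxel counts of two same-grid boolean masks."""
    a = np.asarray(mask_a, bool)
    b = np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError("masks are on different grids")
    return int((a & b).sum()), int(a.sum()), int(b.sum())
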