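"""Phenotype landscape: UMAP embedding, graph clustering, dose trajectories.

The 25-PC organoid profiles are embedded with UMAP (min_dist 0.1, 15
neighbours) and clustered with the Leiden algorithm on a symmetrised
k-nearest-neighbour graph (resolution 1e-7 at full screen scale).  For a
drug screened across doses, a principal curve fitted through the (optionally
cluster-filtered, downsampled) embedding yields a per-organoid arc-length
position -- a morphological pseudotime that is monotone in dose for drugs
with a monotone effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
from scipy.interpolate import UnivariateSpline
from sklearn.neighbors import NearestNeighbors


@dataclass
class EmbeddingResult:
    coordinates: np.ndarray  # rows x 2
    params: dict = field(default_factory=dict)
    cluster_labels: np.ndarray | None = None  # 1..K per row


@dataclass
class DoseTrajectory:
    curve: np.ndarray  # ordered points in embedding space
    pseudotime: np.ndarray  # per input row; NaN for excluded rows
    excluded_clusters: frozenset = frozenset()
    objective_trace: list = field(default_factory=list)


def embed_umap(
    scores, min_dist: float = 0.1, n_neighbors: int = 15, seed: int = 0
) -> EmbeddingResult:
    """2D UMAP of PC scores; deterministic under a fixed seed."""
    import umap  # deferred: numba compilation is slow at import

    x = np.asarray(scores, dtype=float)
    if x.shape[0] < n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 rows")
    reducer = umap.UMAP(
        n_components=2, min_dist=min_dist, n_neighbors=n_neighbors, random_state=seed
    )
    coords = reducer.fit_transform(x)
    return EmbeddingResult(
        np.asarray(coords, dtype=float),
        {"min_dist": min_dist, "n_neighbors": n_neighbors, "seed": seed},
    )


def cluster_graph(
    x, resolution: float = 1e-7, n_neighbors: int = 15, seed: int = 0
) -> np.ndarray:
    """Leiden community detection on a symmetrised kNN graph; labels 1..K.

    Accepts either PC scores or embedding coordinates.  At very small
    resolutions only graph components survive as clusters, so well-separated
    groups remain distinct while diffuse data collapses to few communities.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < 2:
        return np.ones(n, dtype=int)
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(x)
    adj = nn.kneighbors_graph(mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = {(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j}
    graph = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership, dtype=int) + 1


def fit_dose_trajectory(
    embedding: EmbeddingResult,
    doses,
    baseline=None,
    exclude_clusters=frozenset(),
    downsample_frac: float = 0.05,
    downsample_min: int = 200,
    downsample_cap: int = 10_000,
    seed: int = 0,
    max_iter: int = 30,
    tol: float = 1e-4,
    n_curve_points: int = 100,
    spline_smooth: float = 1.0,
) -> DoseTrajectory:
    """Fit a principal curve through the embedding and assign pseudotime.

    ``doses`` gives one dose per row (NaN/0 for controls); ``baseline`` is an
    optional boolean mask of control (DMSO) rows used to orient the curve:
    pseudotime 0 sits at the curve end where baseline density is highest.
    Rows in ``exclude_clusters`` (per the embedding's cluster labels) are
    ignored during fitting and carry no pseudotime.  The curve is fitted by
    projection-expectation iterations on a seeded uniform downsample
    (``downsample_frac`` of points, capped), smoothing each coordinate
    against arc length with a cubic smoothing spline; iterations stop when
    the mean squared projection distance stops improving by ``tol`` of the
    squared embedding diameter.
    """
    coords = np.asarray(embedding.coordinates, dtype=float)
    doses = np.asarray(doses, dtype=float)
    n = coords.shape[0]
    excluded = np.zeros(n, dtype=bool)
    exclude_clusters = frozenset(exclude_clusters)
    if exclude_clusters and embedding.cluster_labels is not None:
        excluded = np.isin(embedding.cluster_labels, sorted(exclude_clusters))
    active = ~excluded
    if not active.any():
        raise ValueError("all points excluded from trajectory fitting")
    if np.unique(doses[active & np.isfinite(doses)]).size < 2:
        raise ValueError("need at least two dose levels")

    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(active)
    m = min(len(idx), max(downsample_min, int(downsample_frac * len(idx))), downsample_cap)
    fit_idx = rng.choice(idx, size=m, replace=False) if m < len(idx) else idx
    pts = coords[fit_idx]

    diam2 = float(np.sum(np.ptp(pts, axis=0) ** 2)) or 1.0
    curve = _initial_curve(pts, n_curve_points)
    trace: list[float] = []
    for _ in range(max_iter):
        arc, dist2, _ = _project_to_polyline(pts, curve)
        obj = float(dist2.mean())
        if trace and obj > trace[-1] - tol * diam2:
            trace.append(min(obj, trace[-1]))
            break
        trace.append(obj)
        curve = _smooth_curve(arc, pts, n_curve_points, spline_smooth)

    pseudo = np.full(n, np.nan)
    arc_all, _, _ = _project_to_polyline(coords[active], curve)
    pseudo[active] = arc_all

    total = float(np.nanmax(pseudo)) or 1.0
    if baseline is not None:
        base = np.asarray(baseline, dtype=bool) & active
    else:
        finite = np.isfinite(doses)
        base = active & finite & (doses == np.nanmin(doses[active & finite]))
    # orient so the baseline-dense end carries pseudotime 0: flip whenever the
    # baseline sits above the bulk of the data along the curve
    if base.any() and np.nanmedian(pseudo[base]) > np.nanmedian(pseudo[active]):
        pseudo[active] = total - pseudo[active]
        curve = curve[::-1]

    return DoseTrajectory(curve, pseudo, exclude_clusters, trace)


def _initial_curve(pts: np.ndarray, n_points: int) -> np.ndarray:
    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    s = (pts - center) @ vt[0]
    ts = np.linspace(s.min(), s.max(), n_points)
    return center + ts[:, None] * vt[0]


def _project_to_polyline(pts: np.ndarray, curve: np.ndarray):
    """Arc-length position, squared distance and foot point per input point."""
    seg_start = curve[:-1]
    seg_vec = np.diff(curve, axis=0)
    seg_len2 = np.maximum((seg_vec**2).sum(axis=1), 1e-300)
    seg_len = np.sqrt(seg_len2)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    arcs = np.empty(len(pts))
    d2 = np.empty(len(pts))
    feet = np.empty_like(pts)
    chunk = 20_000
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk]
        diff = p[:, None, :] - seg_start[None, :, :]
        t = np.clip((diff * seg_vec[None]).sum(-1) / seg_len2[None], 0.0, 1.0)
        proj = seg_start[None] + t[..., None] * seg_vec[None]
        dist2 = ((p[:, None, :] - proj) ** 2).sum(-1)
        j = np.argmin(dist2, axis=1)
        rows = np.arange(len(p))
        arcs[lo : lo + chunk] = cum[j] + t[rows, j] * seg_len[j]
        d2[lo : lo + chunk] = dist2[rows, j]
        feet[lo : lo + chunk] = proj[rows, j]
    return arcs, d2, feet


def _smooth_curve(arc, pts, n_points: int, smooth: float) -> np.ndarray:
    order = np.argsort(arc, kind="stable")
    s_sorted = arc[order]
    uniq, inverse = np.unique(np.round(s_sorted, 9), return_inverse=True)
    new = np.empty((n_points, pts.shape[1]))
    s_new = np.linspace(uniq[0], uniq[-1], n_points)
    for dim in range(pts.shape[1]):
        y = np.bincount(inverse, weights=pts[order, dim]) / np.bincount(inverse)
        if uniq.size >= 4:
            # noise level from first differences: for a smooth signal sampled
            # densely, Var(y_{i+1} - y_i) ~ 2 sigma^2
            sigma2 = float(np.mean(np.diff(y) ** 2) / 2.0)
            spl = UnivariateSpline(uniq, y, k=3, s=smooth * uniq.size * sigma2)
            new[:, dim] = spl(s_new)
        else:
            new[:, dim] = np.interp(s_new, uniq, y)
    return new
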