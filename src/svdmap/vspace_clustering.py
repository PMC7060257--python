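"""Clustering map points in amplitude (V) space.

Each map point is embedded with its values on the significant amplitude
vectors (V_1 ... V_{n_e}) as coordinates in an n_e-dimensional space; the
amplitude values are used unscaled (not multiplied by the singular weights),
so every retained direction contributes on equal footing and a minor
component is not crushed by the dominant one.  Out-of-range points (e.g.
cosmic-ray-like spikes) are flagged by a per-coordinate robust rule
(median +/- c * MAD) before clustering.  Clustering is plain k-means with
Euclidean distance; cluster labels are canonicalized by decreasing cluster
size so runs are comparable.

Per-cluster spectra are arithmetic means of the member spectra, either of
the original spectra (default) or of the rank-n_e noise-filtered
reconstruction.  A cluster spectrum is a convex combination of member
spectra and therefore in general a *mixture* of the underlying component
spectra — it equals a pure component only when that component is spatially
distinct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.cluster import KMeans

from .spectral_model import HyperMap
from .svd_engine import SVDResult, reconstruct

__all__ = [
    "PointSet",
    "ClusterResult",
    "OutlierCapError",
    "embed_points",
    "remove_outliers",
    "kmeans_cluster",
    "cluster_spectra",
]


class OutlierCapError(RuntimeError):
    """Raised when the outlier rule would discard more than the safety cap."""


@dataclass(eq=False)
class PointSet:
    """Map points embedded in n_e-dimensional amplitude space."""

    coordinates: np.ndarray  # (n_points, n_e)
    spatial_coords: np.ndarray  # (n_points, 2)
    excluded: np.ndarray  # (n_points,) bool

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.spatial_coords = np.asarray(self.spatial_coords, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] < 1:
            raise ValueError("coordinates must be (n_points, n_e) with n_e >= 1")
        n = self.coordinates.shape[0]
        if self.spatial_coords.shape != (n, 2) or self.excluded.shape != (n,):
            raise ValueError("inconsistent point counts")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("embedding coordinates must be finite")

    @property
    def n_points(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_e(self) -> int:
        return self.coordinates.shape[1]

    @property
    def active(self) -> np.ndarray:
        return ~self.excluded


@dataclass(eq=False)
class ClusterResult:
    """k-means partition of the embedded points.

    ``labels`` has one entry per map point: 1..k for clustered points, 0 for
    excluded ones.  ``centers`` are in amplitude space.  ``cluster_spectra``
    is filled by :func:`cluster_spectra` (k x n_channels).
    """

    labels: np.ndarray
    k: int
    centers: np.ndarray
    inertia: float
    seed: int
    spatial_coords: np.ndarray
    cluster_spectra: np.ndarray | None = None
    spectra_mode: str | None = None
    empty_clusters: tuple[int, ...] = ()

    def members(self, cluster: int) -> np.ndarray:
        """Boolean member mask (over all map points) of 1-based ``cluster``."""
        if not (1 <= cluster <= self.k):
            raise ValueError(f"cluster {cluster} out of range 1..{self.k}")
        return self.labels == cluster


def embed_points(result: SVDResult, n_e: int) -> PointSet:
    """Use V_1 ... V_{n_e} as per-point coordinates (unscaled)."""
    if not (1 <= n_e <= result.rank):
        raise ValueError(f"n_e {n_e} out of range 1..{result.rank}")
    return PointSet(
        coordinates=result.amplitudes[:n_e].T.copy(),
        spatial_coords=result.coords.copy(),
        excluded=np.zeros(result.n_points, dtype=bool),
    )


def remove_outliers(points: PointSet, c: float = 10.0, max_fraction: float = 0.10) -> PointSet:
    """Flag out-of-range points coordinate-wise by median +/- c * MAD.

    A point is excluded when in ANY embedding coordinate its distance from
    that coordinate's median exceeds ``c`` times the median absolute
    deviation.  Coordinates with MAD = 0 are skipped.  If more than
    ``max_fraction`` of the points would be flagged the rule is assumed
    misconfigured and an :class:`OutlierCapError` is raised instead of
    silently discarding data.
    """
    if not (c > 0):
        raise ValueError("c must be positive")
    X = points.coordinates
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    flag = np.zeros(points.n_points, dtype=bool)
    for j in range(points.n_e):
        if mad[j] == 0:
            continue
        flag |= np.abs(X[:, j] - med[j]) > c * mad[j]
    if flag.sum() > max_fraction * points.n_points:
        raise OutlierCapError(
            f"outlier rule would remove {int(flag.sum())} of {points.n_points} points "
            f"(> {max_fraction:.0%} cap); inspect the data or raise c"
        )
    return replace(points, excluded=points.excluded | flag)


def _canonical_relabel(labels0: np.ndarray, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Renumber clusters 1..k by decreasing size, ties by decreasing center norm."""
    k = centers.shape[0]
    sizes = np.bincount(labels0, minlength=k)
    norms = np.linalg.norm(centers, axis=1)
    order = sorted(range(k), key=lambda c: (-sizes[c], -norms[c]))
    remap = np.empty(k, dtype=int)
    for new, old in enumerate(order):
        remap[old] = new + 1
    return remap[labels0], centers[order]


def kmeans_cluster(
    points: PointSet, k: int, seed: int | None = None, n_init: int = 10
) -> ClusterResult:
    """k-means (Euclidean, Lloyd iterations, k-means++ seeding) on the
    active points, best of ``n_init`` restarts by inertia.

    Deterministic given ``seed``.  Labels are canonicalized by decreasing
    cluster size (ties by center norm); excluded points get label 0.
    """
    if seed is None:
        raise ValueError("kmeans_cluster requires an explicit seed")
    active = points.active
    n_active = int(active.sum())
    if not (1 <= k <= n_active):
        raise ValueError(f"k={k} out of range 1..{n_active} (non-excluded points)")
    X = points.coordinates[active]
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=n_init, algorithm="lloyd",
        random_state=seed % (2**32),
    ).fit(X)
    labels1, centers = _canonical_relabel(km.labels_, km.cluster_centers_)
    labels = np.zeros(points.n_points, dtype=int)
    labels[active] = labels1
    return ClusterResult(
        labels=labels,
        k=k,
        centers=centers,
        inertia=float(km.inertia_),
        seed=seed,
        spatial_coords=points.spatial_coords.copy(),
    )


def cluster_spectra(
    hmap: HyperMap,
    result: ClusterResult,
    mode: str = "original",
    svd: SVDResult | None = None,
    n_e: int | None = None,
) -> np.ndarray:
    """Average spectrum of each cluster (k x n_channels).

    ``mode='original'`` (default) averages the original member spectra;
    ``mode='reconstructed'`` averages the rank-n_e noise-filtered
    reconstruction instead (requires ``svd`` and ``n_e``).  An empty cluster
    yields a zero spectrum and a warning; its index is recorded in
    ``result.empty_clusters``.
    """
    if mode not in ("original", "reconstructed"):
        raise ValueError(f"mode must be original or reconstructed, got {mode!r}")
    if result.labels.shape[0] != hmap.n_points:
        raise ValueError("cluster labels do not align with map points")
    if mode == "reconstructed":
        if svd is None or n_e is None:
            raise ValueError("reconstructed mode requires svd result and n_e")
        source = reconstruct(svd, n_e).T  # back to points x channels
    else:
        source = hmap.spectra
    out = np.zeros((result.k, hmap.n_channels))
    empty = []
    for c in range(1, result.k + 1):
        sel = result.members(c)
        if not sel.any():
            empty.append(c)
            warnings.warn(f"cluster {c} is empty; zero spectrum emitted", stacklevel=2)
            continue
        out[c - 1] = source[sel].mean(axis=0)
    result.cluster_spectra = out
    result.spectra_mode = mode
    result.empty_clusters = tuple(empty)
    return out
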