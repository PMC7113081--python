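"""Data-driven fiber clustering and atlas-based tract identification.

Streamlines are resampled to a fixed number of arc-length-uniform points,
compared by pairwise fiber distances (symmetric mean-closest-point or
flip-invariant mean-direct-flip), spectrally embedded via a Gaussian
affinity, and partitioned by k-means.  Identification assigns each fiber
to the nearest centroid of a cluster atlas (JSON header + centroid
tractogram) by MDF distance, with a rejection radius.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .core import Tractogram
from .io import read_tractogram, write_tractogram

__all__ = [
    "resample_streamline",
    "fiber_distance",
    "pairwise_distance_matrix",
    "spectral_embed",
    "cluster_fibers",
    "ClusterAtlas",
    "assign_to_atlas",
    "build_atlas_from_labels",
]

DEFAULT_K_RESAMPLE = 15
DEFAULT_SIGMA_MM = 30.0
DEFAULT_EMBED_DIMS = 10


def resample_streamline(s: np.ndarray, k: int) -> np.ndarray:
    """Resample a polyline to k points at equal arc-length fractions.

    Endpoints are preserved exactly.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    s = np.asarray(s, float).reshape(-1, 3)
    seg = np.linalg.norm(np.diff(s, axis=0), axis=1)
    total = seg.sum()
    if total <= 0:
        raise ValueError("degenerate streamline")
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, total, k)
    out = np.empty((k, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, arc, s[:, d])
    out[0] = s[0]
    out[-1] = s[-1]
    return out


def fiber_distance(a: np.ndarray, b: np.ndarray, metric: str = "mdf") -> float:
    """Distance (mm) between two equal-k resampled fibers.

    ``mdf``: min over point order flip of the mean corresponding-point
    distance (orientation invariant).  ``mean_closest_point_sym``:
    symmetrized mean closest-point distance.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("feature size mismatch")
    if metric == "mdf":
        direct = np.linalg.norm(a - b, axis=1).mean()
        flipped = np.linalg.norm(a - b[::-1], axis=1).mean()
        return float(min(direct, flipped))
    if metric == "mean_closest_point_sym":
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
        return float(0.5 * (d.min(axis=1).mean() + d.min(axis=0).mean()))
    raise ValueError(f"unknown metric {metric!r}")


def pairwise_distance_matrix(
    features: list[np.ndarray] | np.ndarray, metric: str = "mdf"
) -> np.ndarray:
    """Symmetric zero-diagonal fiber distance matrix."""
    F = np.asarray(features, float)
    if F.ndim != 3:
        raise ValueError("expected (n_fibers, k, 3) features")
    n = len(F)
    if metric == "mdf":
        # vectorized: direct and flipped mean corresponding-point distances
        direct = np.linalg.norm(F[:, None, :, :] - F[None, :, :, :], axis=3).mean(axis=2)
        flip = np.linalg.norm(F[:, None, :, :] - F[None, :, ::-1, :], axis=3).mean(axis=2)
        M = np.minimum(direct, flip)
    else:
        M = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                M[i, j] = M[j, i] = fiber_distance(F[i], F[j], metric)
    np.fill_diagonal(M, 0.0)
    return 0.5 * (M + M.T)


def spectral_embed(M: np.ndarray, sigma_mm: float = DEFAULT_SIGMA_MM,
                   dims: int = DEFAULT_EMBED_DIMS) -> np.ndarray:
    """Normalized spectral embedding of a fiber distance matrix.

    Affinity A = exp(-M^2 / sigma^2); rows of the top-``dims``
    eigenvectors of D^{-1/2} A D^{-1/2}, row-normalized to unit norm.
    Eigenvector signs are fixed (largest-magnitude component positive) so
    repeated runs are bit-identical.
    """
    if sigma_mm <= 0:
        raise ValueError("bad bandwidth")
    M = np.asarray(M, float)
    n = len(M)
    dims = min(dims, n)
    A = np.exp(-(M**2) / sigma_mm**2)
    d = A.sum(axis=1)
    Dh = 1.0 / np.sqrt(np.maximum(d, 1e-300))
    L = A * Dh[:, None] * Dh[None, :]
    w, V = np.linalg.eigh(0.5 * (L + L.T))
    V = V[:, ::-1][:, :dims]  # top eigenvectors, descending eigenvalue
    # deterministic sign: make the largest-magnitude component positive
    for k in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, k]))
        if V[i, k] < 0:
            V[:, k] = -V[:, k]
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    return V / np.maximum(norms, 1e-300)


def cluster_fibers(embedding: np.ndarray, n_clusters: int, rng_seed: int = 0) -> np.ndarray:
    """k-means partition of the embedded fibers, reproducible from seed."""
    if n_clusters < 1:
        raise ValueError("bad k")
    embedding = np.asarray(embedding, float)
    if n_clusters > len(embedding):
        raise ValueError("n_clusters exceeds number of fibers")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=int(rng_seed))
    return km.fit_predict(embedding)


@dataclass
class ClusterAtlas:
    """Labeled cluster centroids for tract identification.

    On disk: a JSON header carrying ``k_resample``, ``sigma_mm`` and the
    ordered labels, next to a centroid tractogram (one streamline per
    label, same order).
    """

    k_resample: int = DEFAULT_K_RESAMPLE
    sigma_mm: float = DEFAULT_SIGMA_MM
    centroids: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [lab for lab, _ in self.centroids]
        if len(set(labels)) != len(labels):
            raise ValueError("centroid labels must be unique")
        cents = []
        for lab, c in self.centroids:
            c = np.asarray(c, float).reshape(-1, 3)
            if len(c) != self.k_resample:
                raise ValueError("centroid point count must equal k_resample")
            cents.append((str(lab), c))
        self.centroids = cents

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        trk = path.with_suffix(".trk")
        write_tractogram(
            Tractogram(streamlines=[c for _, c in self.centroids]), trk, dialect="trk"
        )
        header = {
            "k_resample": self.k_resample,
            "sigma_mm": self.sigma_mm,
            "labels": [lab for lab, _ in self.centroids],
            "centroid_file": trk.name,
        }
        path.write_text(json.dumps(header, indent=2))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ClusterAtlas":
        path = Path(path)
        header = json.loads(path.read_text())
        trk = path.parent / header["centroid_file"]
        t = read_tractogram(trk, dialect="trk")
        if len(t) != len(header["labels"]):
            raise ValueError("atlas centroid count does not match label count")
        return cls(
            k_resample=int(header["k_resample"]),
            sigma_mm=float(header["sigma_mm"]),
            centroids=list(zip(header["labels"], t.streamlines)),
        )


def build_atlas_from_labels(
    t: Tractogram, labels: np.ndarray, k_resample: int = DEFAULT_K_RESAMPLE,
    label_names: dict[int, str] | None = None,
) -> ClusterAtlas:
    """Build an atlas whose centroids are the per-cluster mean fibers.

    Fibers are resampled to ``k_resample`` points and flip-aligned to the
    first fiber of their cluster before averaging.
    """
    labels = np.asarray(labels)
    centroids = []
    for lab in np.unique(labels):
        feats = [resample_streamline(s, k_resample)
                 for s, l in zip(t.streamlines, labels) if l == lab]
        ref = feats[0]
        aligned = []
        for f in feats:
            if np.linalg.norm(f - ref, axis=1).mean() > np.linalg.norm(f[::-1] - ref, axis=1).mean():
                f = f[::-1]
            aligned.append(f)
        name = label_names.get(int(lab), f"cluster_{lab}") if label_names else f"cluster_{lab}"
        centroids.append((name, np.mean(aligned, axis=0)))
    return ClusterAtlas(k_resample=k_resample, centroids=centroids)


def assign_to_atlas(
    t: Tractogram, atlas: ClusterAtlas, reject_distance_mm: float
) -> tuple[list[str], np.ndarray, dict[str, Tractogram]]:
    """Label every fiber with its nearest atlas centroid by MDF distance.

    Fibers farther than ``reject_distance_mm`` from every centroid get
    the label ``"unassigned"``.  Returns (labels, distances,
    per-label sub-tractograms of the assigned fibers).
    """
    if not atlas.centroids:
        raise ValueError("empty atlas")
    cents = np.stack([c for _, c in atlas.centroids])
    names = [lab for lab, _ in atlas.centroids]
    labels: list[str] = []
    dists = np.empty(len(t))
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(t.streamlines):
        f = resample_streamline(s, atlas.k_resample)
        d = np.minimum(
            np.linalg.norm(cents - f[None], axis=2).mean(axis=1),
            np.linalg.norm(cents - f[None, ::-1], axis=2).mean(axis=1),
        )
        j = int(np.argmin(d))
        dists[i] = d[j]
        if d[j] > reject_distance_mm:
            labels.append("unassigned")
        else:
            labels.append(names[j])
            groups.setdefault(names[j], []).append(i)
    subs = {
        name: Tractogram(
            streamlines=[t.streamlines[i] for i in idxs],
            reference_affine=t.reference_affine,
        )
        for name, idxs in groups.items()
    }
    return labels, dists, subs
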