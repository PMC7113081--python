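"""Deterministic single-tensor streamline tractography.

Streamlines follow the principal eigenvector of the trilinearly
interpolated tensor field with fixed-step Euler integration, launched
bidirectionally from each seed.  The *tensor* (not the eigenvector) is
interpolated and decomposed at the interpolated point, which sidesteps
eigenvector sign-discontinuity artifacts.  Stopping rules: FA below
threshold, per-step turning angle above threshold, leaving the mask or
grid, or reaching the length cap (each half-track is capped at half the
maximum so joined streamlines respect it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    FiducialList,
    LabelMap,
    TensorVolume,
    Tractogram,
    trilinear,
    voxel_to_world,
)
from .tensor import fa_from_eigenvalues

__all__ = [
    "TrackingParams",
    "seeds_from_labelmap",
    "seeds_from_fiducials",
    "track_single_tensor",
]


@dataclass
class TrackingParams:
    """Streamline integration and seeding parameters.

    Defaults are conventional clinical-research values, not claimed
    optimal for any particular dataset.
    """

    step_mm: float = 0.5
    fa_stop: float = 0.15
    angle_stop_deg: float = 45.0
    min_length_mm: float = 10.0
    max_length_mm: float = 250.0
    seeds_per_voxel: int = 1
    seed_jitter: str = "center"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.step_mm <= 0:
            raise ValueError("step_mm must be > 0")
        if not (0 <= self.fa_stop < 1):
            raise ValueError("fa_stop must be in [0, 1)")
        if not (0 < self.angle_stop_deg <= 90):
            raise ValueError("angle_stop_deg must be in (0, 90]")
        if self.min_length_mm >= self.max_length_mm:
            raise ValueError("min_length_mm must be < max_length_mm")
        if self.seed_jitter not in ("center", "random"):
            raise ValueError(f"unknown seed_jitter {self.seed_jitter!r}")


def seeds_from_labelmap(roi: LabelMap, label: int, p: TrackingParams) -> np.ndarray:
    """World-mm seed points for every voxel carrying ``label``.

    ``center`` jitter replicates voxel centers; ``random`` draws uniform
    positions within each voxel, reproducibly from ``rng_seed``.
    """
    idx = np.argwhere(roi.data == label)
    if len(idx) == 0:
        raise ValueError("empty ROI")
    idx = np.repeat(idx, p.seeds_per_voxel, axis=0).astype(float)
    if p.seed_jitter == "random":
        rng = np.random.default_rng(p.rng_seed)
        idx = idx + rng.uniform(-0.5, 0.5, size=idx.shape)
    return voxel_to_world(roi.affine, idx)


def seeds_from_fiducials(
    f: FiducialList, radius_mm: float, n_per_fiducial: int, rng_seed: int = 0
) -> np.ndarray:
    """Uniform seed points in a sphere around each fiducial.

    Radius 0 returns each fiducial position itself, once.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    if len(f) == 0:
        return np.zeros((0, 3))
    if radius_mm == 0:
        return f.positions.copy()
    rng = np.random.default_rng(rng_seed)
    seeds = []
    for _, pos in f.points:
        # rejection sampling from the cube is exactly uniform in the ball
        got = 0
        while got < n_per_fiducial:
            cand = rng.uniform(-1, 1, size=(2 * n_per_fiducial, 3))
            cand = cand[np.linalg.norm(cand, axis=1) <= 1.0]
            take = cand[: n_per_fiducial - got]
            seeds.append(pos + radius_mm * take)
            got += len(take)
    return np.concatenate(seeds)


def _principal_direction(t6: np.ndarray) -> tuple[np.ndarray, float]:
    """Principal eigenvector and FA of one 6-component tensor."""
    D = np.array(
        [
            [t6[0], t6[1], t6[2]],
            [t6[1], t6[3], t6[4]],
            [t6[2], t6[4], t6[5]],
        ]
    )
    w, V = np.linalg.eigh(D)  # ascending; principal is last
    fa = float(fa_from_eigenvalues(np.clip(w, 0.0, None)))
    return V[:, 2], fa


class _Field:
    """Caches the world->voxel map for repeated point interpolation."""

    def __init__(self, tv: TensorVolume):
        self.tensors = tv.tensors
        self.maskf = tv.mask.astype(np.float64)
        self.shape3 = np.asarray(tv.shape3, dtype=float)
        inv = np.linalg.inv(tv.affine)
        self._R = inv[:3, :3]
        self._t = inv[:3, 3]

    def to_index(self, x_world: np.ndarray) -> np.ndarray:
        return self._R @ x_world + self._t

    def in_grid(self, idx: np.ndarray) -> bool:
        return bool(np.all(idx >= 0) and np.all(idx <= self.shape3 - 1))

    def in_mask(self, idx: np.ndarray) -> bool:
        return trilinear(self.maskf, idx) >= 0.5

    def tensor_at(self, idx: np.ndarray) -> np.ndarray:
        return trilinear(self.tensors, idx)


def _track_half(
    field: _Field, seed: np.ndarray, d0: np.ndarray, p: TrackingParams
) -> list[np.ndarray]:
    """One half-track in world mm, excluding the seed point itself."""
    pts: list[np.ndarray] = []
    x = seed.copy()
    d = d0 / np.linalg.norm(d0)
    cos_stop = np.cos(np.deg2rad(p.angle_stop_deg))
    max_half = p.max_length_mm / 2.0
    length = 0.0
    while length + p.step_mm <= max_half:
        x_new = x + d * p.step_mm
        idx = field.to_index(x_new)
        if not field.in_grid(idx) or not field.in_mask(idx):
            break
        e1, fa = _principal_direction(field.tensor_at(idx))
        if fa < p.fa_stop:
            break
        if np.dot(e1, d) < 0:
            e1 = -e1
        e1 = e1 / np.linalg.norm(e1)
        if float(np.dot(e1, d)) < cos_stop:
            break
        pts.append(x_new)
        x = x_new
        d = e1
        length += p.step_mm
    return pts


def track_single_tensor(
    tv: TensorVolume, seeds: np.ndarray, p: TrackingParams | None = None
) -> Tractogram:
    """Bidirectional principal-direction streamlining from world-mm seeds.

    Seeds outside the mask are skipped, not fatal; the skip count is
    attached to the result as ``n_skipped_seeds``.  Streamlines shorter
    than ``min_length_mm`` are discarded.
    """
    if p is None:
        p = TrackingParams()
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    field = _Field(tv)

    streamlines: list[np.ndarray] = []
    n_skipped = 0
    for seed in seeds:
        idx = field.to_index(seed)
        if not field.in_grid(idx) or not field.in_mask(idx):
            n_skipped += 1
            continue
        e1, fa = _principal_direction(field.tensor_at(idx))
        if fa < p.fa_stop:
            continue
        fwd = _track_half(field, seed, e1, p)
        bwd = _track_half(field, seed, -e1, p)
        pts = bwd[::-1] + [seed] + fwd
        if len(pts) < 2:
            continue
        arr = np.asarray(pts)
        if np.linalg.norm(np.diff(arr, axis=0), axis=1).sum() < p.min_length_mm:
            continue
        streamlines.append(arr)

    t = Tractogram(streamlines=streamlines, reference_affine=tv.affine)
    t.n_skipped_seeds = n_skipped  # type: ignore[attr-defined]
    return t
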