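"""Core in-memory containers shared by every pipeline stage.

All spatial quantities live in a single canonical frame: RAS world
coordinates in millimeters.  Voxel indexing is 0-based and voxel *centers*
map through the 4x4 affine (index (0,0,0) lands on the affine's translation
column).  Gradient directions are stored in the world frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GradientTable",
    "DWIVolume",
    "LabelMap",
    "FiducialList",
    "Tractogram",
    "ScalarVolume",
    "TensorVolume",
    "world_to_voxel",
    "voxel_to_world",
    "trilinear",
]

_UNIT_TOL = 1e-6


@dataclass
class GradientTable:
    """Diffusion encoding: b-values (s/mm^2) and unit direction vectors.

    Zero-norm directions are legal only for b=0 (baseline) volumes.
    ``frame`` records whether directions are expressed in the image or the
    world frame; everything downstream expects ``"world"``.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    frame: str = "world"

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if len(self.bvals) != len(self.bvecs):
            raise ValueError("gradient count mismatch")
        if self.frame not in ("image", "world"):
            raise ValueError(f"unknown gradient frame {self.frame!r}")
        norms = np.linalg.norm(self.bvecs, axis=1)
        nonzero = norms > _UNIT_TOL
        # re-normalize anything non-zero; tolerate sloppily scaled input
        self.bvecs[nonzero] /= norms[nonzero, None]
        self.bvecs[~nonzero] = 0.0
        if np.any(self.bvals[~nonzero] > 0):
            raise ValueError("zero-norm direction with nonzero b-value")

    @property
    def is_baseline(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_directions(self) -> int:
        """Number of *distinct* non-baseline directions (antipodes merged)."""
        dirs = self.bvecs[~self.is_baseline]
        if len(dirs) == 0:
            return 0
        # canonical hemisphere: first nonzero component positive
        canon = []
        for d in dirs:
            idx = np.flatnonzero(np.abs(d) > _UNIT_TOL)
            s = np.sign(d[idx[0]]) if len(idx) else 1.0
            canon.append(np.round(s * d, 5))
        return len({tuple(c) for c in canon})

    def __len__(self) -> int:
        return len(self.bvals)


@dataclass
class DWIVolume:
    """4D diffusion-weighted volume (X,Y,Z,G) with its gradient table."""

    data: np.ndarray
    affine: np.ndarray
    gradients: GradientTable
    space: str = "RAS"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (X,Y,Z,G)")
        if self.data.shape[3] != len(self.gradients):
            raise ValueError("gradient count mismatch")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite intensities")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.space not in ("RAS", "LPS"):
            raise ValueError(f"unknown space {self.space!r}")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def s0(self) -> np.ndarray:
        """Mean baseline image; requires at least one b=0 volume."""
        base = self.gradients.is_baseline
        if not np.any(base):
            raise ValueError("no baseline (b=0) volume")
        return self.data[..., base].mean(axis=3)


@dataclass
class LabelMap:
    """3D integer label image; 0 is background."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label map must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("labels must be integers")
            self.data = np.round(self.data).astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)


@dataclass
class FiducialList:
    """Named landmark points in RAS mm."""

    points: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        pts = []
        for name, pos in self.points:
            if name in seen:
                raise ValueError(f"duplicate fiducial {name!r}")
            seen.add(name)
            pos = np.asarray(pos, dtype=float).ravel()
            if pos.shape != (3,) or not np.all(np.isfinite(pos)):
                raise ValueError("bad coordinate")
            pts.append((str(name), pos))
        self.points = pts

    def __len__(self) -> int:
        return len(self.points)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.points]

    @property
    def positions(self) -> np.ndarray:
        if not self.points:
            return np.zeros((0, 3))
        return np.stack([p for _, p in self.points])


@dataclass
class Tractogram:
    """Streamlines in world-mm RAS with optional per-point scalar arrays."""

    streamlines: list[np.ndarray] = field(default_factory=list)
    per_point_scalars: dict[str, list[np.ndarray]] = field(default_factory=dict)
    per_streamline_properties: dict[str, np.ndarray] = field(default_factory=dict)
    reference_affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        sl = []
        for s in self.streamlines:
            s = np.asarray(s, dtype=np.float64).reshape(-1, 3)
            if len(s) < 2:
                raise ValueError("degenerate streamline")
            if not np.all(np.isfinite(s)):
                raise ValueError("non-finite streamline point")
            sl.append(s)
        self.streamlines = sl
        for name, arrays in self.per_point_scalars.items():
            if len(arrays) != len(sl):
                raise ValueError(f"scalar {name!r}: wrong streamline count")
            arrays = [np.asarray(a, dtype=float).ravel() for a in arrays]
            for a, s in zip(arrays, sl):
                if len(a) != len(s):
                    raise ValueError(f"scalar {name!r}: one value per point required")
            self.per_point_scalars[name] = arrays
        self.reference_affine = np.asarray(self.reference_affine, float).reshape(4, 4)

    def __len__(self) -> int:
        return len(self.streamlines)

    @property
    def n_points(self) -> int:
        return int(sum(len(s) for s in self.streamlines))

    def lengths(self) -> np.ndarray:
        """Polyline length (mm) of each streamline."""
        return np.array(
            [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in self.streamlines]
        )


@dataclass
class ScalarVolume:
    """Single-channel (or RGB, trailing axis) scalar image."""

    data: np.ndarray
    affine: np.ndarray
    name: str = "scalar"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        if self.data.ndim not in (3, 4):
            raise ValueError("scalar volume must be 3D (or 3D + channels)")


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensor in mm^2/s.

    Tensors are stored as the 6 unique components in the order
    (Dxx, Dxy, Dxz, Dyy, Dyz, Dzz) on a trailing axis.
    """

    tensors: np.ndarray
    s0: np.ndarray
    affine: np.ndarray
    mask: np.ndarray

    COMPONENTS = ("Dxx", "Dxy", "Dxz", "Dyy", "Dyz", "Dzz")

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=np.float64)
        if self.tensors.ndim != 4 or self.tensors.shape[3] != 6:
            raise ValueError("tensor array must be (X,Y,Z,6)")
        self.s0 = np.asarray(self.s0, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float).reshape(4, 4)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.tensors.shape[:3]:
            raise ValueError("mask shape mismatch")

    @property
    def shape3(self) -> tuple[int, int, int]:
        return self.tensors.shape[:3]

    def as_matrices(self) -> np.ndarray:
        """Expand the 6-vector representation to (..., 3, 3) matrices."""
        return tensor6_to_matrix(self.tensors)


def tensor6_to_matrix(t6: np.ndarray) -> np.ndarray:
    t6 = np.asarray(t6, dtype=float)
    out = np.empty(t6.shape[:-1] + (3, 3), dtype=float)
    xx, xy, xz, yy, yz, zz = (t6[..., i] for i in range(6))
    out[..., 0, 0] = xx
    out[..., 0, 1] = out[..., 1, 0] = xy
    out[..., 0, 2] = out[..., 2, 0] = xz
    out[..., 1, 1] = yy
    out[..., 1, 2] = out[..., 2, 1] = yz
    out[..., 2, 2] = zz
    return out


def matrix_to_tensor6(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    return np.stack(
        [m[..., 0, 0], m[..., 0, 1], m[..., 0, 2], m[..., 1, 1], m[..., 1, 2], m[..., 2, 2]],
        axis=-1,
    )


def world_to_voxel(affine: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Map world-mm points to continuous voxel indices."""
    pts = np.asarray(pts, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    inv = np.linalg.inv(affine)
    out = pts @ inv[:3, :3].T + inv[:3, 3]
    return out[0] if single else out


def voxel_to_world(affine: np.ndarray, idx: np.ndarray) -> np.ndarray:
    idx = np.asarray(idx, dtype=float)
    single = idx.ndim == 1
    idx = np.atleast_2d(idx)
    out = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    return out[0] if single else out


def trilinear(vol: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of ``vol`` (3D or 3D+channels) at one
    continuous voxel index, clamping to the edge voxels.

    Returns a scalar for 3D input, a channel vector otherwise.
    """
    shape = np.asarray(vol.shape[:3])
    p = np.clip(np.asarray(idx, dtype=float), 0.0, shape - 1.0)
    i0 = np.floor(p).astype(int)
    i0 = np.minimum(i0, shape - 2)
    i0 = np.maximum(i0, 0)
    f = p - i0
    c = vol[i0[0] : i0[0] + 2, i0[1] : i0[1] + 2, i0[2] : i0[2] + 2]
    wx = np.array([1 - f[0], f[0]])
    wy = np.array([1 - f[1], f[1]])
    wz = np.array([1 - f[2], f[2]])
    if vol.ndim == 3:
        return float(np.einsum("ijk,i,j,k->", c, wx, wy, wz))
    return np.einsum("ijkc,i,j,k->c", c, wx, wy, wz)


def inside_grid(shape3: tuple[int, int, int], idx: np.ndarray, margin: float = 0.0) -> bool:
    """True if a continuous voxel index lies within the voxel-center hull."""
    idx = np.asarray(idx, dtype=float)
    hi = np.asarray(shape3) - 1 - margin
    return bool(np.all(idx >= margin) and np.all(idx <= hi))
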