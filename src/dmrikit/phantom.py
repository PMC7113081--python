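"""Synthetic diffusion-MRI phantoms with known ground truth.

Phantoms are built from declarative bundle geometry (straight segments,
circular arcs, helices) rasterized as tubes on a voxel grid.  Each voxel's
signal is a mixture of bundle tensor compartments, an isotropic background
compartment, and optionally a free-water compartment inside an "edema"
region:

    S(g_i) = s0 * [ fw * exp(-b_i * d_iso)
                    + (1 - fw) * sum_j w_j * exp(-b_i * g_i^T D_j g_i) ]

where the weights w_j come from supersampled tube occupancy fractions
(bundles overlapping in a voxel share the occupancy equally when both
fill it) and the background compartment takes up the rest.  Baselines
(b=0) therefore equal s0 exactly in noiseless mode.

The default acquisition is a clinical single-shell protocol: b = 1000
s/mm^2, six baselines, 2 mm isotropic voxels.  Gradient directions come
from a deterministic generalized-spiral (Saff–Kuijlaars) scheme, which is
reproducible and close enough to uniform for 12–60 directions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    DWIVolume,
    GradientTable,
    LabelMap,
    ScalarVolume,
    TensorVolume,
    Tractogram,
    matrix_to_tensor6,
)
from .tensor import fa_from_eigenvalues

__all__ = [
    "Bundle",
    "EdemaRegion",
    "PhantomSpec",
    "PhantomTruth",
    "build_phantom",
    "add_noise",
    "spiral_directions",
    "preset_spec",
    "synthetic_bundle_tractogram",
    "PRESETS",
]

# white-matter-like eigenvalues in mm^2/s
LAMBDA_PARALLEL = 1.7e-3
LAMBDA_PERP = 0.3e-3
BACKGROUND_DIFFUSIVITY = 0.7e-3  # gray-matter-like isotropic
FREE_WATER_DIFFUSIVITY = 3.0e-3  # body-temperature water

_CENTERLINE_PITCH_MM = 0.25  # dense sampling pitch for tube rasterization
_SUPERSAMPLE = 3


@dataclass
class Bundle:
    """One fiber bundle: a parametric centerline swept as a tube."""

    centerline: dict
    radius_mm: float = 4.0
    lambda_parallel: float = LAMBDA_PARALLEL
    lambda_perp: float = LAMBDA_PERP

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("bundle radius must be > 0")
        if self.lambda_parallel < 0 or self.lambda_perp < 0:
            raise ValueError("eigenvalues must be >= 0")


@dataclass
class EdemaRegion:
    """Free-water admixture region (sphere or box), world mm."""

    region: dict
    fw: float = 0.6
    d_iso: float = FREE_WATER_DIFFUSIVITY

    def __post_init__(self) -> None:
        if not (0 <= self.fw <= 1):
            raise ValueError("fw must be in [0, 1]")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        kind = self.region.get("kind", "sphere")
        if kind == "sphere":
            c = np.asarray(self.region["center"], float)
            r = float(self.region["radius_mm"])
            return np.linalg.norm(pts - c, axis=-1) <= r
        if kind == "box":
            lo = np.asarray(self.region["min"], float)
            hi = np.asarray(self.region["max"], float)
            return np.all((pts >= lo) & (pts <= hi), axis=-1)
        raise ValueError(f"unknown region kind {kind!r}")


@dataclass
class PhantomSpec:
    """Declarative phantom description.

    Acquisition defaults follow a clinical 3T protocol: b = 1000 s/mm^2,
    six baselines, 2 mm isotropic voxels.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 16)
    voxel_mm: float = 2.0
    bundles: list[Bundle] = field(default_factory=list)
    background_diffusivity: float = BACKGROUND_DIFFUSIVITY
    edema: EdemaRegion | None = None
    bval: float = 1000.0
    n_directions: int = 30
    n_baselines: int = 6
    s0: float = 1000.0
    snr: float | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_directions < 6:
            raise ValueError("need at least 6 gradient directions")
        if self.voxel_mm <= 0:
            raise ValueError("voxel size must be > 0")


@dataclass
class PhantomTruth:
    """Ground-truth artifacts consistent with the generated signal."""

    tensor_field: TensorVolume
    bundle_masks: list[LabelMap]
    centerlines: Tractogram
    fw_map: ScalarVolume
    fa_map_true: ScalarVolume
    bundle_fractions: np.ndarray  # (X,Y,Z,n_bundles) occupancy


# --------------------------------------------------------------------------
# geometry

def _sample_centerline(spec: dict) -> tuple[np.ndarray, np.ndarray]:
    """Sample a centerline spec into dense points and unit tangents."""
    kind = spec["kind"]
    if kind == "straight":
        a = np.asarray(spec["start"], float)
        b = np.asarray(spec["end"], float)
        L = np.linalg.norm(b - a)
        n = max(int(np.ceil(L / _CENTERLINE_PITCH_MM)) + 1, 2)
        t = np.linspace(0, 1, n)[:, None]
        pts = a + t * (b - a)
        tan = np.tile((b - a) / L, (n, 1))
        return pts, tan
    if kind == "arc":
        c = np.asarray(spec["center"], float)
        r = float(spec["radius_mm"])
        a0 = np.deg2rad(float(spec.get("start_deg", 0.0)))
        a1 = np.deg2rad(float(spec.get("end_deg", 90.0)))
        L = abs(a1 - a0) * r
        n = max(int(np.ceil(L / _CENTERLINE_PITCH_MM)) + 1, 2)
        ang = np.linspace(a0, a1, n)
        # arc lives in the xy-plane at the center's z
        pts = np.stack(
            [c[0] + r * np.cos(ang), c[1] + r * np.sin(ang), np.full(n, c[2])], axis=1
        )
        s = np.sign(a1 - a0)
        tan = np.stack([-s * np.sin(ang), s * np.cos(ang), np.zeros(n)], axis=1)
        return pts, tan
    if kind == "helix":
        c = np.asarray(spec["center"], float)
        r = float(spec["radius_mm"])
        pitch = float(spec["pitch_mm"])  # z advance per turn
        turns = float(spec.get("turns", 1.0))
        L = turns * np.hypot(2 * np.pi * r, pitch)
        n = max(int(np.ceil(L / _CENTERLINE_PITCH_MM)) + 1, 2)
        ang = np.linspace(0, 2 * np.pi * turns, n)
        pts = np.stack(
            [
                c[0] + r * np.cos(ang),
                c[1] + r * np.sin(ang),
                c[2] + pitch * ang / (2 * np.pi),
            ],
            axis=1,
        )
        tan = np.stack(
            [-r * np.sin(ang), r * np.cos(ang), np.full(n, pitch / (2 * np.pi))], axis=1
        )
        tan /= np.linalg.norm(tan, axis=1, keepdims=True)
        return pts, tan
    raise ValueError(f"unknown centerline kind {kind!r}")


def spiral_directions(n: int) -> np.ndarray:
    """Deterministic near-uniform unit directions (generalized spiral).

    The midpoint latitude rule avoids the poles, so the scheme contains
    no exactly antipodal pair and all n directions are distinct for
    tensor fitting.
    """
    k = np.arange(1, n + 1)
    h = -1 + 2 * (k - 0.5) / n
    theta = np.arccos(np.clip(h, -1, 1))
    phi = np.zeros(n)
    for i in range(1, n):
        phi[i] = (phi[i - 1] + 3.6 / np.sqrt(n * (1 - h[i] ** 2))) % (2 * np.pi)
    return np.stack(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)],
        axis=1,
    )


def _tube_occupancy(
    spec: PhantomSpec, bundle: Bundle
) -> tuple[np.ndarray, np.ndarray]:
    """Supersampled tube occupancy fraction and per-voxel tangent."""
    X, Y, Z = spec.grid_shape
    v = spec.voxel_mm
    pts, tan = _sample_centerline(bundle.centerline)
    # the centerline must stay inside the grid; the tube may be clipped
    extent = np.array([X, Y, Z]) * v - v / 2.0
    if np.any(pts.min(axis=0) < -v / 2.0 - 1e-9) or np.any(pts.max(axis=0) > extent + 1e-9):
        raise ValueError("bundle out of bounds")
    tree = cKDTree(pts)

    s = _SUPERSAMPLE
    off = (np.arange(s) + 0.5) / s - 0.5  # sub-voxel offsets in voxel units
    sub = np.stack(np.meshgrid(off, off, off, indexing="ij"), axis=-1).reshape(-1, 3)
    centers = np.stack(
        np.meshgrid(np.arange(X), np.arange(Y), np.arange(Z), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    frac = np.zeros(len(centers))
    last = len(pts) - 1
    for d in sub:
        q = (centers + d) * v
        dist, near = tree.query(q, workers=-1)
        inside = dist <= bundle.radius_mm
        # flat end caps: drop points that project beyond the curve ends
        at0 = near == 0
        inside[at0] &= (q[at0] - pts[0]) @ tan[0] >= 0
        atL = near == last
        inside[atL] &= (q[atL] - pts[last]) @ tan[last] <= 0
        frac += inside
    frac /= len(sub)

    # tangent at the nearest centerline sample to each voxel center
    _, nearest = tree.query(centers * v, workers=-1)
    tangents = tan[nearest]
    return frac.reshape(X, Y, Z), tangents.reshape(X, Y, Z, 3)


def _axial_tensor(tangent: np.ndarray, lpar: float, lperp: float) -> np.ndarray:
    """D = lperp*I + (lpar - lperp) * t t^T for (..., 3) tangents."""
    t = np.asarray(tangent, float)
    outer = t[..., :, None] * t[..., None, :]
    eye = np.eye(3)
    return lperp * eye + (lpar - lperp) * outer


# --------------------------------------------------------------------------
# phantom assembly

def build_phantom(spec: PhantomSpec) -> tuple[DWIVolume, PhantomTruth]:
    """Synthesize a DWI volume and its ground truth from a PhantomSpec."""
    X, Y, Z = spec.grid_shape
    v = spec.voxel_mm
    affine = np.diag([v, v, v, 1.0])

    dirs = spiral_directions(spec.n_directions)
    bvals = np.concatenate([np.zeros(spec.n_baselines), np.full(spec.n_directions, spec.bval)])
    bvecs = np.concatenate([np.zeros((spec.n_baselines, 3)), dirs])
    grads = GradientTable(bvals=bvals, bvecs=bvecs, frame="world")

    nb = len(spec.bundles)
    fracs = np.zeros((X, Y, Z, max(nb, 1)))
    tensors_b = np.zeros((X, Y, Z, max(nb, 1), 3, 3))
    for j, b in enumerate(spec.bundles):
        frac, tang = _tube_occupancy(spec, b)
        fracs[..., j] = frac
        tensors_b[..., j, :, :] = _axial_tensor(tang, b.lambda_parallel, b.lambda_perp)
    if nb == 0:
        fracs = fracs[..., :0]
        tensors_b = tensors_b[..., :0, :, :]

    total = fracs.sum(axis=-1)
    # bundles overlapping past full occupancy share the voxel equally
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-300), 1.0)
    w_bundle = fracs * scale[..., None]
    w_bg = np.clip(1.0 - w_bundle.sum(axis=-1), 0.0, 1.0)

    centers = (
        np.stack(np.meshgrid(np.arange(X), np.arange(Y), np.arange(Z), indexing="ij"), axis=-1)
        * v
    )
    fw = np.zeros((X, Y, Z))
    d_iso = FREE_WATER_DIFFUSIVITY
    if spec.edema is not None:
        fw[spec.edema.contains(centers)] = spec.edema.fw
        d_iso = spec.edema.d_iso

    # per-gradient attenuation: tissue compartments
    b = grads.bvals  # (G,)
    g = grads.bvecs  # (G, 3)
    quad_bg = spec.background_diffusivity * np.ones((X, Y, Z, 1))
    att = w_bg[..., None] * np.exp(-b * quad_bg)  # (X,Y,Z,G)
    for j in range(nb):
        q = np.einsum("gi,xyzij,gj->xyzg", g, tensors_b[..., j, :, :], g)
        att += w_bundle[..., j, None] * np.exp(-b * q)
    signal = spec.s0 * (fw[..., None] * np.exp(-b * d_iso) + (1 - fw[..., None]) * att)

    dwi = DWIVolume(data=signal, affine=affine, gradients=grads, space="RAS")
    if spec.snr is not None:
        dwi = add_noise(dwi, spec.snr, spec.rng_seed)

    # ground truth: mean tissue tensor per voxel (exact in pure voxels)
    D_true = w_bg[..., None, None] * spec.background_diffusivity * np.eye(3)
    for j in range(nb):
        D_true = D_true + w_bundle[..., j, None, None] * tensors_b[..., j, :, :]
    t6 = matrix_to_tensor6(D_true)
    mask = np.ones((X, Y, Z), dtype=bool)
    tensor_field = TensorVolume(
        tensors=t6, s0=np.full((X, Y, Z), spec.s0), affine=affine, mask=mask
    )
    w_eig = np.linalg.eigvalsh(D_true)
    fa_true = ScalarVolume(data=fa_from_eigenvalues(w_eig), affine=affine, name="FA_true")
    fw_map = ScalarVolume(data=fw, affine=affine, name="fw_true")
    bundle_masks = [
        LabelMap(data=(fracs[..., j] >= 0.5).astype(np.int32), affine=affine)
        for j in range(nb)
    ]
    centerlines = Tractogram(
        streamlines=[_sample_centerline(bd.centerline)[0] for bd in spec.bundles]
        or [np.zeros((2, 3))],
        reference_affine=affine,
    )
    if nb == 0:
        centerlines = Tractogram(streamlines=[], reference_affine=affine)
    truth = PhantomTruth(
        tensor_field=tensor_field,
        bundle_masks=bundle_masks,
        centerlines=centerlines,
        fw_map=fw_map,
        fa_map_true=fa_true,
        bundle_fractions=fracs,
    )
    return dwi, truth


def add_noise(dwi: DWIVolume, snr: float, rng_seed: int = 0) -> DWIVolume:
    """Rician noise: S' = sqrt((S + n1)^2 + n2^2), n ~ N(0, s0/snr)."""
    if snr <= 0:
        raise ValueError("bad snr")
    rng = np.random.default_rng(rng_seed)
    base = dwi.gradients.is_baseline
    s0 = float(dwi.data[..., base].max()) if np.any(base) else float(dwi.data.max())
    sigma = s0 / snr
    n1 = rng.normal(0.0, sigma, size=dwi.data.shape)
    n2 = rng.normal(0.0, sigma, size=dwi.data.shape)
    noisy = np.sqrt((dwi.data + n1) ** 2 + n2**2)
    return DWIVolume(data=noisy, affine=dwi.affine, gradients=dwi.gradients, space=dwi.space)


# --------------------------------------------------------------------------
# presets

def preset_spec(name: str, snr: float | None = None, rng_seed: int = 0) -> PhantomSpec:
    """Named phantom presets used throughout the examples and tests."""
    if name == "straight":
        # bundle along x spanning the whole grid, so every traversed
        # cross-section is pure bundle (no partial end caps)
        return PhantomSpec(
            grid_shape=(20, 12, 12),
            bundles=[
                Bundle(
                    centerline={"kind": "straight", "start": [-1, 11, 11], "end": [39, 11, 11]},
                    radius_mm=4.0,
                )
            ],
            snr=snr,
            rng_seed=rng_seed,
        )
    if name == "arc":
        # quarter circle of radius 20 mm in the xy-plane
        return PhantomSpec(
            grid_shape=(20, 20, 8),
            bundles=[
                Bundle(
                    centerline={
                        "kind": "arc",
                        "center": [7, 7, 7],
                        "radius_mm": 20.0,
                        "start_deg": 0.0,
                        "end_deg": 90.0,
                    },
                    radius_mm=3.5,
                )
            ],
            snr=snr,
            rng_seed=rng_seed,
        )
    if name == "crossing":
        # two orthogonal bundles sharing the central block
        return PhantomSpec(
            grid_shape=(16, 16, 16),
            bundles=[
                Bundle(
                    centerline={"kind": "straight", "start": [2, 15, 15], "end": [28, 15, 15]},
                    radius_mm=4.0,
                ),
                Bundle(
                    centerline={"kind": "straight", "start": [15, 2, 15], "end": [15, 28, 15]},
                    radius_mm=4.0,
                ),
            ],
            snr=snr,
            rng_seed=rng_seed,
        )
    if name == "edema":
        # straight bundle with a free-water collar around its middle
        return PhantomSpec(
            grid_shape=(20, 12, 12),
            bundles=[
                Bundle(
                    centerline={"kind": "straight", "start": [-1, 11, 11], "end": [39, 11, 11]},
                    radius_mm=4.0,
                )
            ],
            edema=EdemaRegion(
                region={"kind": "sphere", "center": [19, 11, 11], "radius_mm": 9.0},
                fw=0.6,
            ),
            snr=snr,
            rng_seed=rng_seed,
        )
    if name == "isotropic":
        return PhantomSpec(grid_shape=(12, 12, 12), bundles=[], snr=snr, rng_seed=rng_seed)
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("straight", "arc", "crossing", "edema", "isotropic")


def synthetic_bundle_tractogram(
    n_bundles: int = 4,
    fibers_per_bundle: int = 50,
    separation_mm: float = 30.0,
    length_mm: float = 60.0,
    jitter_mm: float = 1.0,
    n_points: int = 30,
    rng_seed: int = 0,
) -> tuple[Tractogram, np.ndarray]:
    """Synthetic multi-bundle tractogram for clustering experiments.

    Bundles are parallel straight fiber groups laid out on a line,
    ``separation_mm`` apart, each fiber a jittered copy of its bundle
    centerline.  Returns the tractogram and the true bundle label per
    fiber.
    """
    rng = np.random.default_rng(rng_seed)
    streamlines = []
    labels = []
    t = np.linspace(0, 1, n_points)[:, None]
    for b in range(n_bundles):
        origin = np.array([0.0, b * separation_mm, 0.0])
        base = origin + t * np.array([length_mm, 0.0, 0.0])
        for _ in range(fibers_per_bundle):
            offset = rng.normal(0.0, jitter_mm, size=3)
            wobble = rng.normal(0.0, jitter_mm * 0.3, size=(n_points, 3))
            sl = base + offset + wobble
            if rng.random() < 0.5:  # random point order, mdf must not care
                sl = sl[::-1]
            streamlines.append(sl)
            labels.append(b)
    return Tractogram(streamlines=streamlines), np.asarray(labels)
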