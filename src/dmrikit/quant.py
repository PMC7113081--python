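"""Tract quantification: scalar sampling, statistics, volume, lengths.

Statistics pool over all fiber points (not per-streamline means); the
per-streamline alternative is available via ``per_streamline=True`` on
:func:`tract_statistics`.  Tract volume voxelizes point membership after
densifying each streamline so consecutive samples are at most half the
smallest voxel edge apart, which bounds the voxelization error by the
densification pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LabelMap, ScalarVolume, Tractogram, trilinear, world_to_voxel

__all__ = [
    "TractStats",
    "sample_scalars_on_tract",
    "tract_statistics",
    "tract_volume",
    "length_distribution",
    "densify_streamline",
]


@dataclass
class TractStats:
    n_streamlines: int
    n_points: int
    scalar_stats: dict[str, dict[str, float]] = field(default_factory=dict)
    length_stats: dict[str, float] = field(default_factory=dict)
    lengths: np.ndarray = field(default_factory=lambda: np.zeros(0))
    volume_mm3: float | None = None


def _stat_block(vals: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(vals.mean()),
        "std": float(vals.std()),
        "min": float(vals.min()),
        "max": float(vals.max()),
    }


def sample_scalars_on_tract(
    t: Tractogram, sv: ScalarVolume, name: str | None = None
) -> Tractogram:
    """Attach a per-point scalar array by trilinear probing of ``sv``.

    Points outside the grid receive the nearest in-grid (edge-clamped)
    value and are flagged 0 in a companion ``<name>_valid`` array.
    """
    if name is None:
        name = sv.name
    shape3 = np.asarray(sv.data.shape[:3])
    values: list[np.ndarray] = []
    valid: list[np.ndarray] = []
    any_inside = False
    for s in t.streamlines:
        idx = world_to_voxel(sv.affine, s)
        ok = np.all((idx >= 0) & (idx <= shape3 - 1), axis=1)
        any_inside |= bool(ok.any())
        vals = np.array([trilinear(sv.data, i) for i in idx])
        values.append(vals)
        valid.append(ok.astype(float))
    if len(t) and not any_inside:
        raise ValueError("no overlap between tract and scalar grid")
    scalars = dict(t.per_point_scalars)
    scalars[name] = values
    scalars[f"{name}_valid"] = valid
    return Tractogram(
        streamlines=t.streamlines,
        per_point_scalars=scalars,
        per_streamline_properties=dict(t.per_streamline_properties),
        reference_affine=t.reference_affine,
    )


def tract_statistics(t: Tractogram, per_streamline: bool = False) -> TractStats:
    """Pooled statistics of every attached per-point scalar plus the
    streamline length distribution.

    Scalars with a companion ``<name>_valid`` array only pool points
    flagged valid.  With ``per_streamline=True`` the scalar statistics
    are computed over per-streamline means instead of pooled points.
    """
    if len(t) == 0:
        raise ValueError("empty tract")
    lengths = t.lengths()
    scalar_stats: dict[str, dict[str, float]] = {}
    for name, arrays in t.per_point_scalars.items():
        if name.endswith("_valid"):
            continue
        vmask = t.per_point_scalars.get(f"{name}_valid")
        if per_streamline:
            means = []
            for i, a in enumerate(arrays):
                keep = vmask[i] > 0.5 if vmask is not None else np.ones(len(a), bool)
                if keep.any():
                    means.append(a[keep].mean())
            pooled = np.asarray(means)
        else:
            chunks = []
            for i, a in enumerate(arrays):
                keep = vmask[i] > 0.5 if vmask is not None else np.ones(len(a), bool)
                chunks.append(np.asarray(a)[keep])
            pooled = np.concatenate(chunks) if chunks else np.zeros(0)
        if pooled.size:
            scalar_stats[name] = _stat_block(pooled)
    return TractStats(
        n_streamlines=len(t),
        n_points=t.n_points,
        scalar_stats=scalar_stats,
        length_stats=_stat_block(lengths),
        lengths=lengths,
    )


def densify_streamline(s: np.ndarray, max_pitch_mm: float) -> np.ndarray:
    """Insert points so consecutive samples are <= max_pitch_mm apart.

    Subdivision is linear per segment, so the polyline geometry (and its
    length) is preserved exactly.
    """
    out = [s[0]]
    for a, b in zip(s[:-1], s[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / max_pitch_mm)), 1)
        for k in range(1, n + 1):
            out.append(a + (b - a) * (k / n))
    return np.asarray(out)


def tract_volume(
    t: Tractogram, reference: LabelMap | ScalarVolume
) -> tuple[float, LabelMap]:
    """Voxelized tract volume (mm^3) plus the binary occupancy map.

    A voxel counts if at least one (densified) fiber point falls in it;
    the volume is the voxel count times the voxel volume, so duplicated
    streamlines are idempotent.
    """
    affine = reference.affine
    shape3 = np.asarray(reference.data.shape[:3])
    voxel_edges = np.linalg.norm(affine[:3, :3], axis=0)
    vox_volume = float(abs(np.linalg.det(affine[:3, :3])))
    occ = np.zeros(tuple(shape3), dtype=bool)
    pitch = 0.5 * voxel_edges.min()
    for s in t.streamlines:
        dense = densify_streamline(s, pitch)
        idx = np.round(world_to_voxel(affine, dense)).astype(int)
        ok = np.all((idx >= 0) & (idx <= shape3 - 1), axis=1)
        idx = idx[ok]
        if len(idx):
            occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    volume = float(occ.sum()) * vox_volume
    return volume, LabelMap(data=occ.astype(np.int32), affine=affine)


def length_distribution(t: Tractogram, bin_mm: float) -> dict[str, np.ndarray]:
    """Fixed-width histogram of streamline lengths.

    Bins span [min_length, max_length]; the final bin is closed on the
    right so every streamline is counted exactly once.
    """
    if bin_mm <= 0:
        raise ValueError("bin_mm must be > 0")
    if len(t) == 0:
        return {"bin_edges": np.zeros(0), "counts": np.zeros(0, dtype=int)}
    lengths = t.lengths()
    lo = lengths.min()
    hi = lengths.max()
    n_bins = max(int(np.ceil((hi - lo) / bin_mm)), 1)
    edges = lo + bin_mm * np.arange(n_bins + 1)
    counts, _ = np.histogram(lengths, bins=edges)
    return {"bin_edges": edges, "counts": counts}
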