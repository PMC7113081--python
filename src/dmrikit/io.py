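"""Readers and writers for every on-disk format the pipeline touches.

Supported dialects
------------------
* DWI: NIfTI-1 (``.nii``/``.nii.gz``) with FSL-style sibling ``.bval`` /
  ``.bvec`` files, and NRRD (``.nrrd``) with ``DWMRI_gradient_NNNN``
  key/value gradients.
* Tractograms: TrackVis TRK (via nibabel) and legacy ASCII VTK polydata
  with LINES cells.
* Fiducials: CSV with header ``name,x,y,z`` in RAS mm.

Everything is normalized on read into RAS world millimeters:

* NRRD files in LPS space have x and y negated on the space directions,
  origin and gradient directions.
* FSL bvecs are stated in the image frame; they are rotated by the
  (orthonormalized) rotational part of the affine into the world frame
  and re-normalized.
* NRRD gradients follow the DWMRI convention where the per-gradient
  b-value is ``b_max * |g|^2``; directions are re-normalized after the
  b-value is extracted.
"""

from __future__ import annotations

import csv
import gzip
import os
import re
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import (
    DWIVolume,
    FiducialList,
    GradientTable,
    LabelMap,
    ScalarVolume,
    TensorVolume,
    Tractogram,
)

__all__ = [
    "read_dwi",
    "write_dwi",
    "read_tractogram",
    "write_tractogram",
    "read_fiducials",
    "write_fiducials",
    "read_labelmap",
    "write_labelmap",
    "read_scalar",
    "write_scalar",
    "read_tensor_volume",
    "write_tensor_volume",
]


# --------------------------------------------------------------------------
# gradient frame handling

def _rotation_part(affine: np.ndarray) -> np.ndarray:
    """Orthonormalized rotational part of an affine (columns normalized,
    then polar-decomposed to strip shear)."""
    A = np.asarray(affine)[:3, :3]
    U, _, Vt = np.linalg.svd(A)
    R = U @ Vt
    if np.linalg.det(R) < 0:  # keep it a proper rotation
        U[:, -1] *= -1
        R = U @ Vt
    return R


def _bvecs_image_to_world(bvecs: np.ndarray, affine: np.ndarray) -> np.ndarray:
    R = _rotation_part(affine)
    out = bvecs @ R.T
    norms = np.linalg.norm(out, axis=1)
    nz = norms > 1e-12
    out[nz] /= norms[nz, None]
    out[~nz] = 0.0
    return out


def _bvecs_world_to_image(bvecs: np.ndarray, affine: np.ndarray) -> np.ndarray:
    R = _rotation_part(affine)
    out = bvecs @ R  # R^T applied from the left == right-multiply by R
    norms = np.linalg.norm(out, axis=1)
    nz = norms > 1e-12
    out[nz] /= norms[nz, None]
    out[~nz] = 0.0
    return out


# --------------------------------------------------------------------------
# DWI: NIfTI + bval/bvec

def _bvec_bval_paths(path: Path) -> tuple[Path, Path]:
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            break
    return path.parent / f"{stem}.bval", path.parent / f"{stem}.bvec"


def _read_dwi_nifti(path: Path) -> DWIVolume:
    bval_p, bvec_p = _bvec_bval_paths(path)
    if not bval_p.exists() or not bvec_p.exists():
        raise IOError("no gradient table (missing .bval/.bvec sibling files)")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., None]
    affine = np.asarray(img.affine, dtype=float)
    bvals = np.loadtxt(str(bval_p), ndmin=1).ravel()
    bvecs = np.loadtxt(str(bvec_p), ndmin=2)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        pass  # FSL writes 3 rows x N cols; 3x3 is ambiguous, keep rows=xyz
    if len(bvals) != len(bvecs):
        raise IOError("gradient count mismatch")
    if data.shape[3] != len(bvals):
        raise IOError("gradient count mismatch")
    world = _bvecs_image_to_world(np.asarray(bvecs, float), affine)
    grads = GradientTable(bvals=bvals, bvecs=world, frame="world")
    return DWIVolume(data=data, affine=affine, gradients=grads, space="RAS")


def _write_dwi_nifti(vol: DWIVolume, path: Path) -> Path:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))
    bval_p, bvec_p = _bvec_bval_paths(path)
    np.savetxt(str(bval_p), vol.gradients.bvals[None, :], fmt="%.6g")
    image_bvecs = _bvecs_world_to_image(vol.gradients.bvecs.copy(), vol.affine)
    np.savetxt(str(bvec_p), image_bvecs.T, fmt="%.10g")
    return path


# --------------------------------------------------------------------------
# DWI: NRRD

_NRRD_SPACES = {
    "right-anterior-superior": "RAS",
    "ras": "RAS",
    "left-posterior-superior": "LPS",
    "lps": "LPS",
}


def _parse_nrrd_vector(tok: str) -> np.ndarray | None:
    tok = tok.strip()
    if tok == "none":
        return None
    m = re.match(r"\(([^)]*)\)", tok)
    if not m:
        raise IOError("unparseable NRRD vector")
    return np.array([float(x) for x in m.group(1).split(",")])


def _read_dwi_nrrd(path: Path) -> DWIVolume:
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise IOError("no gradient table (not a NRRD file)")
        fields: dict[str, str] = {}
        keyvals: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").rstrip("\r\n")
            if text.startswith("#"):
                continue
            if ":=" in text:
                k, v = text.split(":=", 1)
                keyvals[k.strip()] = v.strip()
            elif ":" in text:
                k, v = text.split(":", 1)
                fields[k.strip().lower()] = v.strip()
        payload = fh.read()

    try:
        sizes = [int(s) for s in fields["sizes"].split()]
        dim = int(fields.get("dimension", len(sizes)))
        dtype = np.dtype(
            {
                "float": "f4",
                "double": "f8",
                "short": "i2",
                "unsigned short": "u2",
                "int": "i4",
                "uchar": "u1",
            }[fields["type"]]
        )
        if fields.get("endian", "little") == "big":
            dtype = dtype.newbyteorder(">")
        encoding = fields.get("encoding", "raw")
    except KeyError as exc:
        raise IOError(f"unparseable NRRD header (missing {exc})") from exc
    if dim != 4:
        raise IOError("expected a 4D DWI NRRD")
    if encoding == "gzip":
        payload = gzip.decompress(payload)
    elif encoding != "raw":
        raise IOError(f"unsupported NRRD encoding {encoding!r}")

    # NRRD lists the fastest axis first
    data = np.frombuffer(payload, dtype=dtype, count=int(np.prod(sizes)))
    data = data.reshape(sizes, order="F").astype(np.float64)

    sdirs = [
        _parse_nrrd_vector(t)
        for t in re.findall(r"\([^)]*\)|none", fields.get("space directions", ""))
    ]
    if len(sdirs) != 4:
        raise IOError("unparseable NRRD space directions")
    list_axis = next((i for i, d in enumerate(sdirs) if d is None), None)
    if list_axis is None:
        raise IOError("no gradient (list) axis in NRRD")
    if list_axis not in (0, 3):
        raise IOError("gradient axis must be first or last")
    if list_axis == 0:
        data = np.moveaxis(data, 0, 3)
        sdirs = sdirs[1:] + [None]
        sizes = sizes[1:] + [sizes[0]]
    dirmat = np.stack(sdirs[:3], axis=1)  # columns are the space directions
    origin = _parse_nrrd_vector(fields.get("space origin", "(0,0,0)"))
    space = _NRRD_SPACES.get(fields.get("space", "right-anterior-superior").lower())
    if space is None:
        raise IOError(f"unsupported NRRD space {fields.get('space')!r}")

    grad_keys = sorted(k for k in keyvals if k.startswith("DWMRI_gradient_"))
    if not grad_keys:
        raise IOError("no gradient table")
    if len(grad_keys) != sizes[3]:
        raise IOError("gradient count mismatch")
    bmax = float(keyvals.get("DWMRI_b-value", 0.0))
    raw = np.array([[float(x) for x in keyvals[k].split()] for k in grad_keys])
    norms = np.linalg.norm(raw, axis=1)
    bvals = bmax * norms**2
    bvecs = np.zeros_like(raw)
    nz = norms > 1e-8
    bvecs[nz] = raw[nz] / norms[nz, None]
    bvals[~nz] = 0.0

    mf = re.findall(r"\([^)]*\)", fields.get("measurement frame", ""))
    if mf:
        M = np.stack([_parse_nrrd_vector(t) for t in mf], axis=1)
        bvecs = bvecs @ M.T

    affine = np.eye(4)
    affine[:3, :3] = dirmat
    affine[:3, 3] = origin
    if space == "LPS":
        flip = np.diag([-1.0, -1.0, 1.0])
        affine[:3, :3] = flip @ affine[:3, :3]
        affine[:3, 3] = flip @ affine[:3, 3]
        bvecs = bvecs @ flip  # symmetric, so right-multiply is fine

    grads = GradientTable(bvals=bvals, bvecs=bvecs, frame="world")
    return DWIVolume(data=data, affine=affine, gradients=grads, space="RAS")


def _write_dwi_nrrd(vol: DWIVolume, path: Path) -> Path:
    X, Y, Z, G = vol.data.shape
    A = vol.affine
    bvals = vol.gradients.bvals
    bmax = float(bvals.max()) if bvals.max() > 0 else 0.0
    lines = [
        "NRRD0005",
        "# dmrikit diffusion-weighted NRRD",
        "type: float",
        "dimension: 4",
        "space: right-anterior-superior",
        f"sizes: {X} {Y} {Z} {G}",
        "space directions: "
        + " ".join(f"({A[0, j]:.10g},{A[1, j]:.10g},{A[2, j]:.10g})" for j in range(3))
        + " none",
        "kinds: space space space list",
        "endian: little",
        "encoding: raw",
        f"space origin: ({A[0, 3]:.10g},{A[1, 3]:.10g},{A[2, 3]:.10g})",
        "measurement frame: (1,0,0) (0,1,0) (0,0,1)",
        "modality:=DWMRI",
        f"DWMRI_b-value:={bmax:.10g}",
    ]
    for i, (b, v) in enumerate(zip(bvals, vol.gradients.bvecs)):
        scale = np.sqrt(b / bmax) if bmax > 0 and b > 0 else 0.0
        g = v * scale
        lines.append(f"DWMRI_gradient_{i:04d}:={g[0]:.10g} {g[1]:.10g} {g[2]:.10g}")
    header = "\n".join(lines) + "\n\n"
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ravel(vol.data.astype("<f4"), order="F").tobytes())
    return path


def read_dwi(path: str | os.PathLike, dialect: str | None = None) -> DWIVolume:
    """Read a diffusion-weighted volume, normalizing to RAS world space.

    ``dialect`` is ``"nifti_bvec_bval"`` or ``"nrrd"``; if None it is
    inferred from the file extension.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"file not found: {path}")
    if dialect is None:
        dialect = "nrrd" if path.suffix in (".nrrd", ".nhdr") else "nifti_bvec_bval"
    if dialect == "nifti_bvec_bval":
        return _read_dwi_nifti(path)
    if dialect == "nrrd":
        return _read_dwi_nrrd(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_dwi(vol: DWIVolume, path: str | os.PathLike, dialect: str | None = None) -> Path:
    path = Path(path)
    if dialect is None:
        dialect = "nrrd" if path.suffix in (".nrrd", ".nhdr") else "nifti_bvec_bval"
    if dialect == "nifti_bvec_bval":
        return _write_dwi_nifti(vol, path)
    if dialect == "nrrd":
        return _write_dwi_nrrd(vol, path)
    raise ValueError(f"unknown dialect {dialect!r}")


# --------------------------------------------------------------------------
# tractograms

def _read_trk(path: Path) -> Tractogram:
    try:
        trk = nib.streamlines.load(str(path))  # loads into RAS mm
    except Exception as exc:
        raise IOError("unparseable tractogram") from exc
    sl = [np.asarray(s, dtype=np.float64) for s in trk.streamlines]
    scalars: dict[str, list[np.ndarray]] = {}
    for name in trk.tractogram.data_per_point.keys():
        scalars[str(name)] = [
            np.asarray(a, dtype=float).ravel()
            for a in trk.tractogram.data_per_point[name]
        ]
    aff = np.asarray(trk.header.get("voxel_to_rasmm", np.eye(4)), dtype=float)
    return Tractogram(streamlines=sl, per_point_scalars=scalars, reference_affine=aff)


def _write_trk(t: Tractogram, path: Path) -> Path:
    dpp = {
        name: [np.asarray(a, dtype=np.float32)[:, None] for a in arrays]
        for name, arrays in t.per_point_scalars.items()
    }
    nt = nib.streamlines.Tractogram(
        streamlines=[s.astype(np.float32) for s in t.streamlines],
        data_per_point=dpp,
        affine_to_rasmm=np.eye(4),
    )
    header = nib.streamlines.trk.TrkFile.create_empty_header()
    ref = np.asarray(t.reference_affine, dtype=float)
    header["voxel_to_rasmm"] = ref.astype(np.float32)
    header["voxel_sizes"] = np.linalg.norm(ref[:3, :3], axis=0).astype(np.float32)
    header["voxel_order"] = "".join(nib.orientations.aff2axcodes(ref)).encode()
    nib.streamlines.save(nt, str(path), header=header)
    return path


def _write_vtk_ascii(t: Tractogram, path: Path) -> Path:
    pts = np.concatenate(t.streamlines) if len(t) else np.zeros((0, 3))
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("dmrikit tractogram\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        counts = [len(s) for s in t.streamlines]
        fh.write(f"LINES {len(counts)} {sum(counts) + len(counts)}\n")
        offset = 0
        for c in counts:
            fh.write(" ".join([str(c)] + [str(offset + i) for i in range(c)]) + "\n")
            offset += c
        if t.per_point_scalars:
            fh.write(f"POINT_DATA {len(pts)}\n")
            fh.write(f"FIELD scalars {len(t.per_point_scalars)}\n")
            for name, arrays in t.per_point_scalars.items():
                flat = np.concatenate(arrays) if arrays else np.zeros(0)
                fh.write(f"{name} 1 {len(flat)} float\n")
                for i in range(0, len(flat), 9):
                    fh.write(" ".join(f"{v:.6f}" for v in flat[i : i + 9]) + "\n")
    return path


def _read_vtk_ascii(path: Path) -> Tractogram:
    try:
        with open(path) as fh:
            tokens = fh.read().split()
    except UnicodeDecodeError as exc:
        raise IOError("unparseable tractogram") from exc
    if not tokens or "POLYDATA" not in tokens:
        raise IOError("unparseable tractogram")
    try:
        i = tokens.index("POINTS")
        n_pts = int(tokens[i + 1])
        vals = [float(x) for x in tokens[i + 3 : i + 3 + 3 * n_pts]]
        pts = np.array(vals).reshape(n_pts, 3)
        j = tokens.index("LINES")
        n_lines = int(tokens[j + 1])
        total = int(tokens[j + 2])
        conn = [int(x) for x in tokens[j + 3 : j + 3 + total]]
        streamlines = []
        slices = []
        k = 0
        for _ in range(n_lines):
            c = conn[k]
            ids = conn[k + 1 : k + 1 + c]
            streamlines.append(pts[ids])
            slices.append(ids)
            k += 1 + c
        scalars: dict[str, list[np.ndarray]] = {}
        if "POINT_DATA" in tokens:
            f = tokens.index("POINT_DATA")
            rest = tokens[f + 2 :]
            if rest and rest[0] == "FIELD":
                n_arrays = int(rest[2])
                pos = 3
                for _ in range(n_arrays):
                    name = rest[pos]
                    n_vals = int(rest[pos + 2])
                    vals = np.array(
                        [float(x) for x in rest[pos + 4 : pos + 4 + n_vals]]
                    )
                    scalars[name] = [vals[ids] for ids in slices]
                    pos += 4 + n_vals
    except (ValueError, IndexError) as exc:
        raise IOError("unparseable tractogram") from exc
    return Tractogram(streamlines=streamlines, per_point_scalars=scalars)


def read_tractogram(path: str | os.PathLike, dialect: str | None = None) -> Tractogram:
    """Read a tractogram (TRK or legacy ASCII VTK) into RAS world mm."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"file not found: {path}")
    if dialect is None:
        dialect = "trk" if path.suffix == ".trk" else "vtk_ascii"
    if dialect == "trk":
        return _read_trk(path)
    if dialect == "vtk_ascii":
        return _read_vtk_ascii(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_tractogram(
    t: Tractogram, path: str | os.PathLike, dialect: str | None = None
) -> Path:
    path = Path(path)
    for s in t.streamlines:
        if len(s) < 2:
            raise ValueError("degenerate streamline")
    if dialect is None:
        dialect = "trk" if path.suffix == ".trk" else "vtk_ascii"
    if dialect == "trk":
        return _write_trk(t, path)
    if dialect == "vtk_ascii":
        return _write_vtk_ascii(t, path)
    raise ValueError(f"unknown dialect {dialect!r}")


# --------------------------------------------------------------------------
# fiducials

def read_fiducials(path: str | os.PathLike) -> FiducialList:
    """Read a ``name,x,y,z`` CSV (RAS mm) into an ordered FiducialList."""
    points: list[tuple[str, np.ndarray]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"name", "x", "y", "z"}
        if reader.fieldnames is None or not required.issubset(set(reader.fieldnames)):
            raise IOError("fiducial CSV needs a name,x,y,z header")
        for row in reader:
            try:
                pos = np.array([float(row["x"]), float(row["y"]), float(row["z"])])
            except (TypeError, ValueError) as exc:
                raise ValueError("bad coordinate") from exc
            points.append((row["name"], pos))
    return FiducialList(points=points)


def write_fiducials(f: FiducialList, path: str | os.PathLike) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x", "y", "z"])
        for name, pos in f.points:
            writer.writerow([name, f"{pos[0]:.6f}", f"{pos[1]:.6f}", f"{pos[2]:.6f}"])
    return path


# --------------------------------------------------------------------------
# scalar / label / tensor NIfTI helpers (CLI plumbing)

def read_labelmap(path: str | os.PathLike) -> LabelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return LabelMap(data=np.round(data).astype(np.int32), affine=np.asarray(img.affine))


def write_labelmap(lm: LabelMap, path: str | os.PathLike) -> Path:
    nib.save(nib.Nifti1Image(lm.data.astype(np.int16), lm.affine), str(path))
    return Path(path)


def read_scalar(path: str | os.PathLike, name: str = "scalar") -> ScalarVolume:
    img = nib.load(str(path))
    return ScalarVolume(
        data=np.asarray(img.dataobj, dtype=np.float64),
        affine=np.asarray(img.affine),
        name=name,
    )


def write_scalar(sv: ScalarVolume, path: str | os.PathLike) -> Path:
    nib.save(nib.Nifti1Image(sv.data.astype(np.float32), sv.affine), str(path))
    return Path(path)


def write_tensor_volume(tv: TensorVolume, path: str | os.PathLike) -> Path:
    """Persist tensors as a 4D NIfTI with 8 volumes: the 6 unique tensor
    components (Dxx,Dxy,Dxz,Dyy,Dyz,Dzz), then S0, then the binary mask."""
    stack = np.concatenate(
        [tv.tensors, tv.s0[..., None], tv.mask.astype(np.float64)[..., None]], axis=3
    )
    nib.save(nib.Nifti1Image(stack.astype(np.float32), tv.affine), str(path))
    return Path(path)


def read_tensor_volume(path: str | os.PathLike) -> TensorVolume:
    img = nib.load(str(path))
    stack = np.asarray(img.dataobj, dtype=np.float64)
    if stack.ndim != 4 or stack.shape[3] != 8:
        raise IOError("expected an 8-volume tensor NIfTI (6 components + S0 + mask)")
    return TensorVolume(
        tensors=stack[..., :6],
        s0=stack[..., 6],
        affine=np.asarray(img.affine),
        mask=stack[..., 7] > 0.5,
    )
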