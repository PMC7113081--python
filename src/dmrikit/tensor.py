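"""Diffusion tensor estimation and derived scalar maps.

The signal model is the monoexponential tensor model

    S_i = S0 * exp(-b_i * g_i^T D g_i)

fit per voxel by log-linear least squares over the 7 unknowns (6 unique
tensor components plus ln S0).  Weighted least squares (``method="wls"``)
re-solves with weights equal to the squared predicted signals from a
first LLS pass, the standard variance-stabilizing choice for
log-transformed Rician-ish data.  Negative eigenvalues are clamped to
zero after fitting and the tensor reconstructed, so every in-mask tensor
is symmetric positive semi-definite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    DWIVolume,
    LabelMap,
    ScalarVolume,
    TensorVolume,
    matrix_to_tensor6,
    tensor6_to_matrix,
    trilinear,
    world_to_voxel,
)

__all__ = [
    "fit_tensors",
    "fa_map",
    "md_map",
    "dec_map",
    "probe_scalar",
    "roi_statistics",
    "fa_from_eigenvalues",
    "tensor_eigensystem",
    "design_matrix",
]

# voxels where more than this fraction of measurements hit the log floor
# are dropped from the mask (signal too corrupted to fit)
_CLAMP_DROP_FRACTION = 0.25
_SIGNAL_FLOOR_FRACTION = 1e-6


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """(G, 7) design matrix for ln S = X @ [Dxx,Dxy,Dxz,Dyy,Dyz,Dzz, ln S0]."""
    b = np.asarray(bvals, float)
    g = np.asarray(bvecs, float)
    X = np.empty((len(b), 7))
    X[:, 0] = -b * g[:, 0] ** 2
    X[:, 1] = -2 * b * g[:, 0] * g[:, 1]
    X[:, 2] = -2 * b * g[:, 0] * g[:, 2]
    X[:, 3] = -b * g[:, 1] ** 2
    X[:, 4] = -2 * b * g[:, 1] * g[:, 2]
    X[:, 5] = -b * g[:, 2] ** 2
    X[:, 6] = 1.0
    return X


def _clamp_spd(t6: np.ndarray) -> np.ndarray:
    """Clamp negative eigenvalues to 0 and rebuild the tensors (N, 6)."""
    D = tensor6_to_matrix(t6)
    w, V = np.linalg.eigh(D)
    w = np.clip(w, 0.0, None)
    D = np.einsum("...ij,...j,...kj->...ik", V, w, V)
    return matrix_to_tensor6(D)


def fit_tensors(
    dwi: DWIVolume,
    mask: LabelMap | None = None,
    method: str = "lls",
) -> TensorVolume:
    """Fit one diffusion tensor per in-mask voxel.

    Parameters
    ----------
    dwi : acquisition with >=6 distinct non-baseline directions and >=1
        baseline volume.
    mask : optional label map; nonzero voxels are fit.  Without a mask all
        voxels with positive mean baseline are fit.
    method : ``"lls"`` (log-linear least squares) or ``"wls"``
        (two-pass weighted least squares).
    """
    if method not in ("lls", "wls"):
        raise ValueError(f"unknown method {method!r}")
    gt = dwi.gradients
    if gt.n_directions < 6:
        raise ValueError("underdetermined: need >=6 distinct non-baseline directions")
    if not np.any(gt.is_baseline):
        raise ValueError("no baseline (b=0) volume")

    shape3 = dwi.shape3
    s0_img = dwi.s0()
    if mask is not None:
        if mask.data.shape != shape3:
            raise ValueError("mask grid incompatible with DWI")
        m = (mask.data > 0) & (s0_img > 0)
    else:
        m = s0_img > 0

    X = design_matrix(gt.bvals, gt.bvecs)
    sig = dwi.data[m]  # (N, G)
    floor = _SIGNAL_FLOOR_FRACTION * s0_img[m][:, None]
    floor = np.maximum(floor, 1e-300)
    clamped = sig < floor
    keep = clamped.mean(axis=1) <= _CLAMP_DROP_FRACTION
    # all-zero voxels can't be fit at all
    keep &= sig.max(axis=1) > 0

    y = np.log(np.maximum(sig, floor))
    beta = y @ np.linalg.pinv(X).T  # (N, 7) LLS solution

    if method == "wls":
        w = np.exp(2.0 * (beta @ X.T))  # squared predicted signals
        XT = X.T[None, :, :]
        A = np.einsum("ig,ng,gj->nij", X.T, w, X)
        b = np.einsum("ig,ng,ng->ni", X.T, w, y)
        try:
            beta = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            pass  # keep the LLS solution for singular voxels

    t6 = np.zeros((len(sig), 6))
    s0_fit = np.zeros(len(sig))
    t6[keep] = _clamp_spd(beta[keep, :6])
    s0_fit[keep] = np.exp(beta[keep, 6])

    tensors = np.zeros(shape3 + (6,))
    s0_vol = np.zeros(shape3)
    tensors[m] = t6
    s0_vol[m] = s0_fit
    final_mask = np.zeros(shape3, dtype=bool)
    final_mask[m] = keep
    tensors[~final_mask] = 0.0
    return TensorVolume(tensors=tensors, s0=s0_vol, affine=dwi.affine, mask=final_mask)


# --------------------------------------------------------------------------
# eigensystem and scalar maps

def tensor_eigensystem(t6: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and matching eigenvectors of (..., 6) tensors.

    Eigenvector signs follow the first-nonzero-component-positive
    convention so repeated runs are bit-identical.
    """
    D = tensor6_to_matrix(t6)
    w, V = np.linalg.eigh(D)  # ascending
    w = w[..., ::-1]
    V = V[..., ::-1]
    # sign convention: first component of each eigenvector with
    # magnitude > tol is made positive
    for k in range(3):
        v = V[..., :, k]
        comp = np.where(
            np.abs(v[..., 0]) > 1e-12,
            v[..., 0],
            np.where(np.abs(v[..., 1]) > 1e-12, v[..., 1], v[..., 2]),
        )
        sign = np.where(comp < 0, -1.0, 1.0)
        V[..., :, k] = v * sign[..., None]
    return w, V


def fa_from_eigenvalues(w: np.ndarray) -> np.ndarray:
    """Fractional anisotropy from eigenvalues (last axis length 3)."""
    w = np.asarray(w, float)
    mean = w.mean(axis=-1, keepdims=True)
    num = np.sqrt(((w - mean) ** 2).sum(axis=-1))
    den = np.sqrt((w**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def fa_map(tv: TensorVolume) -> ScalarVolume:
    """FA = sqrt(3/2) * ||lambda - mean||, normalized by ||lambda||; 0 for
    zero (out-of-mask or degenerate) tensors."""
    w, _ = tensor_eigensystem(tv.tensors)
    fa = fa_from_eigenvalues(w)
    fa[~tv.mask] = 0.0
    return ScalarVolume(data=fa, affine=tv.affine, name="FA")


def md_map(tv: TensorVolume) -> ScalarVolume:
    """Mean diffusivity: trace(D)/3 in mm^2/s."""
    md = (tv.tensors[..., 0] + tv.tensors[..., 3] + tv.tensors[..., 5]) / 3.0
    md = np.clip(md, 0.0, None)
    md[~tv.mask] = 0.0
    return ScalarVolume(data=md, affine=tv.affine, name="MD")


def dec_map(tv: TensorVolume) -> ScalarVolume:
    """Direction-encoded color map: RGB = FA * |principal eigenvector|."""
    w, V = tensor_eigensystem(tv.tensors)
    fa = fa_from_eigenvalues(w)
    fa[~tv.mask] = 0.0
    rgb = fa[..., None] * np.abs(V[..., :, 0])
    return ScalarVolume(data=np.clip(rgb, 0.0, 1.0), affine=tv.affine, name="DEC")


# --------------------------------------------------------------------------
# probing and ROI statistics

def probe_scalar(sv: ScalarVolume, p, interp: str = "trilinear") -> float:
    """Sample a scalar volume at one world-mm point."""
    idx = world_to_voxel(sv.affine, np.asarray(p, float))
    hi = np.asarray(sv.data.shape[:3]) - 1
    if np.any(idx < -1e-9) or np.any(idx > hi + 1e-9):
        raise ValueError("out of bounds")
    if interp == "nearest":
        i = np.clip(np.round(idx).astype(int), 0, hi)
        return float(sv.data[tuple(i)])
    if interp == "trilinear":
        return float(trilinear(sv.data, idx))
    raise ValueError(f"unknown interpolation {interp!r}")


def roi_statistics(sv: ScalarVolume, roi: LabelMap) -> pd.DataFrame:
    """Per-label count/mean/std/min/max of a scalar map over an ROI.

    std is the population standard deviation (ddof=0).
    """
    if roi.data.shape != sv.data.shape[:3]:
        raise ValueError("ROI grid incompatible with scalar volume")
    rows = []
    for label in np.unique(roi.data):
        if label == 0:
            continue
        vals = sv.data[roi.data == label]
        rows.append(
            {
                "label": int(label),
                "count": int(vals.size),
                "mean": float(vals.mean()),
                "std": float(vals.std()),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        )
    return pd.DataFrame(rows, columns=["label", "count", "mean", "std", "min", "max"])
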