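"""Two-tensor + free-water tractography with an unscented Kalman filter.

Each streamline carries a local multi-fiber model that is recursively
re-estimated as the streamline advances: two axially symmetric tensor
compartments (unit direction, axial and radial diffusivity each) mixed
with equal weights, plus an isotropic free-water compartment with fixed
diffusivity ``d_iso``.  The normalized measurement model is

    S(g_i)/s0 = fw * exp(-b_i * d_iso)
                + (1 - fw) * 1/2 * [exp(-b_i g_i^T D1 g_i)
                                    + exp(-b_i g_i^T D2 g_i)]

with D_j = lperp_j * I + (lpar_j - lperp_j) * m_j m_j^T.  Tracking uses
the filter's prediction/update cycle against the interpolated signal at
each step and advances along the followed compartment's direction; in
crossing regions the second compartment absorbs the interfering bundle
so the followed direction is not deflected, which is what makes this
tracker traverse crossings that defeat single-tensor streamlining.

State vector layout (n = 11), eigenvalues kept in log-space so Kalman
updates cannot push them negative:

    [m1 (3), log lpar1, log lperp1, m2 (3), log lpar2, log lperp2, fw]

Directions are re-normalized and fw clipped to [0, 1] after every
update.  Sigma points are deterministic, so the tracker is fully
reproducible; randomness enters only through seeding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DWIVolume, GradientTable, Tractogram, matrix_to_tensor6, trilinear
from .tensor import design_matrix, fa_from_eigenvalues, tensor_eigensystem

__all__ = ["UKFState", "UKFParams", "predict_signal", "ukf_step", "track_ukf",
           "FilterDivergence"]

_EIG_FLOOR = 1e-6  # mm^2/s; hard floor for compartment eigenvalues
_EIG_CAP = 2.0e-3  # mm^2/s; tissue diffusivity cannot approach free water
_TISSUE_MD = 0.75e-3  # mm^2/s; typical parenchymal mean diffusivity (init prior)
_STATE_DIM = 11


class FilterDivergence(RuntimeError):
    """Raised when the state covariance cannot be repaired to positive
    definiteness (e.g. NaNs from a numerically broken update)."""


@dataclass
class UKFState:
    """Per-streamline two-tensor + free-water model state."""

    m1: np.ndarray
    l1_1: float  # lambda_parallel, compartment 1
    l2_1: float  # lambda_perp, compartment 1
    m2: np.ndarray
    l1_2: float
    l2_2: float
    fw: float

    def __post_init__(self) -> None:
        self.m1 = _unit(np.asarray(self.m1, float))
        self.m2 = _unit(np.asarray(self.m2, float))
        self.l1_1 = float(np.clip(self.l1_1, _EIG_FLOOR, _EIG_CAP))
        self.l2_1 = float(np.clip(self.l2_1, _EIG_FLOOR, _EIG_CAP))
        self.l1_2 = float(np.clip(self.l1_2, _EIG_FLOOR, _EIG_CAP))
        self.l2_2 = float(np.clip(self.l2_2, _EIG_FLOOR, _EIG_CAP))
        self.fw = float(np.clip(self.fw, 0.0, 1.0))

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [
                self.m1,
                [np.log(self.l1_1), np.log(self.l2_1)],
                self.m2,
                [np.log(self.l1_2), np.log(self.l2_2)],
                [self.fw],
            ]
        )

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "UKFState":
        x = np.asarray(x, float)
        return cls(
            m1=x[0:3],
            l1_1=np.exp(np.clip(x[3], np.log(_EIG_FLOOR), np.log(_EIG_CAP))),
            l2_1=np.exp(np.clip(x[4], np.log(_EIG_FLOOR), np.log(_EIG_CAP))),
            m2=x[5:8],
            l1_2=np.exp(np.clip(x[8], np.log(_EIG_FLOOR), np.log(_EIG_CAP))),
            l2_2=np.exp(np.clip(x[9], np.log(_EIG_FLOOR), np.log(_EIG_CAP))),
            fw=x[10],
        )

    def compartment(self, idx: int) -> tuple[np.ndarray, float, float]:
        if idx == 0:
            return self.m1, self.l1_1, self.l2_1
        return self.m2, self.l1_2, self.l2_2

    def compartment_fa(self, idx: int) -> float:
        _, lpar, lperp = self.compartment(idx)
        return float(fa_from_eigenvalues(np.array([lpar, lperp, lperp])))


@dataclass
class UKFParams:
    """Filter and tracking parameters.

    ``q_dir``/``q_eig``/``q_fw`` are the diagonal process-noise entries
    for direction, log-eigenvalue and free-water state components; ``r``
    is the measurement-noise variance on the s0-normalized signal.
    ``p0_*`` set the initial state uncertainty, which governs how fast
    the filter can move away from its single-tensor initialization.
    """

    q_dir: float = 1e-8
    q_eig: float = 1e-8
    q_fw: float = 1e-6
    r: float = 0.02
    p0_dir: float = 0.01
    p0_eig: float = 1e-4
    p0_fw: float = 0.1
    sigma_alpha: float = 0.001
    sigma_beta: float = 2.0
    sigma_kappa: float = 0.0
    d_iso: float = 3.0e-3
    step_mm: float = 0.5
    fa_stop: float = 0.15
    angle_stop_deg: float = 45.0
    min_length_mm: float = 10.0
    max_length_mm: float = 250.0
    init_fw: float = 0.1
    seeds_per_voxel: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.q_dir, self.q_eig, self.q_fw) <= 0 or self.r <= 0:
            raise ValueError("process/measurement noise must be > 0")
        if self.d_iso <= 0:
            raise ValueError("d_iso must be > 0")

    def q_diag(self) -> np.ndarray:
        q = np.empty(_STATE_DIM)
        q[[0, 1, 2, 5, 6, 7]] = self.q_dir
        q[[3, 4, 8, 9]] = self.q_eig
        q[10] = self.q_fw
        return q

    def p0_diag(self) -> np.ndarray:
        p = np.empty(_STATE_DIM)
        p[[0, 1, 2, 5, 6, 7]] = self.p0_dir
        p[[3, 4, 8, 9]] = self.p0_eig
        p[10] = self.p0_fw
        return p


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        return np.array([1.0, 0.0, 0.0])
    return v / n


# --------------------------------------------------------------------------
# measurement model

def predict_signal(
    s: UKFState, g: GradientTable, s0: float = 1.0, d_iso: float = 3.0e-3
) -> np.ndarray:
    """Model signal for every gradient; baselines (b=0) return s0."""
    x = s.to_vector()[None, :]
    return s0 * _predict_normalized(x, g.bvals, g.bvecs, d_iso)[0]


def _predict_normalized(
    X: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray, d_iso: float
) -> np.ndarray:
    """Vectorized normalized measurement model.

    X is (n_sigma, 11) in state-vector layout; returns (n_sigma, G).
    """
    m1 = X[:, 0:3]
    m2 = X[:, 5:8]
    n1 = np.linalg.norm(m1, axis=1, keepdims=True)
    n2 = np.linalg.norm(m2, axis=1, keepdims=True)
    m1 = np.where(n1 > 1e-12, m1 / np.maximum(n1, 1e-300), [[1.0, 0.0, 0.0]])
    m2 = np.where(n2 > 1e-12, m2 / np.maximum(n2, 1e-300), [[1.0, 0.0, 0.0]])
    lo, hi = np.log(_EIG_FLOOR), np.log(_EIG_CAP)
    lpar1 = np.exp(np.clip(X[:, 3], lo, hi))
    lperp1 = np.exp(np.clip(X[:, 4], lo, hi))
    lpar2 = np.exp(np.clip(X[:, 8], lo, hi))
    lperp2 = np.exp(np.clip(X[:, 9], lo, hi))
    fw = np.clip(X[:, 10:11], 0.0, 1.0)

    dot1 = m1 @ bvecs.T  # (n_sigma, G)
    dot2 = m2 @ bvecs.T
    q1 = lperp1[:, None] + (lpar1 - lperp1)[:, None] * dot1**2
    q2 = lperp2[:, None] + (lpar2 - lperp2)[:, None] * dot2**2
    b = bvals[None, :]
    tissue = 0.5 * (np.exp(-b * q1) + np.exp(-b * q2))
    return fw * np.exp(-b * d_iso) + (1.0 - fw) * tissue


# --------------------------------------------------------------------------
# unscented transform machinery

def _sigma_points(x: np.ndarray, P: np.ndarray, p: UKFParams):
    n = len(x)
    lam = p.sigma_alpha**2 * (n + p.sigma_kappa) - n
    c = n + lam
    try:
        L = np.linalg.cholesky(c * P)
    except np.linalg.LinAlgError:
        P = _repair_pd(P)
        L = np.linalg.cholesky(c * P)
    pts = np.empty((2 * n + 1, n))
    pts[0] = x
    pts[1 : n + 1] = x[None, :] + L.T
    pts[n + 1 :] = x[None, :] - L.T
    wm = np.full(2 * n + 1, 1.0 / (2 * c))
    wc = wm.copy()
    wm[0] = lam / c
    wc[0] = lam / c + (1 - p.sigma_alpha**2 + p.sigma_beta)
    return pts, wm, wc


def _repair_pd(P: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    """Symmetrize and floor the eigenvalues of a covariance."""
    if not np.all(np.isfinite(P)):
        raise FilterDivergence("filter divergence")
    P = 0.5 * (P + P.T)
    w, V = np.linalg.eigh(P)
    if w.min() < floor:
        w = np.clip(w, floor, None)
        P = V @ np.diag(w) @ V.T
        P = 0.5 * (P + P.T)
    return P


def ukf_step(
    s: UKFState,
    P: np.ndarray,
    z: np.ndarray,
    g: GradientTable,
    s0: float,
    p: UKFParams,
) -> tuple[UKFState, np.ndarray]:
    """One predict/update cycle against a measured signal vector ``z``.

    The state transition is the identity plus process noise Q; the
    measurement is the s0-normalized model signal.  The returned state is
    re-normalized (unit directions, fw in [0,1], eigenvalues floored) and
    the covariance symmetrized and floored to stay positive definite.
    """
    x = s.to_vector()
    P_pred = _repair_pd(np.asarray(P, float) + np.diag(p.q_diag()))

    pts, wm, wc = _sigma_points(x, P_pred, p)
    Z = _predict_normalized(pts, g.bvals, g.bvecs, p.d_iso)  # (2n+1, G)
    z_mean = wm @ Z
    dZ = Z - z_mean
    dX = pts - x
    S = (dZ.T * wc) @ dZ + p.r * np.eye(Z.shape[1])
    C = (dX.T * wc) @ dZ
    K = np.linalg.solve(S.T, C.T).T  # C @ inv(S)

    z_norm = np.asarray(z, float) / max(float(s0), 1e-300)
    x_new = x + K @ (z_norm - z_mean)
    P_new = P_pred - K @ S @ K.T
    P_new = _repair_pd(P_new)
    if not np.all(np.isfinite(x_new)):
        raise FilterDivergence("filter divergence")
    return UKFState.from_vector(x_new), P_new


# --------------------------------------------------------------------------
# tracking

class _SignalField:
    """Interpolated access to the 4D signal and its baseline."""

    def __init__(self, dwi: DWIVolume):
        self.data = dwi.data
        self.s0_vol = dwi.s0()
        self.mask = (self.s0_vol > 0).astype(np.float64)
        self.shape3 = np.asarray(dwi.shape3, dtype=float)
        inv = np.linalg.inv(dwi.affine)
        self._R = inv[:3, :3]
        self._t = inv[:3, 3]

    def to_index(self, x_world):
        return self._R @ x_world + self._t

    def in_grid(self, idx) -> bool:
        return bool(np.all(idx >= 0) and np.all(idx <= self.shape3 - 1))

    def sample(self, idx) -> tuple[np.ndarray, float]:
        return trilinear(self.data, idx), trilinear(self.s0_vol, idx)


def _init_state(
    field: _SignalField, idx: np.ndarray, gt: GradientTable, p: UKFParams
) -> UKFState | None:
    """Free-water-corrected single-tensor fit at the seed.

    A single shell cannot separate free water from inflated tissue
    diffusivities in a plain log-linear fit (the fitted tensor absorbs
    the isotropic excess), so the initializer grid-searches the water
    fraction under the standard single-shell constraint that the tissue
    compartment's mean diffusivity equals a typical parenchymal value:
    for each candidate fw the isotropic compartment is subtracted from
    the normalized attenuations, a tensor is refit on the corrected
    attenuations, rescaled to the fixed tissue MD, and the candidate
    minimizing the composite-model residual wins.  Both compartments
    start with the corrected tensor's eigenvalues; directions come from
    its first two eigenvectors.
    """
    sig, s0 = field.sample(idx)
    if s0 <= 0 or np.any(sig <= 0):
        return None
    # average the signal over a small ball (seed +/- 1 voxel-ish) so the
    # initialization is not at the mercy of a single voxel's noise
    sigs, s0s = [sig], [s0]
    for off in np.vstack([np.eye(3), -np.eye(3)]):
        j = idx + off * 0.5
        if field.in_grid(j):
            si, s0i = field.sample(j)
            if s0i > 0 and np.all(si > 0):
                sigs.append(si)
                s0s.append(s0i)
    sig = np.mean(sigs, axis=0)
    s0 = float(np.mean(s0s))
    X = design_matrix(gt.bvals, gt.bvecs)
    pinv = np.linalg.pinv(X)
    A = sig / s0
    A_iso = np.exp(-gt.bvals * p.d_iso)
    best: tuple | None = None
    for fw in np.linspace(0.0, 0.95, 39):
        At = np.clip((A - fw * A_iso) / (1.0 - fw), 1e-6, None)
        beta = pinv @ np.log(At)
        w, V = tensor_eigensystem(beta[None, :6])
        w = np.clip(w[0], _EIG_FLOOR, None)
        w = np.clip(w * (3.0 * _TISSUE_MD / w.sum()), 0.0, _EIG_CAP)
        V = V[0]
        t6 = matrix_to_tensor6(V @ np.diag(w) @ V.T)
        pred = fw * A_iso + (1.0 - fw) * np.exp(X[:, :6] @ t6)
        resid = float(np.sum((pred - A) ** 2))
        if best is None or resid < best[0]:
            best = (resid, fw, w, V)
    _, fw0, w, V = best
    # compartment 2 follows the second eigenvector with the second/third
    # eigenvalues, so in single-fiber voxels its FA is ~0 and the second
    # branch is not spawned; in crossing voxels the fitted tensor is
    # oblate and both compartments start anisotropic
    return UKFState(
        m1=V[:, 0],
        l1_1=max(w[0], _EIG_FLOOR),
        l2_1=max(0.5 * (w[1] + w[2]), _EIG_FLOOR),
        m2=V[:, 1],
        l1_2=max(w[1], _EIG_FLOOR),
        l2_2=max(w[2], _EIG_FLOOR),
        fw=fw0 if p.init_fw is None else max(fw0, p.init_fw),
    )


def _track_branch(
    field: _SignalField,
    gt: GradientTable,
    seed: np.ndarray,
    state0: UKFState,
    P0: np.ndarray,
    follow: int,
    direction0: np.ndarray,
    p: UKFParams,
) -> tuple[list[np.ndarray], list[float], list[float]]:
    """One half-track of one compartment branch (seed excluded)."""
    pts: list[np.ndarray] = []
    fws: list[float] = []
    fas: list[float] = []
    x = seed.copy()
    d = _unit(direction0.copy())
    state, P = state0, P0.copy()
    cos_stop = np.cos(np.deg2rad(p.angle_stop_deg))
    n_max = int(np.floor(p.max_length_mm / 2.0 / p.step_mm))
    for _ in range(n_max):
        x_new = x + d * p.step_mm
        idx = field.to_index(x_new)
        if not field.in_grid(idx) or trilinear(field.mask, idx) < 0.5:
            break
        sig, s0 = field.sample(idx)
        if s0 <= 0:
            break
        try:
            state, P = ukf_step(state, P, sig, gt, s0, p)
        except FilterDivergence:
            break
        m, _, _ = state.compartment(follow)
        if np.dot(m, d) < 0:
            m = -m
        if state.compartment_fa(follow) < p.fa_stop:
            break
        if float(np.dot(m, d)) < cos_stop:
            break
        pts.append(x_new)
        fws.append(state.fw)
        fas.append(state.compartment_fa(follow))
        x = x_new
        d = m
    return pts, fws, fas


def track_ukf(
    dwi: DWIVolume, seeds: np.ndarray, p: UKFParams | None = None
) -> Tractogram:
    """UKF tractography: two streamlines per seed, one per compartment.

    Each streamline carries per-point scalars ``fw`` (free-water
    fraction) and ``fa_compartment`` (FA of the followed compartment's
    axially symmetric tensor).  Seeds outside the grid/brain mask are
    skipped; the count is attached as ``n_skipped_seeds``.
    """
    if p is None:
        p = UKFParams()
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    field = _SignalField(dwi)
    gt = dwi.gradients
    P0 = np.diag(p.p0_diag())

    streamlines: list[np.ndarray] = []
    fw_arrays: list[np.ndarray] = []
    fa_arrays: list[np.ndarray] = []
    n_skipped = 0
    for seed in seeds:
        idx = field.to_index(seed)
        if not field.in_grid(idx) or trilinear(field.mask, idx) < 0.5:
            n_skipped += 1
            continue
        state0 = _init_state(field, idx, gt, p)
        if state0 is None:
            n_skipped += 1
            continue
        for follow in (0, 1):
            m0, _, _ = state0.compartment(follow)
            if state0.compartment_fa(follow) < p.fa_stop:
                continue
            fwd = _track_branch(field, gt, seed, state0, P0, follow, m0, p)
            bwd = _track_branch(field, gt, seed, state0, P0, follow, -m0, p)
            pts = bwd[0][::-1] + [seed] + fwd[0]
            if len(pts) < 2:
                continue
            arr = np.asarray(pts)
            if np.linalg.norm(np.diff(arr, axis=0), axis=1).sum() < p.min_length_mm:
                continue
            streamlines.append(arr)
            fw_arrays.append(
                np.asarray(bwd[1][::-1] + [state0.fw] + fwd[1])
            )
            fa_arrays.append(
                np.asarray(bwd[2][::-1] + [state0.compartment_fa(follow)] + fwd[2])
            )

    t = Tractogram(
        streamlines=streamlines,
        per_point_scalars={"fw": fw_arrays, "fa_compartment": fa_arrays},
        reference_affine=dwi.affine,
    )
    t.n_skipped_seeds = n_skipped  # type: ignore[attr-defined]
    return t
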