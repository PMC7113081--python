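"""Tensor estimation against an independent forward simulator, and
closed-form checks of the derived scalar maps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmrikit.core import (
    DWIVolume,
    GradientTable,
    LabelMap,
    ScalarVolume,
    matrix_to_tensor6,
    tensor6_to_matrix,
)
from dmrikit.phantom import spiral_directions
from dmrikit.tensor import (
    dec_map,
    fa_from_eigenvalues,
    fa_map,
    fit_tensors,
    md_map,
    probe_scalar,
    roi_statistics,
)

# ---------------------------------------------------------------------------
# independent forward simulator (oracle): synthesize signals directly from
# the monoexponential model without touching the fitting code


def _simulate(D_list, bvals, bvecs, s0=1000.0):
    """Signals for a list of tensors; one voxel per tensor, in a row."""
    n = len(D_list)
    data = np.zeros((n, 1, 1, len(bvals)))
    for i, D in enumerate(D_list):
        quad = np.einsum("gi,ij,gj->g", bvecs, D, bvecs)
        data[i, 0, 0] = s0 * np.exp(-bvals * quad)
    gt = GradientTable(bvals=bvals, bvecs=bvecs)
    return DWIVolume(data=data, affine=np.eye(4), gradients=gt)


def _random_spd(rng, scale=1e-3):
    A = rng.normal(size=(3, 3))
    evals = rng.uniform(0.1, 2.5, 3) * scale
    Q, _ = np.linalg.qr(A)
    return Q @ np.diag(evals) @ Q.T


def _acquisition(n_dirs=12, n_b0=1, bval=1000.0):
    bvals = np.r_[np.zeros(n_b0), np.full(n_dirs, bval)]
    bvecs = np.r_[np.zeros((n_b0, 3)), spiral_directions(n_dirs)]
    return bvals, bvecs


@pytest.mark.parametrize("method", ["lls", "wls"])
def test_noiseless_fit_recovers_random_tensors(rng, method):
    """Simulate -> fit recovers 100 random SPD tensors to <=1e-9 mm^2/s."""
    bvals, bvecs = _acquisition()
    D_list = [_random_spd(rng) for _ in range(100)]
    dwi = _simulate(D_list, bvals, bvecs)
    tv = fit_tensors(dwi, method=method)
    fitted = tensor6_to_matrix(tv.tensors[:, 0, 0])
    for D, F in zip(D_list, fitted):
        assert np.abs(F - D).max() <= 1e-9


def test_wls_equals_lls_on_noiseless_data(rng):
    bvals, bvecs = _acquisition()
    D_list = [_random_spd(rng) for _ in range(10)]
    dwi = _simulate(D_list, bvals, bvecs)
    t_lls = fit_tensors(dwi, method="lls")
    t_wls = fit_tensors(dwi, method="wls")
    assert np.allclose(t_lls.tensors, t_wls.tensors, atol=1e-12)


def test_isotropic_voxel_recovered_isotropic(rng):
    bvals, bvecs = _acquisition()
    D = 0.7e-3 * np.eye(3)
    dwi = _simulate([D], bvals, bvecs)
    tv = fit_tensors(dwi)
    assert np.abs(tensor6_to_matrix(tv.tensors[0, 0, 0]) - D).max() <= 1e-9


def test_underdetermined_acquisition_rejected(rng):
    bvals, bvecs = _acquisition(n_dirs=5)
    dwi = _simulate([0.7e-3 * np.eye(3)], bvals, bvecs)
    with pytest.raises(ValueError, match="underdetermined"):
        fit_tensors(dwi)


def test_all_zero_voxel_dropped_from_mask():
    bvals, bvecs = _acquisition()
    dwi = _simulate([1e-3 * np.eye(3), 1e-3 * np.eye(3)], bvals, bvecs)
    dwi.data[1] = 0.0
    tv = fit_tensors(dwi)
    assert tv.mask[0, 0, 0]
    assert not tv.mask[1, 0, 0]
    assert np.all(tv.tensors[1, 0, 0] == 0)


# ---------------------------------------------------------------------------
# scalar maps: closed forms


def _single_tensor_volume(D):
    t6 = np.zeros((1, 1, 1, 6))
    t6[0, 0, 0] = matrix_to_tensor6(D)
    return fa_map, t6


def _tv_of(D_list):
    from dmrikit.core import TensorVolume

    n = len(D_list)
    t6 = np.zeros((n, 1, 1, 6))
    for i, D in enumerate(D_list):
        t6[i, 0, 0] = matrix_to_tensor6(np.asarray(D))
    return TensorVolume(
        tensors=t6,
        s0=np.ones((n, 1, 1)),
        affine=np.eye(4),
        mask=np.ones((n, 1, 1), bool),
    )


def test_fa_closed_forms():
    tv = _tv_of(
        [
            0.7e-3 * np.eye(3),  # isotropic -> 0
            np.diag([1.3e-3, 0.0, 0.0]),  # stick -> 1
            np.diag([1.7e-3, 0.3e-3, 0.3e-3]),
        ]
    )
    fa = fa_map(tv).data[:, 0, 0]
    assert fa[0] == pytest.approx(0.0, abs=1e-12)
    assert fa[1] == pytest.approx(1.0, abs=1e-12)
    # closed form: sqrt(3/2)*sqrt(sum (l-lb)^2)/sqrt(sum l^2) evaluated by hand
    lam = np.array([1.7e-3, 0.3e-3, 0.3e-3])
    expect = np.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / np.linalg.norm(lam)
    assert fa[2] == pytest.approx(expect, abs=1e-12)
    assert expect == pytest.approx(0.799, abs=1e-3)


def test_md_closed_forms():
    tv = _tv_of(
        [np.diag([1.7e-3, 0.3e-3, 0.3e-3]), np.zeros((3, 3)), 0.9e-3 * np.eye(3)]
    )
    md = md_map(tv).data[:, 0, 0]
    assert md[0] == pytest.approx((1.7e-3 + 0.3e-3 + 0.3e-3) / 3, rel=1e-12)
    assert md[1] == 0.0
    assert md[2] == pytest.approx(0.9e-3, rel=1e-12)


def test_fa_rotation_invariance(rng):
    """FA and MD are rotation invariants of the tensor (1000 rotations)."""
    lam = np.diag([1.7e-3, 0.5e-3, 0.2e-3])
    base_fa = fa_map(_tv_of([lam])).data[0, 0, 0]
    base_md = md_map(_tv_of([lam])).data[0, 0, 0]
    Ds = []
    for _ in range(1000):
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        Ds.append(Q @ lam @ Q.T)
    tv = _tv_of(Ds)
    assert np.abs(fa_map(tv).data[:, 0, 0] - base_fa).max() < 1e-10
    assert np.abs(md_map(tv).data[:, 0, 0] - base_md).max() < 1e-10


@given(scale=st.floats(min_value=0.1, max_value=10.0))
def test_md_scales_linearly(scale):
    D = np.diag([1.7e-3, 0.5e-3, 0.2e-3])
    md1 = md_map(_tv_of([D])).data[0, 0, 0]
    md2 = md_map(_tv_of([scale * D])).data[0, 0, 0]
    assert md2 == pytest.approx(scale * md1, rel=1e-9)


def test_dec_map_axis_aligned():
    tv = _tv_of([np.diag([1.7e-3, 0.3e-3, 0.3e-3]), 0.7e-3 * np.eye(3)])
    rgb = dec_map(tv).data
    fa = fa_map(tv).data[0, 0, 0]
    assert np.allclose(rgb[0, 0, 0], [fa, 0, 0], atol=1e-9)  # +x -> red
    assert np.allclose(rgb[1, 0, 0], [0, 0, 0], atol=1e-9)  # isotropic -> black


def test_dec_map_oblique_axis():
    e = np.array([1.0, 1.0, 0.0]) / np.sqrt(2)
    D = 1.0e-3 * np.outer(e, e)  # stick along (1,1,0): FA = 1
    rgb = dec_map(_tv_of([D])).data[0, 0, 0]
    assert np.allclose(rgb, [np.sqrt(0.5), np.sqrt(0.5), 0.0], atol=1e-9)


# ---------------------------------------------------------------------------
# probing and ROI statistics


def _ramp_volume():
    data = np.zeros((5, 4, 4))
    data[:] = np.arange(5)[:, None, None] * 0.2
    return ScalarVolume(data=data, affine=np.eye(4), name="ramp")


def test_probe_voxel_center_both_modes():
    sv = _ramp_volume()
    for interp in ("nearest", "trilinear"):
        assert probe_scalar(sv, [2, 1, 1], interp) == pytest.approx(0.4, abs=1e-12)


def test_probe_midway_trilinear():
    sv = _ramp_volume()
    # midway between centers with values 0.2 and 0.6 -> 0.4
    assert probe_scalar(sv, [2.0, 2.0, 2.0], "trilinear") == pytest.approx(0.4)
    sv2 = ScalarVolume(data=np.zeros((2, 1, 1)), affine=np.eye(4))
    sv2.data[0, 0, 0], sv2.data[1, 0, 0] = 0.2, 0.6
    assert probe_scalar(sv2, [0.5, 0, 0], "trilinear") == pytest.approx(0.4)


def test_probe_out_of_bounds():
    sv = _ramp_volume()
    with pytest.raises(ValueError, match="out of bounds"):
        probe_scalar(sv, [40.0, 0.0, 0.0])


def test_roi_statistics_arithmetic():
    data = np.zeros((4, 1, 1))
    data[:, 0, 0] = [0.2, 0.4, 0.6, 0.8]
    sv = ScalarVolume(data=data, affine=np.eye(4))
    roi = LabelMap(data=np.ones((4, 1, 1), dtype=np.int32), affine=np.eye(4))
    df = roi_statistics(sv, roi)
    row = df.iloc[0]
    assert row["count"] == 4
    assert row["mean"] == pytest.approx(0.5)
    assert row["min"] == pytest.approx(0.2)
    assert row["max"] == pytest.approx(0.8)


def test_roi_statistics_two_labels_and_single_voxel():
    data = np.zeros((4, 1, 1))
    data[:, 0, 0] = [0.1, 0.3, 0.5, 0.7]
    sv = ScalarVolume(data=data, affine=np.eye(4))
    labels = np.zeros((4, 1, 1), dtype=np.int32)
    labels[0, 0, 0] = 1
    labels[2:, 0, 0] = 2
    df = roi_statistics(sv, LabelMap(data=labels, affine=np.eye(4)))
    assert len(df) == 2
    one = df[df.label == 1].iloc[0]
    assert one["mean"] == pytest.approx(0.1)
    assert one["std"] == 0.0
    two = df[df.label == 2].iloc[0]
    assert two["count"] == 2
    assert two["mean"] == pytest.approx(0.6)


def test_roi_statistics_empty():
    sv = ScalarVolume(data=np.zeros((2, 2, 2)), affine=np.eye(4))
    roi = LabelMap(data=np.zeros((2, 2, 2), dtype=np.int32), affine=np.eye(4))
    assert roi_statistics(sv, roi).empty


def test_fa_from_eigenvalues_bounds(rng):
    lam = rng.uniform(0, 3e-3, size=(500, 3))
    fa = fa_from_eigenvalues(lam)
    assert np.all(fa >= 0) and np.all(fa <= 1)
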