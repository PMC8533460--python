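"""Fiducial-based affine solve, decomposition, mapping and resampling."""

import json

import numpy as np
import pytest
from skimage.transform import AffineTransform as SkAffine

from nanoclem.image import RasterImage
from nanoclem.registration import (
    AffineTransform,
    DegenerateGeometryError,
    FiducialSet,
    InsufficientFiducialsError,
    map_points,
    resample_image,
    solve_transform,
)

TRIANGLE = np.array([[0.0, 0.0], [1000.0, 0.0], [200.0, 800.0]])


def test_identity_from_coincident_points():
    fids = FiducialSet(TRIANGLE, TRIANGLE)
    T = solve_transform(fids)
    dec = T.decomposition
    assert np.allclose(T.matrix, np.eye(2), atol=1e-12)
    assert np.allclose(T.translation, 0, atol=1e-9)
    assert abs(dec["rotation_rad"]) < 1e-12
    assert np.allclose(dec["scale"], 1.0)
    assert fids.fre_nm < 1e-9


def test_pure_translation_recovered():
    fids = FiducialSet(TRIANGLE, TRIANGLE + [5.0, 7.0])
    T = solve_transform(fids)
    assert np.allclose(T.translation, [5.0, 7.0], atol=1e-9)
    assert np.allclose(T.matrix, np.eye(2), atol=1e-12)


def test_three_point_solve_recovers_generating_parameters():
    # forward-generate targets from stated parameters, recover them exactly
    truth = AffineTransform.from_params(
        rotation_rad=np.deg2rad(30.0), scale=(1.2, 0.8), translation_nm=(10.0, -4.0)
    )
    fids = FiducialSet(TRIANGLE, truth.apply(TRIANGLE))
    T = solve_transform(fids)
    dec = T.decomposition
    assert abs(dec["rotation_rad"] - np.deg2rad(30)) < 1e-9
    assert np.allclose(dec["scale"], (1.2, 0.8), atol=1e-9)
    assert abs(dec["shear_rad"]) < 1e-9
    assert np.allclose(dec["translation_nm"], (10.0, -4.0), atol=1e-9)
    assert fids.fre_nm < 1e-6


@pytest.mark.parametrize("seed", range(20))
def test_three_point_exactness_random(seed):
    rng = np.random.default_rng(seed)
    src = rng.uniform(0, 20000, (3, 2))
    truth = AffineTransform.from_params(
        rotation_rad=rng.uniform(-0.5, 0.5),
        scale=tuple(rng.uniform(0.8, 1.2, 2)),
        translation_nm=tuple(rng.uniform(-500, 500, 2)),
    )
    fids = FiducialSet(src, truth.apply(src))
    solve_transform(fids)
    assert fids.fre_nm < 1e-6


def test_overdetermined_consistent_equals_three_point():
    truth = AffineTransform.from_params(0.1, (1.05, 0.95), (30.0, -20.0))
    src6 = np.vstack([TRIANGLE, TRIANGLE + [3000.0, 4000.0]])
    T3 = solve_transform(FiducialSet(TRIANGLE, truth.apply(TRIANGLE)))
    T6 = solve_transform(FiducialSet(src6, truth.apply(src6)))
    assert np.allclose(T3.matrix, T6.matrix, atol=1e-9)
    assert np.allclose(T3.translation, T6.translation, atol=1e-6)


def test_least_squares_matches_normal_equations_oracle():
    # independent route: solve the normal equations explicitly
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = rng.integers(4, 12)
        src = rng.uniform(0, 10000, (n, 2))
        dst = rng.uniform(0, 10000, (n, 2))
        fids = FiducialSet(src, dst)
        T = solve_transform(fids)
        X = np.column_stack([src, np.ones(n)])
        beta = np.linalg.solve(X.T @ X, X.T @ dst)
        assert np.allclose(T.matrix, beta[:2].T, atol=1e-9)
        assert np.allclose(T.translation, beta[2], atol=1e-9)


def test_solve_matches_skimage_estimator():
    # independent implementation cross-check on noisy but affine-shaped data
    rng = np.random.default_rng(11)
    truth = AffineTransform.from_params(0.1, (1.1, 0.9), (50.0, -30.0))
    src = rng.uniform(0, 10000, (6, 2))
    dst = truth.apply(src) + rng.normal(0, 5, (6, 2))
    T = solve_transform(FiducialSet(src, dst))
    sk = SkAffine.from_estimate(src, dst)
    assert np.allclose(T.matrix, sk.params[:2, :2], atol=1e-6)
    assert np.allclose(T.translation, sk.params[:2, 2], atol=1e-2)


def test_translation_error_scales_with_fiducial_noise():
    truth = AffineTransform.from_params(0.05, (1.02, 0.98), (100.0, -50.0))
    rng = np.random.default_rng(3)
    src = rng.uniform(0, 20000, (6, 2))
    dst = truth.apply(src)
    mean_err = {}
    for sigma in (1.0, 2.0, 4.0):
        errs = []
        for _ in range(300):
            noisy = dst + rng.normal(0, sigma, dst.shape)
            T = solve_transform(FiducialSet(src, noisy))
            errs.append(np.linalg.norm(T.translation - truth.translation))
        mean_err[sigma] = np.mean(errs)
    # error grows ~ linearly in sigma
    assert 1.6 < mean_err[2.0] / mean_err[1.0] < 2.4
    assert 1.6 < mean_err[4.0] / mean_err[2.0] < 2.4


def test_insufficient_and_degenerate_fiducials():
    with pytest.raises(InsufficientFiducialsError):
        FiducialSet(TRIANGLE[:2], TRIANGLE[:2])
    collinear = np.array([[0.0, 0.0], [500.0, 500.0], [1000.0, 1000.0]])
    with pytest.raises(DegenerateGeometryError):
        solve_transform(FiducialSet(collinear, collinear))


def test_map_points_inverse_roundtrip():
    T = AffineTransform.from_params(0.3, (1.1, 0.9), (123.0, -45.0))
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 30000, (100, 2))
    back = map_points(T.inverse(), map_points(T, pts))
    assert np.max(np.abs(back - pts)) < 1e-9


def test_compose_with_inverse_is_identity():
    T = AffineTransform.from_params(-0.2, (0.8, 1.3), (10.0, 20.0))
    I = T.compose(T.inverse())
    pts = np.random.default_rng(1).uniform(0, 20000, (50, 2))
    assert np.max(np.abs(I.apply(pts) - pts)) < 1e-9


def test_map_points_rejects_nonfinite():
    with pytest.raises(ValueError):
        map_points(AffineTransform.identity(), np.array([[np.nan, 0.0]]))


def test_truth_fixture_geometric_consistency(pair100):
    _, _, _, truth = pair100
    p = truth.particles
    mapped = map_points(
        truth.transform, p[["x_esem_nm", "y_esem_nm"]].to_numpy()
    )
    err = np.abs(mapped - p[["x_tirf_nm", "y_tirf_nm"]].to_numpy())
    assert err.max() < 1e-9


def test_shear_warning():
    T = AffineTransform.from_params(0.0, (1.0, 1.0), (0.0, 0.0), shear_rad=0.1)
    with pytest.warns(UserWarning, match="shear"):
        T.decomposition


def test_json_roundtrip(tmp_path):
    T = AffineTransform.from_params(0.2, (1.1, 0.95), (5.0, -3.0))
    path = tmp_path / "t.json"
    T.to_json(path)
    T2 = AffineTransform.from_json(path)
    assert np.allclose(T.matrix, T2.matrix)
    assert np.allclose(T.translation, T2.translation)
    with open(path) as fh:
        assert json.load(fh)["units"] == "nm"


# -- resampling ------------------------------------------------------------

def _smooth_image(shape=(64, 64), px=60.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    data = 100 + 50 * np.sin(2 * np.pi * cc / 32) * np.cos(2 * np.pi * rr / 32)
    return RasterImage(data, px, "tirf")


def test_resample_identity_is_exact():
    img = _smooth_image()
    out = resample_image(AffineTransform.identity(), img, img.shape, 60.0)
    assert np.allclose(out.data, img.data, atol=1e-9)


def test_resample_integer_translation_shifts_exactly():
    img = _smooth_image()
    T = AffineTransform.from_params(translation_nm=(120.0, 0.0))  # +2 columns
    out = resample_image(T, img, img.shape, 60.0, fill_value=np.nan)
    assert np.allclose(out.data[:, 2:], img.data[:, :-2], atol=1e-9)
    assert np.isnan(out.data[:, :2]).all()


def test_resample_roundtrip_within_interpolation_tolerance():
    img = _smooth_image((96, 96))
    T = AffineTransform.from_params(0.15, (1.05, 0.95), (37.0, -21.0))
    fwd = resample_image(T, img, (120, 120), 60.0, fill_value=np.nan)
    back = resample_image(T.inverse(), fwd, img.shape, 60.0, fill_value=np.nan)
    valid = ~np.isnan(back.data)
    # crop the border where fill values bleed in
    core = np.zeros_like(valid)
    core[8:-8, 8:-8] = True
    sel = valid & core
    err = np.abs(back.data[sel] - img.data[sel])
    assert err.max() < 0.02 * np.ptp(img.data)


def test_resample_degenerate_transform_raises():
    img = _smooth_image((16, 16))
    with pytest.raises(DegenerateGeometryError):
        AffineTransform(np.array([[1.0, 0.0], [1.0, 0.0]]), np.zeros(2))
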