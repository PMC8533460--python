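"""Synthetic generator: determinism, truth-table invariants, calibration."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nanoclem.registration import AffineTransform
from nanoclem.simulate import (
    BACKGROUND_ID,
    ConfigurationError,
    SimulationConfig,
    calibrate_truncated_nb,
    load_fixture,
    noiseless_spot_image,
    sample_truncated_nb,
    simulate_disk_field,
    simulate_pair,
    simulate_tirf,
    truncated_nb_mean,
    write_fixture,
)
from nanoclem.spots import detect_and_measure

SMALL = dict(field_nm=(10000.0, 10000.0), n_domains=8, seed=3)


def test_empty_configuration_gives_pure_noise_and_empty_tables():
    config = SimulationConfig(
        field_nm=(6000.0, 6000.0), n_domains=0, background_particle_density=0.0, seed=0
    )
    tirf, esem, truth = simulate_pair(config)
    assert truth.domains.empty and truth.particles.empty
    # noise only: TIRF fluctuates around the photon baseline
    assert 0 < tirf.data.mean() < 20
    assert np.ptp(esem.data) > 0  # gaussian noise present, no structure


def test_seed_determinism_is_bitwise():
    config = SimulationConfig(**SMALL)
    a = simulate_pair(config)
    b = simulate_pair(SimulationConfig(**SMALL))
    assert np.array_equal(a[0].data, b[0].data)
    assert np.array_equal(a[1].data, b[1].data)
    pd.testing.assert_frame_equal(a[2].domains, b[2].domains)
    pd.testing.assert_frame_equal(a[2].particles, b[2].particles)


def test_different_seed_changes_output():
    a = simulate_pair(SimulationConfig(**SMALL))
    b = simulate_pair(SimulationConfig(**{**SMALL, "seed": 4}))
    assert not np.array_equal(a[0].data, b[0].data)


def test_simulate_tirf_matches_pair_at_same_seed():
    config = SimulationConfig(**SMALL)
    tirf_only, truth_only = simulate_tirf(config)
    tirf_pair, _, truth_pair = simulate_pair(config)
    assert np.array_equal(tirf_only.data, tirf_pair.data)
    pd.testing.assert_frame_equal(truth_only.domains, truth_pair.domains)


# -- truncated negative-binomial counts ------------------------------------

def test_truncated_nb_calibration_closed_form():
    m0 = calibrate_truncated_nb(5.0, 2.0)
    assert m0 < 5.0
    assert truncated_nb_mean(m0, 2.0) == pytest.approx(5.0, abs=1e-9)


@pytest.mark.parametrize("dispersion", [0.5, 2.0, 50.0])
def test_truncated_nb_sample_calibration(dispersion):
    # oracle: the calibrated truncated distribution has mean exactly 5;
    # check the sampler against analytic mean and variance
    rng = np.random.default_rng(0)
    x = sample_truncated_nb(rng, 5000, 5.0, dispersion)
    assert x.min() >= 1
    m0 = calibrate_truncated_nb(5.0, dispersion)
    p = dispersion / (dispersion + m0)
    p0 = p**dispersion
    # analytic moments of the >=1-truncated law
    ex2_untrunc = m0 + m0**2 / dispersion + m0**2  # E[X^2] = var + mean^2
    var_trunc = ex2_untrunc / (1 - p0) - 5.0**2
    se = np.sqrt(var_trunc / len(x))
    assert abs(x.mean() - 5.0) < 3 * se
    assert x.var() == pytest.approx(var_trunc, rel=0.15)


def test_truth_count_mean_calibrated_at_500_domains():
    # per-domain counts in the truth table at n_domains >= 500
    rng = np.random.default_rng(1)
    counts = sample_truncated_nb(rng, 500, 5.0, 2.0)
    se = counts.std(ddof=1) / np.sqrt(len(counts))
    assert abs(counts.mean() - 5.0) < 3 * se


def test_large_dispersion_approaches_truncated_poisson():
    rng = np.random.default_rng(2)
    x = sample_truncated_nb(rng, 20000, 5.0, 1e6)
    lam = calibrate_truncated_nb(5.0, 1e6)
    var_pois = (lam + lam**2) / (1 - np.exp(-lam)) - 5.0**2
    assert x.var() == pytest.approx(var_pois, rel=0.1)


# -- truth-table invariants -------------------------------------------------

def test_in_domain_particles_lie_within_fwhm_radius(pair100):
    _, _, _, truth = pair100
    dom = truth.domains.set_index("domain_id")
    p = truth.particles[truth.particles["domain_id"] != BACKGROUND_ID]
    dx = p["x_tirf_nm"].to_numpy() - dom.loc[p["domain_id"], "x_nm"].to_numpy()
    dy = p["y_tirf_nm"].to_numpy() - dom.loc[p["domain_id"], "y_nm"].to_numpy()
    r = np.hypot(dx, dy)
    assert np.all(r <= dom.loc[p["domain_id"], "fwhm_nm"].to_numpy() / 2.0 + 1e-9)


def test_hard_core_placement_rarely_overlaps(pair100):
    _, _, _, truth = pair100
    p = truth.particles[truth.particles["domain_id"] != BACKGROUND_ID]
    n_overlap = 0
    for _, grp in p.groupby("domain_id"):
        xy = grp[["x_tirf_nm", "y_tirf_nm"]].to_numpy()
        d = grp["diam_nm"].to_numpy()
        dist = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        req = (d[:, None] + d[None, :]) / 2.0
        iu = np.triu_indices(len(xy), 1)
        n_overlap += int((dist[iu] < req[iu]).sum())
    assert n_overlap <= 0.02 * len(p)


def test_fiducials_satisfy_transform_exactly(pair100):
    _, _, _, truth = pair100
    mapped = truth.transform.apply(truth.fiducials.source_nm)
    assert np.max(np.abs(mapped - truth.fiducials.target_nm)) < 1e-9


def test_domain_mapping_outside_esem_field_warns():
    shifted = AffineTransform.from_params(translation_nm=(30000.0, 0.0))
    config = SimulationConfig(
        field_nm=(8000.0, 8000.0), n_domains=3, transform_truth=shifted, seed=0
    )
    with pytest.warns(UserWarning, match="outside the ESEM field"):
        _, _, truth = simulate_pair(config)
    assert not truth.domains["in_esem_field"].any()


# -- rendering calibration ---------------------------------------------------

@pytest.mark.parametrize("fwhm", [300.0, 400.0, 560.0])
def test_noiseless_spot_fwhm_calibration(fwhm):
    img = noiseless_spot_image(fwhm, pixel_nm=60.0, size_px=61)
    spots = detect_and_measure(img)
    assert len(spots) == 1
    assert spots[0].fwhm_nm == pytest.approx(fwhm, rel=0.01)


# -- configuration validation ------------------------------------------------

@pytest.mark.parametrize(
    "overrides",
    [
        {"field_nm": (0.0, 1000.0)},
        {"tirf_pixel_nm": -1.0},
        {"n_domains": -1},
        {"fwhm_mean_nm": 50.0},  # below the TIRF pixel size
        {"count_mean": 0.8},
        {"particle_polarity": "weird"},
        {"noise": (50.0, 2.0)},
    ],
)
def test_invalid_config_rejected(overrides):
    with pytest.raises(ConfigurationError):
        SimulationConfig(**overrides)


def test_unknown_config_key_rejected():
    with pytest.raises(ConfigurationError, match="bogus"):
        SimulationConfig.from_dict({"bogus": 1})


# -- fixture I/O -------------------------------------------------------------

def test_fixture_roundtrip_and_regeneration(tmp_path):
    config = SimulationConfig(**SMALL)
    tirf, esem, truth = simulate_pair(config)
    manifest = write_fixture(truth, tirf, esem, tmp_path / "fx", config)
    assert set(manifest["files"]) == {
        "tirf.tif", "esem.tif", "domains.csv", "particles.csv",
        "fiducials.csv", "transform.json",
    }
    tirf2, esem2, truth2, manifest2 = load_fixture(tmp_path / "fx")
    assert np.array_equal(tirf.data, tirf2.data)
    assert np.array_equal(esem.data, esem2.data)
    pd.testing.assert_frame_equal(truth.domains, truth2.domains)
    pd.testing.assert_frame_equal(truth.particles, truth2.particles)
    assert manifest2["files"] == manifest["files"]

    # regenerating from the manifest's config echo reproduces every checksum
    regen = SimulationConfig.from_dict(
        {**manifest["config"], "transform_truth": manifest["config"]["transform_truth"]}
    )
    t3, e3, tr3 = simulate_pair(regen)
    manifest3 = write_fixture(tr3, t3, e3, tmp_path / "fx2", regen)
    assert manifest3["files"] == manifest["files"]


def test_disk_field_is_non_overlapping():
    img, truth = simulate_disk_field(100, seed=5)
    xy = truth[["x_nm", "y_nm"]].to_numpy()
    d = truth["diam_nm"].to_numpy()
    dist = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
    req = (d[:, None] + d[None, :]) / 2.0
    iu = np.triu_indices(len(xy), 1)
    assert np.all(dist[iu] > req[iu])
    assert img.data.dtype == np.uint16
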