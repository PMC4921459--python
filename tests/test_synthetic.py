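"""Synthetic-data module: range model, emission density, background,
projection and Poisson sampling."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad as sciquad

from pgslit.geometry import default_kes_setup, default_mps_setup, detector_to_object
from pgslit.synthetic_data import (
    BackgroundModel,
    BeamTargetModel,
    QuadratureSpec,
    background_rate,
    beam_target_model,
    expected_profile,
    impulse_response,
    pg_emission_density,
    profile_fwhm,
    range_pmma,
    sample_profile,
)

# ---------------------------------------------------------------------------
# range model


def test_range_monotone_in_energy():
    assert range_pmma(230.0) > range_pmma(160.0) > range_pmma(100.0)


def test_range_validity_window():
    with pytest.raises(ValueError):
        range_pmma(40.0)
    with pytest.raises(ValueError):
        range_pmma(300.0)


def test_range_water_fit_anchors():
    # the Bragg-Kleeman constants reproduce the tabulated water CSDA ranges
    assert range_pmma(100.0, rsp_pmma=1.0) == pytest.approx(7.718, rel=0.01)
    assert range_pmma(250.0, rsp_pmma=1.0) == pytest.approx(37.94, rel=0.01)


# ---------------------------------------------------------------------------
# emission density


def test_emission_far_tail_negligible():
    beam = beam_target_model(160.0)
    z = beam.range_pmma + 10.0 * beam.falloff_width
    plateau = pg_emission_density(beam.range_pmma / 2.0, beam)
    assert pg_emission_density(z, beam) < 1e-6 * plateau


def test_emission_edge_midpoint_is_half_plateau():
    beam = beam_target_model(160.0)
    edge = beam.range_pmma - beam.falloff_offset
    plateau = pg_emission_density(beam.range_pmma / 2.0, beam)
    assert pg_emission_density(edge, beam) == pytest.approx(0.5 * plateau, rel=1e-3)


def test_emission_integral_quadrature_oracle():
    # integral over z ~= yield * (R - falloff_offset) for sharp edges
    beam = beam_target_model(160.0)
    total, _ = sciquad(lambda z: pg_emission_density(z, beam), -20.0, beam.target_length,
                       limit=400)
    expected = beam.emission_yield * (beam.range_pmma - beam.falloff_offset)
    assert total == pytest.approx(expected, rel=1e-3)


def test_beam_target_model_lengths():
    assert beam_target_model(100.0).target_length == 200.0
    assert beam_target_model(160.0).target_length == 200.0
    assert beam_target_model(230.0).target_length == 400.0


def test_beam_target_model_invariants():
    with pytest.raises(ValueError):
        BeamTargetModel(energy=160.0, range_pmma=250.0, target_length=200.0)
    with pytest.raises(ValueError):
        BeamTargetModel(energy=160.0, range_pmma=150.0, falloff_width=0.0)


# ---------------------------------------------------------------------------
# background


def test_background_slope_direction_and_magnitude():
    m = BackgroundModel()
    lo = background_rate(-40.0, m, "entrance", 230.0)
    hi = background_rate(40.0, m, "entrance", 230.0)
    assert hi > lo
    # +-40 mm ends differ by 2*beta_eff relative to the centre
    mid = background_rate(0.0, m, "entrance", 230.0)
    assert hi / mid == pytest.approx(1.0 + m.beta_eff("entrance", 230.0), rel=1e-9)


def test_background_energy_scaling():
    m = BackgroundModel()
    r100 = background_rate(0.0, m, "bragg_peak", 100.0)
    r230 = background_rate(0.0, m, "bragg_peak", 230.0)
    assert r230 / r100 == pytest.approx((230.0 / 100.0) ** m.energy_exponent, rel=1e-9)


def test_background_inverse_square_distance():
    m = BackgroundModel()
    near = background_rate(0.0, m, "bragg_peak", 160.0, distance=125.0)
    ref = background_rate(0.0, m, "bragg_peak", 160.0, distance=250.0)
    assert near / ref == pytest.approx(4.0, rel=1e-9)


def test_background_entrance_slope_exceeds_peak_slope():
    m = BackgroundModel()
    assert m.beta_eff("entrance", 160.0) > m.beta_eff("bragg_peak", 160.0)


# ---------------------------------------------------------------------------
# expected profiles


def test_expected_profile_linearity_in_protons():
    setup = default_kes_setup(fov_center=10 * range_pmma(160.0), n_rows=2)
    beam = beam_target_model(160.0)
    a = expected_profile(setup, beam, n_protons=1e9)
    b = expected_profile(setup, beam, n_protons=2e9)
    np.testing.assert_allclose(b.counts, 2.0 * a.counts, rtol=1e-12)


def test_expected_profile_determinism():
    setup = default_mps_setup(fov_center=10 * range_pmma(160.0), n_rows=2)
    beam = beam_target_model(160.0)
    a = expected_profile(setup, beam)
    b = expected_profile(setup, beam)
    np.testing.assert_array_equal(a.counts, b.counts)


def test_full_camera_doubles_expected_counts():
    beam = beam_target_model(160.0)
    fov = 10 * range_pmma(160.0)
    one = expected_profile(default_kes_setup(fov_center=fov, n_rows=1), beam)
    two = expected_profile(default_kes_setup(fov_center=fov, n_rows=2), beam)
    np.testing.assert_allclose(two.counts, 2.0 * one.counts, rtol=1e-12)


def test_attenuation_sandwich():
    # removing tungsten attenuation can only increase every bin
    from dataclasses import replace
    from pgslit.geometry import MaterialProps, TUNGSTEN_ALLOY

    beam = beam_target_model(160.0)
    fov = 10 * range_pmma(160.0)
    setup = default_kes_setup(fov_center=fov)
    thin = MaterialProps(mu_linear=1e-9)
    setup_open = replace(setup, collimator=replace(setup.collimator, material=thin))
    closed = expected_profile(setup, beam)
    open_ = expected_profile(setup_open, beam)
    assert np.all(open_.counts >= closed.counts)
    assert open_.counts.sum() > 1.5 * closed.counts.sum()


def test_efficiency_anchor_default_kes_160():
    # total correlated counts per proton for the default (single-row) KES
    # setup at 160 MeV must sit at the clinical order of 1e-5
    beam = beam_target_model(160.0)
    setup = default_kes_setup(fov_center=10 * range_pmma(160.0), n_rows=1)
    prof = expected_profile(setup, beam, bg=BackgroundModel(b0=0.0), n_protons=1.0)
    assert 0.3e-5 <= prof.counts.sum() <= 3e-5


def test_quadrature_convergence():
    # doubling the face-sampling density moves no bin by more than 0.5%
    beam = beam_target_model(160.0)
    fov = 10 * range_pmma(160.0)
    for setup in (default_mps_setup(fov_center=fov), default_kes_setup(fov_center=fov)):
        coarse = expected_profile(setup, beam, quad=QuadratureSpec())
        fine = expected_profile(setup, beam, quad=QuadratureSpec(n_u=32, n_h=8))
        rel = np.abs(coarse.counts - fine.counts) / fine.counts
        assert rel.max() < 0.005


def test_profile_csv_roundtrip(tmp_path):
    beam = beam_target_model(160.0)
    prof = expected_profile(default_mps_setup(fov_center=150.0), beam)
    path = tmp_path / "prof.csv"
    prof.to_csv(path)
    from pgslit.synthetic_data import DetectionProfile

    back = DetectionProfile.from_csv(path, n_protons=prof.n_protons)
    np.testing.assert_allclose(back.counts, prof.counts, rtol=1e-12)
    np.testing.assert_allclose(back.bin_centers_z, prof.bin_centers_z, rtol=1e-12)


# ---------------------------------------------------------------------------
# impulse response


def test_impulse_response_peak_at_source_kes():
    setup = default_kes_setup(fov_center=150.0)
    ir = impulse_response(setup)
    z_peak = ir.bin_centers_z[np.argmax(ir.response)]
    assert abs(z_peak - 150.0) <= 5.0  # within one object-pitch of the source


def test_kes_image_inversion_with_off_centre_source():
    setup = default_kes_setup(fov_center=150.0)
    ir = impulse_response(setup, source_z=160.0)  # downstream source
    u_peak = ir.bin_centers_u[np.argmax(ir.response)]
    assert u_peak < 0  # imaged upstream on the camera: inverted


def test_mps_image_upright_with_off_centre_source():
    setup = default_mps_setup(fov_center=150.0)
    ir = impulse_response(setup, source_z=160.0)
    u_peak = ir.bin_centers_u[np.argmax(ir.response)]
    assert u_peak > 0


def test_profile_fwhm_on_synthetic_gaussian():
    z = np.linspace(-50, 50, 201)
    sigma = 6.0
    v = np.exp(-0.5 * (z / sigma) ** 2)
    assert profile_fwhm(z, v) == pytest.approx(2.3548 * sigma, rel=0.01)


def test_profile_fwhm_rejects_flat():
    z = np.linspace(0, 10, 11)
    with pytest.raises(ValueError):
        profile_fwhm(z, np.ones(11))


# ---------------------------------------------------------------------------
# Poisson sampling


def test_sample_profile_mean_and_variance():
    beam = beam_target_model(160.0)
    ref = expected_profile(default_kes_setup(fov_center=150.0, n_rows=2), beam,
                           n_protons=1e11)
    n = 1e8
    lam = ref.counts * (n / 1e11)
    draws = np.stack([sample_profile(ref, n, seed=s).counts for s in range(400)])
    mean = draws.mean(axis=0)
    var = draws.var(axis=0)
    assert np.all(np.abs(mean - lam) < 5.0 * np.sqrt(lam / 400))
    # Poisson: variance ~= mean (within sampling error of 400 draws)
    np.testing.assert_allclose(var, lam, rtol=0.35)


def test_sample_profile_deterministic_under_seed():
    beam = beam_target_model(160.0)
    ref = expected_profile(default_mps_setup(fov_center=150.0), beam)
    a = sample_profile(ref, 1e8, seed=42)
    b = sample_profile(ref, 1e8, seed=42)
    np.testing.assert_array_equal(a.counts, b.counts)
    c = sample_profile(ref, 1e8, seed=43)
    assert not np.array_equal(a.counts, c.counts)
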