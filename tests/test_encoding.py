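"""Linear encoding model: E/R algebra, SRFs, noise, tensor series."""

import numpy as np
import pytest

from tdspect import (IntervalScheme, LinearEncodingModel, encoding_row,
                     reconstruction_matrix)
from tdspect.encoding import EncodingError, apply_to_table
from tdspect.waveforms import EncodingSpectrum


def _boxcar(lo_hz, hi_hz, height=1.0, f_max=400.0, df=0.05):
    omega = 2 * np.pi * np.arange(0, f_max, df)
    power = height * ((omega >= 2 * np.pi * lo_hz) & (omega < 2 * np.pi * hi_hz))
    b = np.trapezoid(power, omega) / np.pi
    return EncodingSpectrum(omega=omega, power=power.astype(float), bvalue=b)


@pytest.fixture(scope="module")
def model7(library8, scheme3):
    return LinearEncodingModel(library8.spectra([0, 1, 2, 3, 4, 5, 6]), scheme3)


def test_single_open_interval_coefficient_equals_b(library8):
    s = library8.spectra([0])[0]
    scheme = IntervalScheme.from_hz([0.0])
    row = encoding_row(s, scheme)
    assert row.shape == (1,)
    assert row[0] == pytest.approx(s.bvalue_mm2, rel=1e-3)


def test_boxcar_power_lands_in_its_interval():
    s = _boxcar(30, 45)
    scheme = IntervalScheme.from_hz([0, 25, 50])
    row = encoding_row(s, scheme, tail_cutoff=2 * np.pi * 399)
    assert row[1] == pytest.approx(s.bvalue * 1e-6, rel=1e-6)
    assert abs(row[0]) < 1e-12 and abs(row[2]) < 1e-12


def test_row_sums_equal_bvalues(model7):
    np.testing.assert_allclose(model7.E.sum(axis=1), model7.bvalues, rtol=1e-3)


def test_reconstruction_hand_inverse():
    R = reconstruction_matrix(np.array([[1.0, 0.0], [1.0, 1.0]]))
    np.testing.assert_allclose(R, [[1.0, 0.0], [-1.0, 1.0]], atol=1e-12)


def test_diagonal_system_reciprocal():
    E = np.diag([2.0, 4.0, 5.0])
    np.testing.assert_allclose(reconstruction_matrix(E),
                               np.diag([0.5, 0.25, 0.2]), atol=1e-12)


def test_pseudoinverse_property(model7):
    eye = model7.R @ model7.E
    assert np.abs(eye - np.eye(model7.n_intervals)).max() < 1e-8


def test_rank_deficient_matrix_raises():
    E = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
    with pytest.raises(EncodingError, match="rank-deficient"):
        reconstruction_matrix(E)


def test_estimate_recovers_piecewise_constant_d(model7):
    d = np.array([0.8e-3, 1.4e-3, 2.1e-3])
    res = model7.fit(model7.E @ d)
    np.testing.assert_allclose(res.values, d, rtol=1e-10)
    assert np.all(model7.fit(np.zeros(7)).values == 0.0)


def test_estimate_is_linear(model7, rng):
    s1 = rng.standard_normal(7)
    s2 = rng.standard_normal(7)
    lhs = model7.fit(2.5 * s1 - 1.25 * s2).values
    rhs = 2.5 * model7.fit(s1).values - 1.25 * model7.fit(s2).values
    np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-18)


def test_fit_length_mismatch_raises(model7):
    with pytest.raises(EncodingError, match="length"):
        model7.fit(np.zeros(5))


def test_noise_amplification_hand_example():
    E = np.array([[1.0, 0.0], [1.0, 1.0]])
    R = reconstruction_matrix(E)
    amp = np.sqrt(np.diag(R @ R.T))
    np.testing.assert_allclose(amp, [1.0, np.sqrt(2.0)], atol=1e-12)


def test_orthogonal_encodings_have_unit_amplification():
    """E = b * I means each interval is read from one measurement."""
    spectra = [_boxcar(0, 20, 2.0), _boxcar(20, 40, 2.0)]
    scheme = IntervalScheme.from_hz([0, 20])
    model = LinearEncodingModel(spectra, scheme, tail_cutoff=2 * np.pi * 399)
    np.testing.assert_allclose(model.noise_amplification_normalized(),
                               [1.0, 1.0], rtol=2e-3)


def test_noise_matches_monte_carlo(model7, rng):
    """Empirical SD of D_hat over 10^4 noisy draws matches
    sigma_S * sqrt((R R^T)_nn) within 5%."""
    sigma = 0.01
    draws = sigma * rng.standard_normal((10_000, 7))
    d_hat = draws @ model7.R.T
    np.testing.assert_allclose(d_hat.std(axis=0, ddof=1),
                               model7.noise_amplification(sigma), rtol=0.05)


def test_srf_of_single_measurement_is_scaled_spectrum(library8):
    s = library8.spectra([3])[0]
    scheme = IntervalScheme.from_hz([0.0])
    model = LinearEncodingModel([s], scheme)
    srf = model.srf()
    expected = np.interp(srf.omega, s.omega, s.power, right=0) / s.bvalue
    np.testing.assert_allclose(srf.values[0], expected, rtol=5e-4,
                               atol=expected.max() * 1e-6)


def test_srf_interval_area_delta_property(model7):
    areas = model7.srf().interval_areas()
    assert np.abs(areas - np.eye(model7.n_intervals)).max() < 1e-3


def test_srfs_attain_negative_values(model7):
    """SRFs oscillate around zero outside their interval."""
    srfs = model7.srf()
    assert np.all(srfs.values.min(axis=1) < 0)


def test_srf_centroids_near_intervals(model7):
    c = model7.srf().centroids_hz
    edges = np.append(model7.scheme.edges_hz, np.inf)
    for n in range(model7.n_intervals):
        assert edges[n] - 15.0 <= c[n] <= edges[n + 1] + 20.0 if np.isfinite(
            edges[n + 1]) else c[n] >= edges[n] - 15.0


# -- tensor series ------------------------------------------------------

def test_isotropic_frequency_independent_tensors(model7):
    d = 1.2e-3
    tensors = np.tile([d, d, d, 0, 0, 0], (7, 1))
    res = model7.fit_tensor_series(tensors)
    # exact up to the 0.01% spectral-coverage truncation of the E rows
    np.testing.assert_allclose(res.tensors[:, :3], d, rtol=1e-3)
    np.testing.assert_allclose(res.md, d, rtol=1e-3)
    np.testing.assert_allclose(res.ad, d, rtol=1e-3)
    np.testing.assert_allclose(res.rd, d, rtol=1e-3)


def test_md_ad_rd_eigenvalue_arithmetic(model7):
    """Eigenvalues (3, 1, 1) x 1e-3 give MD = 1.667e-3, AD = 3e-3, RD = 1e-3."""
    tensors = np.tile([3e-3, 1e-3, 1e-3, 0, 0, 0], (7, 1))
    res = model7.fit_tensor_series(tensors)
    assert res.md[0] == pytest.approx(5e-3 / 3, rel=1e-3)
    assert res.ad[0] == pytest.approx(3e-3, rel=1e-3)
    assert res.rd[0] == pytest.approx(1e-3, rel=1e-3)


def test_diagonal_tensor_forward_inverse_roundtrip(model7, rng):
    truth = np.zeros((model7.n_intervals, 6))
    truth[:, :3] = 0.5e-3 + 2e-3 * rng.random((model7.n_intervals, 3))
    signals = np.einsum("mn,nj->mj", model7.E, truth)
    res = model7.fit_tensor_series(signals / model7.bvalues[:, None])
    np.testing.assert_allclose(res.tensors, truth, rtol=1e-8)


def test_nonfinite_tensor_inputs_masked(model7):
    tensors = np.tile([1e-3, 1e-3, 1e-3, 0, 0, 0], (7, 1))
    tensors[2, 1] = np.nan
    res = model7.fit_tensor_series(tensors)
    assert np.all(np.isnan(res.tensors))


def test_apply_to_table_scalar_and_tensor_agree_for_isotropic(model7):
    d_interval = np.linspace(0.8e-3, 2e-3, model7.n_intervals)
    adc = (model7.E @ d_interval) / model7.bvalues
    scalar_out = apply_to_table(model7, adc[None, :])
    np.testing.assert_allclose(scalar_out[0], d_interval, rtol=1e-9)
    tensor_row = np.zeros((7, 6))
    tensor_row[:, :3] = adc[:, None]
    tensor_out = apply_to_table(model7, tensor_row.reshape(1, -1))
    np.testing.assert_allclose(tensor_out[0].reshape(model7.n_intervals, 6)[:, 0],
                               d_interval, rtol=1e-9)


def test_apply_to_table_column_mismatch(model7):
    with pytest.raises(EncodingError, match="columns"):
        apply_to_table(model7, np.zeros((3, 5)))


def test_interval_scheme_validation():
    with pytest.raises(EncodingError):
        IntervalScheme.from_hz([10, 20])  # must start at 0
    with pytest.raises(EncodingError):
        IntervalScheme.from_hz([0, 20, 20])  # strictly increasing
    scheme = IntervalScheme.uniform(10.0)
    assert scheme.n_intervals == 6
    assert scheme.labels()[0] == "0-10 Hz"
    assert scheme.labels()[-1] == "50+ Hz"
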