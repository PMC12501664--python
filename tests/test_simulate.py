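"""Simulated measurements: attenuation, both estimation paradigms, noise."""

import numpy as np
import pytest

from tdspect import (IntervalScheme, LinearEncodingModel, SimulationProtocol,
                     attenuation, fit_dispersion, run_noiseless, run_noisy,
                     single_frequency_estimate)
from tdspect.simulate import (SimulationError, interval_width_study,
                              predicted_noise_sd_for)
from tdspect.spectra import DiffusionSpectrumModel, all_scenarios, power_law
from tdspect.waveforms import EncodingSpectrum

TWO_PI = 2 * np.pi


def _flat(d):
    return DiffusionSpectrumModel(
        name="flat", kind="power_law", params={"d0": d},
        _func=lambda w: np.full_like(np.asarray(w, float), d))


@pytest.fixture(scope="module")
def protocol(library8, scheme3):
    return SimulationProtocol(spectra=library8.spectra([0, 2, 3, 5, 6, 7]),
                              scheme=scheme3, reps=400, seed=7)


def test_constant_d_attenuation_equals_b_times_d(library8):
    d = 1.1e-3
    for s in library8.spectra([0, 4]):
        assert attenuation(_flat(d), s) == pytest.approx(
            s.bvalue_mm2 * d, rel=1e-4)


def test_zero_spectrum_attenuates_nothing():
    omega = TWO_PI * np.linspace(0, 100, 101)
    s = EncodingSpectrum(omega=omega, power=np.zeros_like(omega), bvalue=0.0)
    assert attenuation(_flat(1e-3), s) == 0.0


def test_piecewise_constant_d_attenuation_identity(scheme3):
    """For D(omega) piecewise constant on the scheme, the attenuation equals
    sum_n E_n D_n: two independent quadratures of the same integral (a fine
    grid keeps the step-discontinuity quadrature error negligible)."""
    from tdspect.fixtures import toy_waveforms
    spectra = [w.spectrum(df=0.05) for w in toy_waveforms(7)[::3]]
    model = LinearEncodingModel(spectra, scheme3)
    d_n = np.array([0.9e-3, 1.6e-3, 2.2e-3])
    edges = np.append(model.scheme.edges, np.inf)

    def step(w):
        idx = np.clip(np.searchsorted(edges, w, side="right") - 1, 0, 2)
        return d_n[idx]

    for m, s in enumerate(model.spectra):
        assert attenuation(step, s) == pytest.approx(
            float(model.E[m] @ d_n), rel=2e-3)


def test_single_frequency_attribution_conventions(library8):
    pg = library8.spectra([0])[0]
    og = library8.spectra([3])[0]
    f_pg, d_pg = single_frequency_estimate(pg, 1.0)
    f_og, _ = single_frequency_estimate(og, 1.0)
    assert f_pg == 0.0
    assert d_pg == pytest.approx(1.0 / pg.bvalue_mm2)
    assert f_og == pytest.approx(og.centroid_hz())


def test_pg_zero_hz_misattribution_for_increasing_d(library8):
    """For increasing D(omega) the PG estimate exceeds D(0): attributing the
    measurement to 0 Hz is a consistent overestimate."""
    pg = library8.spectra([0])[0]
    model = lambda w: power_law(w, 7e-4, 8.5, 0.5)
    _, d_hat = single_frequency_estimate(pg, attenuation(model, pg))
    assert d_hat > model(np.array([0.0]))[0]


def test_noiseless_flat_model_has_zero_errors(protocol):
    report = run_noiseless(protocol, [_flat(1.3e-3)])
    # bounded by the 0.01% spectral-coverage truncation of the open interval
    assert report.linear.error_pct.abs().max() < 0.1
    assert report.single.error_pct.abs().max() < 0.1


def test_noiseless_exact_for_piecewise_constant_but_not_single_frequency(
        library8, scheme3):
    """The linear model is exact when D(omega) is piecewise constant on the
    scheme; single-frequency attribution generally is not."""
    model = LinearEncodingModel(library8.spectra([0, 2, 3, 5, 6, 7]), scheme3)
    d_n = np.array([0.8e-3, 1.5e-3, 2.4e-3])
    edges = np.append(model.scheme.edges, np.inf)
    signals = model.E @ d_n
    rec = model.fit(signals).values
    np.testing.assert_allclose(rec, d_n, rtol=1e-9)
    sf = [single_frequency_estimate(s, signals[m])[1]
          for m, s in enumerate(model.spectra)]
    idx = np.clip(np.searchsorted(
        edges, TWO_PI * np.array([single_frequency_estimate(s, 0)[0]
                                  for s in model.spectra]),
        side="right") - 1, 0, 2)
    assert np.max(np.abs(np.array(sf) - d_n[idx]) / d_n[idx]) > 0.01


def test_noiseless_report_is_seed_free(protocol):
    models = [all_scenarios()[0]]
    a = run_noiseless(protocol, models)
    b = run_noiseless(SimulationProtocol(
        spectra=protocol.spectra, scheme=protocol.scheme, seed=999), models)
    assert a.linear.equals(b.linear) and a.single.equals(b.single)


def test_noisy_zero_sigma_gives_zero_sds(library8, scheme3):
    protocol = SimulationProtocol(spectra=library8.spectra([0, 2, 3, 5]),
                                  scheme=scheme3, sigma_rel=0.0, reps=10, seed=3)
    report = run_noisy(protocol, [_flat(1e-3)])
    # identical repetitions: SDs vanish up to summation round-off
    assert report.linear.sd_pct.max() < 1e-10
    assert report.single.sd_pct.max() < 1e-10


def test_noisy_seeded_reproducibility(protocol):
    models = all_scenarios()[:2]
    a = run_noisy(protocol, models)
    b = run_noisy(protocol, models)
    assert a.linear.equals(b.linear) and a.single.equals(b.single)
    c = run_noisy(SimulationProtocol(
        spectra=protocol.spectra, scheme=protocol.scheme, reps=protocol.reps,
        seed=protocol.seed + 1), models)
    assert not a.linear.sd.equals(c.linear.sd)


def test_noisy_sd_matches_delta_method(library8, scheme3):
    """Monte-Carlo SDs converge to the analytic error propagation of
    ln(mean S0 / mean S) through the reconstruction within 5%."""
    protocol = SimulationProtocol(spectra=library8.spectra([0, 2, 3, 5, 6, 7]),
                                  scheme=scheme3, sigma_rel=0.02,
                                  reps=10_000, seed=11)
    model = all_scenarios()[0]
    report = run_noisy(protocol, [model])
    predicted = predicted_noise_sd_for(protocol, model)
    np.testing.assert_allclose(report.linear.sd.to_numpy(), predicted,
                               rtol=0.05)


def test_fit_dispersion_exact_recovery():
    freqs = np.array([3.0, 12.0, 25.0, 40.0, 60.0])
    d = power_law(TWO_PI * freqs, 7e-4, 8.5, 0.5)
    d0, lam = fit_dispersion(freqs, d, theta=0.5)
    assert d0 == pytest.approx(7e-4, rel=1e-9)
    assert lam == pytest.approx(8.5, rel=1e-9)


def test_fit_dispersion_two_points_interpolates():
    freqs = np.array([10.0, 40.0])
    d = power_law(TWO_PI * freqs, 1e-3, 2.0, 1.0)
    d0, lam = fit_dispersion(freqs, d, theta=1.0)
    resid = d - (d0 + lam * 1e-6 * TWO_PI * freqs)
    assert np.abs(resid).max() < 1e-18


def test_fit_dispersion_degenerate_design_raises():
    with pytest.raises(SimulationError, match="degenerate|two points"):
        fit_dispersion(np.array([10.0, 10.0]), np.array([1e-3, 1e-3]), 0.5)
    with pytest.raises(SimulationError):
        fit_dispersion(np.array([10.0]), np.array([1e-3]), 0.5)


def test_linear_model_fits_dispersion_more_accurately(library8, scheme3):
    """Noiseless scenario-1 pipeline: D0/Lambda recovered from linear-model
    estimates at SRF centroids beat single-frequency recovery."""
    protocol = SimulationProtocol(spectra=library8.spectra([0, 2, 3, 5, 6, 7]),
                                  scheme=scheme3)
    model = all_scenarios()[0]
    report = run_noiseless(protocol, [model])
    lin = report.linear
    d0_l, lam_l = fit_dispersion(lin.ref_freq_hz.to_numpy(),
                                 lin.d_hat.to_numpy(), theta=0.5)
    sf = report.single
    d0_s, lam_s = fit_dispersion(sf.assigned_freq_hz.to_numpy(),
                                 sf.d_hat.to_numpy(), theta=0.5)
    err_l = abs(d0_l / 7e-4 - 1) + abs(lam_l / 8.5 - 1)
    err_s = abs(d0_s / 7e-4 - 1) + abs(lam_s / 8.5 - 1)
    assert err_l < err_s


def test_interval_width_study_structure(library8):
    schemes = [(IntervalScheme.uniform(25.0), 3),
               (IntervalScheme.uniform(50.0 / 3), 4)]
    models = all_scenarios()[:2]
    table = interval_width_study(schemes, library8, models,
                                 sigma_rel=0.02, reps=100, seed=5)
    assert len(table) == 4  # two schemes x two paradigms
    assert set(table.paradigm) == {"single", "linear"}
    # N equals number of primary intervals + 1 in every scheme
    assert set(table.n_intervals) == {3, 4}
    assert np.all(table.avg_abs_error_pct >= 0)
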