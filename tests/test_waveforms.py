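"""Waveform synthesis: b-values, refocusing, feasibility, spectral shape."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdspect.waveforms import (EncodingSpectrum, HardwareConstraints,
                               Waveform, WaveformError, make_double_bipolar,
                               make_og_trapcos, make_pg,
                               pg_bvalue_closed_form, scale_to_b, GAMMA)

HIGH_SLEW = 1e6  # effectively rectangular lobes


@pytest.mark.parametrize("delta,Delta", [(5e-3, 25e-3), (10e-3, 30e-3),
                                         (20e-3, 45e-3), (40e-3, 48e-3)])
def test_pg_bvalue_matches_closed_form(delta, Delta):
    w = make_pg(0.08, delta, Delta, slew=HIGH_SLEW)
    expected = pg_bvalue_closed_form(0.08, delta, Delta)
    assert w.bvalue() == pytest.approx(expected, rel=1e-3)


def test_pg_reference_bvalue():
    """G=50 mT/m, delta=10 ms, Delta=30 ms gives b close to 477 s/mm^2."""
    w = make_pg(0.05, 0.010, 0.030, slew=HIGH_SLEW)
    assert w.bvalue_mm2() == pytest.approx(477.12, rel=1e-3)


def test_zero_amplitude_gives_zero_b():
    assert make_pg(0.0, 0.01, 0.03).bvalue() == 0.0
    assert make_double_bipolar(0.0, 0.01).bvalue() == 0.0


def test_protocol_admits_b1000():
    """A 200 mT/m, <=90 ms PG protocol reaches b = 1000 s/mm^2."""
    c = HardwareConstraints()
    w = make_pg(c.g_max, 0.015, 0.060, slew=c.slew_max)
    scaled = scale_to_b(w, 1000.0, constraints=c)
    assert scaled.bvalue_mm2() == pytest.approx(1000.0, rel=1e-6)
    assert scaled.duration <= c.t_dw_max


def test_pg_q_is_trapezoid():
    g_amp, delta, Delta = 0.06, 0.012, 0.040
    w = make_pg(g_amp, delta, Delta, slew=HIGH_SLEW)
    q = w.q_trajectory()
    assert np.max(q.q) == pytest.approx(GAMMA * g_amp * delta, rel=1e-4)
    # plateau between the lobes
    t = np.arange(len(q.q)) * q.dt
    plateau = (t > delta + 1e-3) & (t < Delta - 1e-3)
    assert np.ptp(q.q[plateau]) < 1e-6 * np.max(q.q)


def test_zero_waveform_q_identically_zero():
    q = make_pg(0.0, 0.01, 0.03).q_trajectory()
    assert np.all(q.q == 0.0)


def test_unbalanced_waveform_flagged():
    """A single unipolar lobe violates the refocusing condition."""
    w = Waveform(np.array([0.0, 1e-3, 9e-3, 10e-3]),
                 np.array([0.0, 0.05, 0.05, 0.0]),
                 dt=1e-5, refocus_time=5e-3, family="PG")
    with pytest.raises(WaveformError, match="refocus"):
        w.q_trajectory()


def test_og_peak_near_oscillation_frequency():
    w = make_og_trapcos(40.0, 2, 0.1, gap=0.0)
    s = w.spectrum(df=0.05)
    assert 35.0 <= s.peak_hz() <= 45.0


def test_og_gap_variants_centroid_near_f_osc():
    for gap_fill, polarity in [(True, "matched"), (True, "unmatched"),
                               (False, "matched"), (False, "unmatched")]:
        w = make_og_trapcos(40.0, 2 if gap_fill else 1, 0.1,
                            gap_fill=gap_fill, polarity=polarity)
        s = w.spectrum(df=0.1)
        assert 33.0 <= s.centroid_hz() <= 47.0


def test_og_rejects_degenerate_periods():
    with pytest.raises(WaveformError):
        make_og_trapcos(40.0, 0, 0.1)


def test_og_too_low_frequency_rejected():
    """Oscillations that cannot complete within T_DW are infeasible."""
    with pytest.raises(WaveformError, match="fit"):
        make_og_trapcos(10.0, 1, 0.1, t_dw_max=0.090)


def test_mainlobe_time_bandwidth_product():
    """A full-window waveform has spectral FWHM about 0.9 / T_DW."""
    c = HardwareConstraints()
    r0 = 0.1 / c.slew_max
    f = 3 / (c.t_dw_max - c.refocus_gap - 2 * r0)
    w = make_og_trapcos(f, 3, 0.1, gap=c.refocus_gap, slew=c.slew_max)
    assert w.duration == pytest.approx(c.t_dw_max, rel=1e-6)
    product = w.spectrum(df=0.02).fwhm_hz() * c.t_dw_max
    assert product == pytest.approx(0.9, rel=0.10)


def test_double_bipolar_wide_lobe_centroid_below_10hz():
    w = make_double_bipolar(0.2, 0.0205, slew=600.0, polarity="unmatched")
    assert w.spectrum(df=0.1).centroid_hz() < 10.0


@pytest.mark.parametrize("maker", [
    lambda pol: make_og_trapcos(45.0, 1, 0.15, gap_fill=False, polarity=pol),
    lambda pol: make_double_bipolar(0.15, 0.015, polarity=pol),
])
def test_polarity_flip_preserves_bvalue(maker):
    b = {pol: maker(pol).bvalue() for pol in ("matched", "unmatched")}
    assert b["matched"] == pytest.approx(b["unmatched"], rel=1e-3)


@pytest.mark.parametrize("w", [
    make_pg(0.2, 0.015, 0.050, slew=600.0),
    make_og_trapcos(30.0, 2, 0.2, slew=600.0),
    make_og_trapcos(50.0, 2, 0.2, slew=600.0, gap_fill=False),
    make_double_bipolar(0.2, 0.012, slew=600.0),
], ids=["PG", "OG-gapfill", "OG-twoburst", "DB"])
def test_parseval_and_refocusing(w):
    """(1/pi) int |Q|^2 domega equals int q^2 dt within 0.1%; q refocuses."""
    q = w.q_trajectory()
    assert abs(q.q[-1]) <= 1e-6 * np.max(np.abs(q.q))
    s = w.spectrum(df=0.1)
    assert s.total_power() == pytest.approx(q.bvalue, rel=1e-3)


def test_spectrum_time_shift_invariance():
    a = make_og_trapcos(35.0, 2, 0.1).spectrum(df=0.1)
    b = make_og_trapcos(35.0, 2, 0.1, t_start=7.7e-3).spectrum(df=0.1)
    n = min(len(a.power), len(b.power))
    assert np.allclose(a.power[:n], b.power[:n], rtol=1e-9, atol=a.power.max() * 1e-9)


def test_pg_spectrum_peaks_at_zero_with_positive_centroid():
    s = make_pg(0.1, 0.010, 0.040, slew=600.0).spectrum(df=0.05)
    assert s.peak_hz() == 0.0
    assert s.centroid_hz() > 0.0


def _boxcar(lo_hz, hi_hz):
    omega = 2 * np.pi * np.linspace(0, 100, 2001)
    power = ((omega >= 2 * np.pi * lo_hz) & (omega <= 2 * np.pi * hi_hz)).astype(float)
    return EncodingSpectrum(omega=omega, power=power, bvalue=1.0)


def test_centroid_of_boxcar_is_midpoint():
    assert _boxcar(20, 30).centroid_hz() == pytest.approx(25.0, abs=0.1)


def test_centroid_of_symmetric_spectrum_is_center():
    omega = 2 * np.pi * np.linspace(0, 80, 4001)
    power = np.exp(-0.5 * ((omega / (2 * np.pi) - 40) / 3) ** 2)
    s = EncodingSpectrum(omega=omega, power=power, bvalue=1.0)
    assert s.centroid_hz() == pytest.approx(40.0, abs=0.05)


def test_all_zero_spectrum_centroid_errors():
    omega = 2 * np.pi * np.linspace(0, 10, 101)
    s = EncodingSpectrum(omega=omega, power=np.zeros_like(omega), bvalue=0.0)
    with pytest.raises(WaveformError):
        s.centroid_hz()


def test_scale_to_b_identity_and_quadratic_scaling():
    w = make_pg(0.05, 0.010, 0.030, slew=600.0)
    b0 = w.bvalue_mm2()
    same = scale_to_b(w, b0)
    assert np.allclose(same.breaks_g, w.breaks_g)
    doubled = w.scaled(2.0)
    assert doubled.bvalue_mm2() == pytest.approx(4 * b0, rel=1e-9)


def test_scale_to_b_infeasible_raises():
    c = HardwareConstraints(g_max=0.04)
    w = make_pg(0.04, 0.010, 0.030, slew=600.0)
    with pytest.raises(WaveformError, match="amplitude"):
        scale_to_b(w, 50 * w.bvalue_mm2(), constraints=c)


def test_feasibility_checks_error_rather_than_clip():
    c = HardwareConstraints()
    w = make_pg(0.3, 0.010, 0.030, slew=c.slew_max)
    with pytest.raises(WaveformError, match="amplitude"):
        w.check_feasible(c)
    w2 = make_pg(0.2, 0.010, 0.030, slew=5000.0)
    with pytest.raises(WaveformError, match="slew"):
        w2.check_feasible(c)
    w3 = make_pg(0.1, 0.020, 0.080, slew=c.slew_max)
    with pytest.raises(WaveformError, match="duration"):
        w3.check_feasible(c)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    delta_ms=st.floats(4.0, 30.0),
    gap_ms=st.floats(1.0, 30.0),
    g_amp=st.floats(0.01, 0.2),
)
def test_pg_invariants_property(delta_ms, gap_ms, g_amp):
    """Closed-form b, refocusing and Parseval hold across the PG envelope."""
    delta = delta_ms * 1e-3
    Delta = delta + gap_ms * 1e-3
    w = make_pg(g_amp, delta, Delta, slew=HIGH_SLEW)
    assert w.bvalue() == pytest.approx(
        pg_bvalue_closed_form(g_amp, delta, Delta), rel=1e-3)
    s = w.spectrum(df=0.2)
    assert s.total_power() == pytest.approx(w.bvalue(), rel=1e-3)
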