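"""Diffusion gradient waveform synthesis and encoding-spectrum computation.

Waveforms are represented in the *effective gradient* convention: the sign of
the gradient played out after the 180 degree refocusing pulse is already
inverted, so the refocusing condition reads ``integral g_eff(t) dt = 0`` and
the q-space trajectory returns to zero at the end of encoding.

Three waveform families are provided:

* monopolar pulsed gradient (PG): two rectangular-with-ramps lobes separated
  by Delta, encoding spectrum peaked at 0 Hz;
* trapezoidal-cosine oscillating gradient (OG): spectrum peaked near the
  oscillation frequency, either gap-filled across the refocusing dead time
  (phase-continuous splice at a gradient zero crossing) or as two independent
  zero-area bursts with matched/unmatched polarity;
* double-bipolar: two bipolar pairs straddling the refocusing pulse, reaching
  spectral centroids below 10 Hz for wide lobes.

Internally all quantities are SI (T/m, s, rad/m, rad/s, s/m^2); frequencies
are expressed in Hz and b-values in s/mm^2 only at user-facing interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.fft import next_fast_len, rfft, rfftfreq

#: Proton gyromagnetic ratio (rad/s/T).
GAMMA = 2.6752218744e8

#: Fraction of total spectral power a stored frequency grid must cover.
SPECTRUM_COVERAGE = 0.9999

S_MM2_PER_S_M2 = 1e-6  # b-value unit conversion


class WaveformError(ValueError):
    """Raised for infeasible or ill-specified waveform requests."""


@dataclass(frozen=True)
class HardwareConstraints:
    """Gradient hardware and protocol constraints.

    Parameters
    ----------
    g_max : maximum gradient amplitude (T/m).
    slew_max : maximum slew rate (T/m/s).
    b_value : protocol b-value every library member is normalised to (s/mm^2).
    t_dw_max : maximum total diffusion-encoding duration (s).
    dt : gradient raster time (s).
    refocus_gap : gradient dead time bridging the 180 degree pulse (s).
    """

    g_max: float = 0.200
    slew_max: float = 600.0
    b_value: float = 1000.0
    t_dw_max: float = 0.090
    dt: float = 10e-6
    refocus_gap: float = 6e-3

    @classmethod
    def from_dict(cls, d: dict) -> "HardwareConstraints":
        """Build from the config keys used in YAML/JSON constraint files."""
        conv = {
            "gmax_mT_m": ("g_max", 1e-3),
            "slew_mT_m_ms": ("slew_max", 1.0),
            "b_s_mm2": ("b_value", 1.0),
            "tdw_ms": ("t_dw_max", 1e-3),
            "dt_us": ("dt", 1e-6),
            "refocus_gap_ms": ("refocus_gap", 1e-3),
        }
        kwargs = {}
        for key, value in d.items():
            if key not in conv:
                raise WaveformError(f"unknown constraint key: {key!r}")
            name, scale = conv[key]
            kwargs[name] = float(value) * scale
        return cls(**kwargs)


def _piecewise_area(t: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Cumulative integral of a piecewise-linear curve at its breakpoints."""
    seg = 0.5 * (g[1:] + g[:-1]) * np.diff(t)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _eval_antiderivative(t: np.ndarray, g: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Evaluate the exact antiderivative of the piecewise-linear (t, g) curve.

    Points outside [t[0], t[-1]] are treated as zero gradient.
    """
    area = _piecewise_area(t, g)
    q = np.clip(query, t[0], t[-1])
    idx = np.clip(np.searchsorted(t, q, side="right") - 1, 0, len(t) - 2)
    t0 = t[idx]
    g0 = g[idx]
    dtseg = t[idx + 1] - t0
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(dtseg > 0, (g[idx + 1] - g0) / np.where(dtseg > 0, dtseg, 1.0), 0.0)
    x = q - t0
    return area[idx] + g0 * x + 0.5 * slope * x * x


@dataclass(frozen=True)
class QTrajectory:
    """Sampled q-space trajectory q(t) = gamma * int_0^t g_eff dt' (rad/m)."""

    q: np.ndarray
    dt: float

    @property
    def duration(self) -> float:
        return (len(self.q) - 1) * self.dt

    @property
    def bvalue(self) -> float:
        """b = int q(t)^2 dt in s/m^2."""
        return float(np.trapezoid(self.q**2, dx=self.dt))

    @property
    def bvalue_mm2(self) -> float:
        return self.bvalue * S_MM2_PER_S_M2

    def check_refocused(self, tol: float = 1e-6) -> None:
        peak = float(np.max(np.abs(self.q)))
        if peak == 0.0:
            return
        if abs(self.q[-1]) / peak > tol:
            raise WaveformError(
                f"q-trajectory endpoint {self.q[-1]:.3e} rad/m exceeds refocusing "
                f"tolerance ({tol:g} of peak {peak:.3e})"
            )


@dataclass(frozen=True)
class EncodingSpectrum:
    """Diffusion encoding power spectrum |Q(omega)|^2 on a one-sided grid.

    ``omega`` ascends from 0 (rad/s); ``power`` is |Q|^2 in (rad/m)^2 s^2;
    ``bvalue`` is the time-domain b (s/m^2). The stored grid extends at least
    to the frequency containing 99.99% of total spectral power.
    """

    omega: np.ndarray
    power: np.ndarray
    bvalue: float
    label: str = ""
    family: str = ""
    params: dict = field(default_factory=dict)

    @property
    def bvalue_mm2(self) -> float:
        return self.bvalue * S_MM2_PER_S_M2

    @property
    def domega(self) -> float:
        return float(self.omega[1] - self.omega[0])

    def total_power(self) -> float:
        """(1/pi) * integral of the stored power: approximates b (s/m^2)."""
        return float(np.trapezoid(self.power, self.omega)) / np.pi

    def coverage_omega(self, fraction: float = SPECTRUM_COVERAGE) -> float:
        """Lowest grid frequency below which ``fraction`` of stored power lies."""
        cum = np.concatenate([[0.0], np.cumsum((self.power[1:] + self.power[:-1]) / 2)])
        cum *= self.domega
        idx = int(np.searchsorted(cum, fraction * cum[-1]))
        return float(self.omega[min(idx, len(self.omega) - 1)])

    def centroid_hz(self) -> float:
        """Power-weighted mean frequency (Hz)."""
        total = np.trapezoid(self.power, self.omega)
        if total <= 0:
            raise WaveformError("centroid undefined for all-zero spectrum")
        return float(np.trapezoid(self.omega * self.power, self.omega) / total / (2 * np.pi))

    def peak_hz(self) -> float:
        return float(self.omega[int(np.argmax(self.power))] / (2 * np.pi))

    def fwhm_hz(self) -> float:
        """Full width at half maximum of the mainlobe around the global peak.

        Spectra are even in omega, so a peak at 0 Hz contributes twice its
        one-sided half width.
        """
        return _mainlobe_fwhm(self.omega, self.power) / (2 * np.pi)


def _mainlobe_fwhm(omega: np.ndarray, power: np.ndarray) -> float:
    """Mainlobe FWHM (rad/s) of a curve that is even in omega."""
    k = int(np.argmax(power))
    half = power[k] / 2.0
    if power[k] <= 0:
        raise WaveformError("FWHM undefined for non-positive spectrum")

    def cross(idx_range):
        prev = k
        for i in idx_range:
            if power[i] < half:
                # linear interpolation between i and prev
                w = (power[prev] - half) / (power[prev] - power[i])
                return omega[prev] + w * (omega[i] - omega[prev])
            prev = i
        return None

    right = cross(range(k + 1, len(power)))
    if right is None:
        raise WaveformError("mainlobe FWHM: no half-power crossing above the peak")
    left = cross(range(k - 1, -1, -1))
    if left is None:
        # peak is (effectively) at 0 Hz: reflect the right crossing
        return 2.0 * (right - omega[k]) if k == 0 else right - (-right)
    return right - left


@dataclass(frozen=True)
class Waveform:
    """An effective diffusion gradient waveform.

    The exact piecewise-linear curve is stored as breakpoints; ``samples``
    returns per-raster-step averages of the exact curve, which preserves the
    refocusing integral to floating-point precision.
    """

    breaks_t: np.ndarray
    breaks_g: np.ndarray
    dt: float
    refocus_time: float
    family: str
    params: dict = field(default_factory=dict)
    gamma: float = GAMMA

    def __post_init__(self):
        t = np.asarray(self.breaks_t, dtype=float)
        g = np.asarray(self.breaks_g, dtype=float)
        if t.ndim != 1 or t.shape != g.shape or len(t) < 2:
            raise WaveformError("breakpoints must be two equal-length 1-D arrays")
        if np.any(np.diff(t) < 0):
            raise WaveformError("breakpoint times must be non-decreasing")
        object.__setattr__(self, "breaks_t", t)
        object.__setattr__(self, "breaks_g", g)

    # -- basic geometry -------------------------------------------------
    @property
    def duration(self) -> float:
        return float(self.breaks_t[-1] - self.breaks_t[0])

    @property
    def n_samples(self) -> int:
        return int(np.ceil(self.duration / self.dt - 1e-9))

    @property
    def samples(self) -> np.ndarray:
        """Per-step average effective gradient (T/m) on the raster grid."""
        n = self.n_samples
        edges = self.breaks_t[0] + np.arange(n + 1) * self.dt
        anti = _eval_antiderivative(self.breaks_t, self.breaks_g, edges)
        return np.diff(anti) / self.dt

    @property
    def amplitude(self) -> float:
        return float(np.max(np.abs(self.breaks_g)))

    @property
    def slew(self) -> float:
        """Maximum slew rate over the exact curve (T/m/s)."""
        dg = np.abs(np.diff(self.breaks_g))
        dts = np.diff(self.breaks_t)
        mask = dg > 0
        if not np.any(mask):
            return 0.0
        if np.any(dts[mask] <= 0):
            return np.inf
        return float(np.max(dg[mask] / dts[mask]))

    def check_feasible(self, constraints: HardwareConstraints, rtol: float = 1e-9) -> None:
        """Raise :class:`WaveformError` on any hardware-constraint violation."""
        if self.amplitude > constraints.g_max * (1 + rtol):
            raise WaveformError(
                f"amplitude {self.amplitude*1e3:.1f} mT/m exceeds "
                f"G_max {constraints.g_max*1e3:.1f} mT/m"
            )
        if self.slew > constraints.slew_max * (1 + rtol):
            raise WaveformError(
                f"slew {self.slew:.0f} T/m/s exceeds limit {constraints.slew_max:.0f}"
            )
        if self.duration > constraints.t_dw_max * (1 + rtol):
            raise WaveformError(
                f"duration {self.duration*1e3:.2f} ms exceeds "
                f"T_DW,max {constraints.t_dw_max*1e3:.1f} ms"
            )

    # -- derived quantities ---------------------------------------------
    def net_area(self) -> float:
        return float(_piecewise_area(self.breaks_t, self.breaks_g)[-1])

    def q_trajectory(self) -> QTrajectory:
        n = self.n_samples
        edges = self.breaks_t[0] + np.arange(n + 1) * self.dt
        q = self.gamma * _eval_antiderivative(self.breaks_t, self.breaks_g, edges)
        traj = QTrajectory(q=q, dt=self.dt)
        traj.check_refocused()
        return traj

    def bvalue(self) -> float:
        return self.q_trajectory().bvalue

    def bvalue_mm2(self) -> float:
        return self.bvalue() * S_MM2_PER_S_M2

    def spectrum(
        self,
        df: float = 0.1,
        f_max: Optional[float] = None,
        label: Optional[str] = None,
    ) -> EncodingSpectrum:
        """Encoding power spectrum |Q(omega)|^2 via zero-padded FFT of q(t).

        Parameters
        ----------
        df : frequency grid resolution (Hz); achieved by zero padding.
        f_max : upper grid limit (Hz). If None the grid is truncated at the
            99.99%-power coverage frequency; if given, coverage up to f_max
            must still reach 99.99% of total power.
        """
        traj = self.q_trajectory()
        q = traj.q
        n_pad = next_fast_len(int(np.ceil(1.0 / (df * self.dt))))
        if n_pad < len(q):
            raise WaveformError("frequency grid too coarse for this waveform duration")
        qf = rfft(q, n=n_pad) * self.dt
        power = np.abs(qf) ** 2
        omega = 2 * np.pi * rfftfreq(n_pad, self.dt)

        cum = np.concatenate([[0.0], np.cumsum((power[1:] + power[:-1]) / 2)])
        total = cum[-1]
        if f_max is None:
            if total > 0:
                k = int(np.searchsorted(cum, SPECTRUM_COVERAGE * total)) + 1
            else:
                k = len(power)
            k = min(max(k, 2), len(power))
        else:
            k = int(np.searchsorted(omega, 2 * np.pi * f_max, side="right"))
            k = min(max(k, 2), len(power))
            if total > 0 and cum[k - 1] < SPECTRUM_COVERAGE * total:
                raise WaveformError(
                    f"f_max={f_max:g} Hz covers only {cum[k-1]/total:.6f} of the "
                    "spectral power (0.9999 required)"
                )
        return EncodingSpectrum(
            omega=omega[:k],
            power=power[:k],
            bvalue=traj.bvalue,
            label=label if label is not None else self.describe(),
            family=self.family,
            params=dict(self.params),
        )

    def scaled(self, factor: float) -> "Waveform":
        return replace(self, breaks_g=self.breaks_g * factor)

    def describe(self) -> str:
        inner = ",".join(f"{k}={v:g}" if isinstance(v, float) else f"{k}={v}"
                         for k, v in self.params.items())
        return f"{self.family}({inner})"


def scale_to_b(
    w: Waveform,
    b_target_mm2: float,
    constraints: Optional[HardwareConstraints] = None,
) -> Waveform:
    """Rescale amplitude so the b-value equals ``b_target_mm2`` (s/mm^2).

    b scales with the square of the amplitude, so the scale factor is
    sqrt(b_target / b_current). If ``constraints`` are given, the scaled
    waveform must remain feasible (no hard clipping).
    """
    if b_target_mm2 <= 0:
        raise WaveformError("b_target must be positive")
    b_current = w.bvalue_mm2()
    if b_current <= 0:
        raise WaveformError("cannot rescale a zero-b waveform")
    factor = float(np.sqrt(b_target_mm2 / b_current))
    scaled = w.scaled(factor)
    if constraints is not None:
        scaled.check_feasible(constraints)
    return scaled


# ---------------------------------------------------------------------------
# waveform constructors
# ---------------------------------------------------------------------------

def make_pg(
    g_amp: float,
    delta: float,
    Delta: float,
    dt: float = 10e-6,
    slew: float = 600.0,
    refocus_time: Optional[float] = None,
    t_start: float = 0.0,
) -> Waveform:
    """Monopolar pulsed gradient: two lobes of width ``delta`` whose leading
    edges are ``Delta`` apart; the second lobe is sign-inverted in the
    effective-gradient representation.

    ``delta`` follows the start-of-ramp-up to start-of-ramp-down convention,
    so each lobe area is exactly ``g_amp * delta``.
    """
    if delta <= 0 or Delta <= 0:
        raise WaveformError("delta and Delta must be positive")
    if delta > Delta:
        raise WaveformError("delta must not exceed Delta")
    if g_amp < 0:
        raise WaveformError("negative amplitude")
    if g_amp == 0.0:
        t = np.array([t_start, t_start + Delta + delta])
        return Waveform(t, np.zeros(2), dt, refocus_time or (t_start + Delta / 2),
                        "PG", {"G": g_amp, "delta": delta, "Delta": Delta})
    ramp = g_amp / slew
    if delta < ramp:
        raise WaveformError("delta shorter than the slew-limited ramp time")
    if Delta < delta + ramp:
        raise WaveformError("lobes overlap: Delta < delta + ramp")
    t0 = t_start
    t1 = t0 + Delta
    t = np.array([
        t0, t0 + ramp, t0 + delta, t0 + delta + ramp,
        t1, t1 + ramp, t1 + delta, t1 + delta + ramp,
    ])
    g = np.array([0, g_amp, g_amp, 0, 0, -g_amp, -g_amp, 0], dtype=float)
    if refocus_time is None:
        refocus_time = 0.5 * ((t0 + delta + ramp) + t1)
    if not (t0 + delta + ramp) <= refocus_time <= t1:
        raise WaveformError("refocusing pulse must fall between the two lobes")
    return Waveform(t, g, dt, refocus_time, "PG",
                    {"G": g_amp, "delta": delta, "Delta": Delta})


def _trapcos_burst(g_amp: float, f_osc: float, n_periods: int, slew: float):
    """Breakpoints of a zero-net-area trapezoidal-cosine burst.

    The burst spans ``n_periods / f_osc + r0`` where ``r0 = g_amp/slew``; the
    flat-top pattern follows the sign of cos(2 pi f t) with slew-limited
    transitions, and the end flats are extended by half a ramp so the net
    area vanishes exactly.
    """
    T = 1.0 / f_osc
    r0 = g_amp / slew       # 0 <-> G ramp
    r = 2 * g_amp / slew    # +G <-> -G ramp
    crossings = r0 / 2 + (2 * np.arange(2 * n_periods) + 1) * T / 4
    # every flat segment must have non-negative length
    if T / 4 - r0 / 2 - r / 2 < r0 / 2 or T / 2 - r < 0:
        raise WaveformError(
            f"slew-infeasible trapezoidal cosine: f={f_osc:g} Hz at G={g_amp:g} T/m"
        )
    t = [0.0, r0]
    g = [0.0, g_amp]
    sign = 1.0
    for c in crossings:
        t.extend([c - r / 2, c + r / 2])
        g.extend([sign * g_amp, -sign * g_amp])
        sign = -sign
    end = n_periods * T + r0
    t.extend([end - r0, end])
    g.extend([sign * g_amp, 0.0])
    return np.array(t), np.array(g), crossings


def make_og_trapcos(
    f_osc: float,
    n_periods: int,
    g_amp: float,
    dt: float = 10e-6,
    slew: float = 600.0,
    gap: float = 6e-3,
    gap_fill: bool = True,
    polarity: str = "matched",
    t_dw_max: float = 0.090,
    t_start: float = 0.0,
) -> Waveform:
    """Cosine-modulated trapezoidal oscillating gradient.

    gap_fill=True
        A single oscillation of ``n_periods`` total periods spliced at the
        q-trajectory zero crossing nearest the waveform centre. The flat tops
        adjacent to the refocusing dead time are extended by half a ramp so
        lobe areas are preserved and q enters and leaves the gap at exactly
        zero (q-periodicity is bridged across the gap). ``polarity`` sets
        whether the post-refocus half continues the oscillation phase
        (``matched``) or is sign-flipped (``unmatched``); both refocus since
        each half has zero net area.
    gap_fill=False
        Two independent zero-area bursts of ``n_periods`` periods each, one
        per side of the refocusing pulse. ``polarity`` sets the sign of the
        post-refocus burst in the effective-gradient representation.
    """
    if n_periods < 1:
        raise WaveformError("n_periods must be at least 1")
    if f_osc <= 0 or g_amp < 0:
        raise WaveformError("f_osc must be positive and amplitude non-negative")
    if polarity not in ("matched", "unmatched"):
        raise WaveformError(f"unknown polarity {polarity!r}")
    params = {"f_osc": f_osc, "n_periods": n_periods, "G": g_amp,
              "gap_fill": gap_fill, "polarity": polarity}

    bt, bg, crossings = _trapcos_burst(g_amp, f_osc, n_periods, slew)
    burst_len = bt[-1]
    T = 1.0 / f_osc
    r0 = g_amp / slew
    r = 2 * g_amp / slew

    if gap_fill:
        if burst_len + gap + r0 > t_dw_max + 1e-12:
            raise WaveformError(
                f"OG f={f_osc:g} Hz x {n_periods} periods does not fit in "
                f"T_DW={t_dw_max*1e3:g} ms"
            )
        if n_periods < 1 or T / 2 - r < 2 * r0:
            raise WaveformError("flat tops too short to splice the refocusing gap")
        # q-trajectory zeros sit at the centres of the full-width flat tops,
        # at t = r0/2 + k T/2 for k = 1 .. 2 n_periods - 1
        ks = np.arange(1, 2 * n_periods)
        zeros = r0 / 2 + ks * T / 2
        t_c = zeros[int(np.argmin(np.abs(zeros - burst_len / 2)))]
        flat_g = g_amp if np.interp(t_c, bt, bg) > 0 else -g_amp
        pre = bt < t_c - r0 / 2 - 1e-15
        post = bt > t_c + r0 / 2 + 1e-15
        sign2 = 1.0 if polarity == "matched" else -1.0
        shift = gap + r0  # extra ramp pair, flats extended by r0/2 each side
        t = np.concatenate([
            bt[pre], [t_c - r0 / 2, t_c + r0 / 2],
            [t_c + r0 / 2 + gap, t_c + 3 * r0 / 2 + gap],
            bt[post] + shift,
        ])
        g = np.concatenate([
            bg[pre], [flat_g, 0.0], [0.0, sign2 * flat_g], sign2 * bg[post],
        ])
        refocus = t_c + r0 / 2 + gap / 2
    else:
        if 2 * burst_len + gap > t_dw_max + 1e-12:
            raise WaveformError(
                f"two OG bursts of f={f_osc:g} Hz x {n_periods} periods do not "
                f"fit in T_DW={t_dw_max*1e3:g} ms"
            )
        sign2 = -1.0 if polarity == "matched" else 1.0
        shift = burst_len + gap
        t = np.concatenate([bt, bt + shift])
        g = np.concatenate([bg, sign2 * bg])
        refocus = burst_len + gap / 2
    return Waveform(t + t_start, g, dt, refocus + t_start, "OG", params)


def make_double_bipolar(
    g_amp: float,
    lobe_width: float,
    dt: float = 10e-6,
    slew: float = 600.0,
    gap: float = 6e-3,
    polarity: str = "matched",
    spacing: float = 0.0,
    t_dw_max: float = 0.090,
    t_start: float = 0.0,
) -> Waveform:
    """Two bipolar gradient pairs straddling the refocusing pulse.

    Each pair is a +/- trapezoid doublet of zero net area (lobe flat width
    set by ``lobe_width``); ``polarity`` sets the effective sign of the
    post-refocus pair, and ``spacing`` adds extra dead time on each side of
    the refocusing gap.
    """
    if lobe_width <= 0:
        raise WaveformError("lobe_width must be positive")
    if polarity not in ("matched", "unmatched"):
        raise WaveformError(f"unknown polarity {polarity!r}")
    if g_amp == 0.0:
        t = np.array([t_start, t_start + 4 * lobe_width + gap])
        return Waveform(t, np.zeros(2), dt, t_start + 2 * lobe_width + gap / 2,
                        "DB", {"G": g_amp, "lobe_width": lobe_width,
                               "polarity": polarity, "spacing": spacing})
    r0 = g_amp / slew
    r = 2 * g_amp / slew
    if lobe_width < r0 + r / 2:
        raise WaveformError("lobe_width shorter than slew-limited ramps")
    # one bipolar pair: ramp up, +flat, full ramp, -flat, ramp down (zero area)
    bt = np.array([0.0, r0, lobe_width, lobe_width + r,
                   2 * lobe_width + r - r0, 2 * lobe_width + r])
    bg = np.array([0.0, g_amp, g_amp, -g_amp, -g_amp, 0.0])
    pair_len = bt[-1]
    total = 2 * pair_len + gap + 2 * spacing
    if total > t_dw_max + 1e-12:
        raise WaveformError(
            f"double-bipolar with lobe_width={lobe_width*1e3:g} ms does not fit "
            f"in T_DW={t_dw_max*1e3:g} ms"
        )
    sign2 = -1.0 if polarity == "matched" else 1.0
    shift = pair_len + gap + 2 * spacing
    t = np.concatenate([bt, bt + shift])
    g = np.concatenate([bg, sign2 * bg])
    refocus = pair_len + spacing + gap / 2
    return Waveform(t + t_start, g, dt, refocus + t_start, "DB",
                    {"G": g_amp, "lobe_width": lobe_width,
                     "polarity": polarity, "spacing": spacing})


def pg_bvalue_closed_form(g_amp: float, delta: float, Delta: float,
                          gamma: float = GAMMA) -> float:
    """Ideal rectangular-lobe PG b-value, gamma^2 G^2 delta^2 (Delta - delta/3),
    in s/m^2. Used as an independent oracle for the numerical b integral."""
    return gamma**2 * g_amp**2 * delta**2 * (Delta - delta / 3.0)
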