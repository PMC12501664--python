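"""Interval-wise linear encoding model for temporal diffusion spectroscopy.

A spectral diffusion measurement attenuates the signal as

    ln(S0/S) = (1/pi) * int_0^inf D(omega) |Q(omega)|^2 domega,

so after subdividing the frequency axis into N contiguous intervals (the last
one open-ended) a series of M >= N measurements obeys the linear system
S = E D, where E_{m,n} = (1/pi) * int_{interval n} |Q_m|^2 domega. Interval
diffusivities follow from the Moore-Penrose pseudoinverse, D_hat = R S with
R = (E^T E)^{-1} E^T, and each interval's effective frequency profile is its
spectral response function SRF_n(omega) = sum_m R_{n,m} |Q_m(omega)|^2.

:class:`LinearEncodingModel` wraps a set of encoding spectra and an interval
scheme; its :meth:`~LinearEncodingModel.fit` returns an
:class:`IntervalDiffusivityResult` carrying estimates, reference frequencies
(SRF centroids), and noise propagation.

Units at this interface: diffusivities in mm^2/s, b-values in s/mm^2,
frequencies in Hz (rad/s internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .waveforms import EncodingSpectrum, S_MM2_PER_S_M2

TWO_PI = 2.0 * np.pi

#: condition number above which an encoding matrix is treated as rank-deficient
COND_LIMIT = 1e8


class EncodingError(ValueError):
    """Raised for ill-posed encoding systems or mismatched inputs."""


@dataclass(frozen=True)
class IntervalScheme:
    """Contiguous frequency intervals [0, w1), [w1, w2), ..., [w_{N-1}, inf).

    ``edges`` holds the N-1 interior edges plus the leading zero, ascending,
    in rad/s. The final interval is open; numerically its integrals are
    truncated at a tail cutoff chosen from the spectra it is paired with.
    """

    edges: np.ndarray  # rad/s, starts at 0, strictly increasing

    def __post_init__(self):
        e = np.asarray(self.edges, dtype=float)
        if e.ndim != 1 or len(e) < 1:
            raise EncodingError("edges must be a 1-D array")
        if e[0] != 0.0:
            raise EncodingError("first interval edge must be 0")
        if np.any(np.diff(e) <= 0):
            raise EncodingError("interval edges must be strictly increasing")
        object.__setattr__(self, "edges", e)

    @classmethod
    def from_hz(cls, edges_hz: Sequence[float]) -> "IntervalScheme":
        return cls(edges=TWO_PI * np.asarray(edges_hz, dtype=float))

    @classmethod
    def uniform(cls, width_hz: float, f_max_hz: float = 50.0) -> "IntervalScheme":
        """Primary intervals of ``width_hz`` up to ``f_max_hz`` plus the open
        tail interval, e.g. ``uniform(10)`` -> 0-10, ..., 40-50, 50+ Hz."""
        n = int(round(f_max_hz / width_hz))
        return cls.from_hz(np.linspace(0.0, f_max_hz, n + 1)[:-1].tolist() + [f_max_hz])

    @property
    def n_intervals(self) -> int:
        return len(self.edges)

    @property
    def edges_hz(self) -> np.ndarray:
        return self.edges / TWO_PI

    def labels(self) -> list[str]:
        hz = self.edges_hz
        out = [f"{hz[i]:g}-{hz[i+1]:g} Hz" for i in range(len(hz) - 1)]
        out.append(f"{hz[-1]:g}+ Hz")
        return out

    def tail_cutoff(self, spectra: Sequence[EncodingSpectrum]) -> float:
        """Numeric upper limit for the open interval: the largest coverage
        frequency among ``spectra``, at least 4x the highest edge (rad/s)."""
        cov = max(s.coverage_omega() for s in spectra)
        return max(cov, 4.0 * self.edges[-1])


def _common_grid(spectra: Sequence[EncodingSpectrum], omega_max: float):
    """Power matrix of all spectra on a shared grid up to ``omega_max``."""
    base = spectra[0].omega
    dom = base[1] - base[0]
    n = int(np.ceil(omega_max / dom)) + 1
    omega = np.arange(n) * dom
    rows = []
    for s in spectra:
        if len(s.omega) >= n and np.allclose(s.omega[:n], omega, rtol=0, atol=dom * 1e-9):
            rows.append(s.power[:n])
        else:
            rows.append(np.interp(omega, s.omega, s.power, right=0.0))
    return omega, np.vstack(rows)


def _cumulative_interval_integrals(omega, power, edges, omega_max):
    """(1/pi) integral of each row of ``power`` over every scheme interval.

    Uses exact cumulative trapezoids so intervals partition the grid without
    double counting; breakpoints are linearly interpolated.
    """
    power = np.atleast_2d(power)
    seg = (power[:, 1:] + power[:, :-1]) / 2 * np.diff(omega)
    cum = np.concatenate([np.zeros((power.shape[0], 1)), np.cumsum(seg, axis=1)], axis=1)

    def cum_at(x):
        x = np.clip(x, omega[0], omega[-1])
        i = np.clip(np.searchsorted(omega, x, side="right") - 1, 0, len(omega) - 2)
        frac = x - omega[i]
        p_x = power[:, i] + (power[:, i + 1] - power[:, i]) * frac / (omega[i + 1] - omega[i])
        return cum[:, i] + (power[:, i] + p_x) / 2 * frac

    bounds = np.concatenate([edges, [omega_max]])
    vals = np.stack([cum_at(b) for b in bounds], axis=1)
    return np.diff(vals, axis=1) / np.pi


def encoding_row(spectrum: EncodingSpectrum, scheme: IntervalScheme,
                 tail_cutoff: Optional[float] = None) -> np.ndarray:
    """Interval-integrated encoding coefficients of one spectrum (s/mm^2).

    E_n = (1/pi) * int_{interval n} |Q|^2 domega; the open interval is
    integrated up to ``tail_cutoff`` (default: the spectrum's own coverage
    limit). Coefficients sum to the b-value to within the spectral coverage.
    """
    if tail_cutoff is None:
        tail_cutoff = scheme.tail_cutoff([spectrum])
    if spectrum.omega[-1] < scheme.edges[-1]:
        raise EncodingError("spectrum grid does not cover the interval scheme")
    omega_max = min(tail_cutoff, spectrum.omega[-1])
    row = _cumulative_interval_integrals(
        spectrum.omega, spectrum.power, scheme.edges, omega_max)[0]
    return row * S_MM2_PER_S_M2


@dataclass(frozen=True)
class SRFSet:
    """Spectral response functions of all intervals on a common grid.

    ``values[n]`` is SRF_n(omega) scaled so that (1/pi) * its integral over
    interval j equals delta_{nj} (dimensionless per (rad/s) once multiplied
    by b in matching units).
    """

    omega: np.ndarray
    values: np.ndarray  # N x G
    scheme: IntervalScheme

    @property
    def centroids_hz(self) -> np.ndarray:
        """Signed-area centroid frequency of each SRF (Hz)."""
        num = np.trapezoid(self.values * self.omega, self.omega, axis=1)
        den = np.trapezoid(self.values, self.omega, axis=1)
        return num / den / TWO_PI

    @property
    def peak_hz(self) -> np.ndarray:
        return self.omega[np.argmax(self.values, axis=1)] / TWO_PI

    @property
    def fwhm_hz(self) -> np.ndarray:
        from .waveforms import _mainlobe_fwhm
        return np.array([_mainlobe_fwhm(self.omega, v) for v in self.values]) / TWO_PI

    def interval_areas(self) -> np.ndarray:
        """(1/pi) * integral of SRF_n over interval j -> approx identity."""
        return _cumulative_interval_integrals(
            self.omega, self.values, self.scheme.edges, self.omega[-1])

    def sidelobe_power(self) -> np.ndarray:
        """int SRF_n^2 outside interval n (the contamination integrals)."""
        sq = self.values**2
        per_interval = _cumulative_interval_integrals(
            self.omega, sq, self.scheme.edges, self.omega[-1]) * np.pi
        return per_interval.sum(axis=1) - np.diag(per_interval)


def reconstruction_matrix(E: np.ndarray, cond_limit: float = COND_LIMIT) -> np.ndarray:
    """Moore-Penrose pseudoinverse of the encoding matrix via SVD.

    Raises :class:`EncodingError` for rank-deficient systems, naming the
    interval combinations that are not independently encoded.
    """
    E = np.asarray(E, dtype=float)
    if E.ndim != 2:
        raise EncodingError("encoding matrix must be 2-D")
    u, s, vt = np.linalg.svd(E, full_matrices=False)
    if s[0] <= 0 or s[0] / s[-1] > cond_limit:
        null = vt[s <= s[0] / cond_limit]
        combos = [
            " + ".join(f"{c:+.2f}*D{j}" for j, c in enumerate(v) if abs(c) > 0.05)
            for v in null
        ]
        raise EncodingError(
            "rank-deficient encoding matrix (condition number "
            f"{s[0]/max(s[-1], np.finfo(float).tiny):.2e}); unencoded interval "
            f"combinations: {combos}"
        )
    return (vt.T / s) @ u.T


class LinearEncodingModel:
    """Linear interval-wise encoding model built from M encoding spectra and
    an N-interval scheme (M >= N).

    Parameters
    ----------
    spectra : encoding power spectra of the M measurements, all at the same
        protocol b-value.
    scheme : frequency interval scheme.
    tail_cutoff : numeric upper limit (rad/s) for the open interval; default
        is the coverage-based limit from :meth:`IntervalScheme.tail_cutoff`.
    """

    def __init__(self, spectra: Sequence[EncodingSpectrum], scheme: IntervalScheme,
                 tail_cutoff: Optional[float] = None):
        if len(spectra) < scheme.n_intervals:
            raise EncodingError(
                f"need at least N={scheme.n_intervals} measurements, got {len(spectra)}"
            )
        self.spectra = list(spectra)
        self.scheme = scheme
        self.tail_cutoff = (scheme.tail_cutoff(self.spectra)
                            if tail_cutoff is None else float(tail_cutoff))
        self.omega, self._power = _common_grid(self.spectra, self.tail_cutoff)
        # mm^2 unit spectra so that E, R, SRF are mutually consistent
        self._power_mm2 = self._power * S_MM2_PER_S_M2
        self.E = _cumulative_interval_integrals(
            self.omega, self._power_mm2, scheme.edges, self.omega[-1])
        self.R = reconstruction_matrix(self.E)
        self.bvalues = np.array([s.bvalue_mm2 for s in self.spectra])

    # -- system diagnostics ---------------------------------------------
    @property
    def n_measurements(self) -> int:
        return len(self.spectra)

    @property
    def n_intervals(self) -> int:
        return self.scheme.n_intervals

    def noise_amplification(self, sigma_s: float = 1.0) -> np.ndarray:
        """Per-interval diffusivity noise sigma_n^D = sigma_s * sqrt((RR^T)_nn)."""
        return sigma_s * np.sqrt(np.diag(self.R @ self.R.T))

    def noise_amplification_normalized(self) -> np.ndarray:
        """sigma_n^D / (sigma_s / b): dimensionless coefficients as reported
        per interval (1 = no amplification relative to a single measurement
        of b-matched encoding power)."""
        return self.noise_amplification() * np.mean(self.bvalues)

    def srf(self) -> SRFSet:
        return SRFSet(omega=self.omega, values=self.R @ self._power_mm2,
                      scheme=self.scheme)

    def summary(self) -> pd.DataFrame:
        srfs = self.srf()
        return pd.DataFrame({
            "interval": self.scheme.labels(),
            "encoding_power_fraction": np.max(self.E, axis=0) / np.mean(self.bvalues),
            "noise_amplification": self.noise_amplification_normalized(),
            "srf_centroid_hz": srfs.centroids_hz,
            "srf_peak_hz": srfs.peak_hz,
            "srf_sidelobe_power": srfs.sidelobe_power(),
        })

    # -- estimation ------------------------------------------------------
    def fit(self, signal: np.ndarray, sigma_s: Optional[float] = None
            ) -> "IntervalDiffusivityResult":
        """Estimate interval diffusivities from log-attenuations.

        Parameters
        ----------
        signal : length-M vector of ln(S0/S_m) (dimensionless).
        sigma_s : optional measurement noise SD of the log-attenuations, used
            to propagate per-interval diffusivity SDs.
        """
        signal = np.asarray(signal, dtype=float)
        if signal.shape != (self.n_measurements,):
            raise EncodingError(
                f"signal vector must have length M={self.n_measurements}, "
                f"got shape {signal.shape}"
            )
        if not np.all(np.isfinite(signal)):
            raise EncodingError("signal vector contains non-finite entries")
        values = self.R @ signal
        noise_sd = None if sigma_s is None else self.noise_amplification(sigma_s)
        return IntervalDiffusivityResult(model=self, values=values, noise_sd=noise_sd)

    def fit_tensor_series(self, tensors: np.ndarray) -> "IntervalTensorResult":
        """Apply the linear model element-wise to per-measurement diffusion
        tensors.

        Parameters
        ----------
        tensors : (M, 6) array of tensor elements ordered (xx, yy, zz, xy,
            xz, yz) in mm^2/s, one row per measurement. Signal entries are
            formed as b * D_(i,j),m and mapped through the reconstruction.
        """
        tensors = np.asarray(tensors, dtype=float)
        if tensors.shape != (self.n_measurements, 6):
            raise EncodingError(
                f"expected ({self.n_measurements}, 6) tensor elements, got "
                f"{tensors.shape}"
            )
        signals = self.bvalues[:, None] * tensors  # M x 6
        finite = np.all(np.isfinite(signals), axis=1)
        out = np.full((self.n_intervals, 6), np.nan)
        if np.all(finite):
            out = self.R @ signals
        return IntervalTensorResult(model=self, tensors=out)


@dataclass
class IntervalDiffusivityResult:
    """Interval-wise diffusivity estimates D_hat = R S (mm^2/s)."""

    model: LinearEncodingModel
    values: np.ndarray
    noise_sd: Optional[np.ndarray] = None
    _srfs: Optional[SRFSet] = field(default=None, repr=False)

    @property
    def ref_freqs_hz(self) -> np.ndarray:
        """SRF centroid per interval: the frequency each estimate maps to."""
        if self._srfs is None:
            self._srfs = self.model.srf()
        return self._srfs.centroids_hz

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "interval": self.model.scheme.labels(),
            "ref_freq_hz": self.ref_freqs_hz,
            "D_mm2_s": self.values,
        })
        if self.noise_sd is not None:
            df["sd_mm2_s"] = self.noise_sd
        return df


def _eigvals_sym(tensors: np.ndarray) -> np.ndarray:
    """Eigenvalues (ascending) of symmetric tensors given as 6-element rows."""
    xx, yy, zz, xy, xz, yz = tensors.T
    mats = np.empty(tensors.shape[:-1] + (3, 3))
    mats[..., 0, 0] = xx
    mats[..., 1, 1] = yy
    mats[..., 2, 2] = zz
    mats[..., 0, 1] = mats[..., 1, 0] = xy
    mats[..., 0, 2] = mats[..., 2, 0] = xz
    mats[..., 1, 2] = mats[..., 2, 1] = yz
    return np.linalg.eigvalsh(mats)


@dataclass
class IntervalTensorResult:
    """Per-interval diffusion tensors with derived MD/AD/RD."""

    model: LinearEncodingModel
    tensors: np.ndarray  # N x 6, (xx, yy, zz, xy, xz, yz)

    def eigenvalues(self) -> np.ndarray:
        return _eigvals_sym(self.tensors)

    @property
    def md(self) -> np.ndarray:
        """Mean diffusivity: mean eigenvalue (= trace / 3)."""
        return self.eigenvalues().mean(axis=1)

    @property
    def ad(self) -> np.ndarray:
        """Axial diffusivity: largest eigenvalue."""
        return self.eigenvalues()[:, -1]

    @property
    def rd(self) -> np.ndarray:
        """Radial diffusivity: mean of the two smallest eigenvalues."""
        return self.eigenvalues()[:, :2].mean(axis=1)

    def summary(self) -> pd.DataFrame:
        cols = ["xx", "yy", "zz", "xy", "xz", "yz"]
        df = pd.DataFrame(self.tensors, columns=cols)
        df.insert(0, "interval", self.model.scheme.labels())
        df["MD"] = self.md
        df["AD"] = self.ad
        df["RD"] = self.rd
        return df


def apply_to_tensor_series(model: LinearEncodingModel, tensors: np.ndarray
                           ) -> IntervalTensorResult:
    """Functional alias of :meth:`LinearEncodingModel.fit_tensor_series`."""
    return model.fit_tensor_series(tensors)


def apply_to_table(model: LinearEncodingModel, table: np.ndarray) -> np.ndarray:
    """Row-wise application of the linear model to a measurement table.

    ``table`` has one row per voxel and either M columns (scalar ADCs,
    mm^2/s) or 6*M columns (tensor elements grouped per measurement as
    xx, yy, zz, xy, xz, yz). Rows with non-finite entries yield NaN output.
    Returns N or 6*N columns accordingly.
    """
    table = np.atleast_2d(np.asarray(table, dtype=float))
    M, N = model.n_measurements, model.n_intervals
    if table.shape[1] == M:
        signals = table * model.bvalues
        out = signals @ model.R.T
    elif table.shape[1] == 6 * M:
        d = table.reshape(table.shape[0], M, 6)
        signals = d * model.bvalues[None, :, None]
        out = np.einsum("nm,vmj->vnj", model.R, signals).reshape(table.shape[0], 6 * N)
    else:
        raise EncodingError(
            f"table must have M={M} (scalar) or 6M={6*M} (tensor) columns, "
            f"got {table.shape[1]}"
        )
    bad = ~np.all(np.isfinite(table), axis=1)
    out[bad] = np.nan
    return out
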