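"""Diagnostic plots: waveforms, encoding spectra, SRFs, and simulated
D(omega) estimates at their reference frequencies."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

TWO_PI = 2.0 * np.pi


def plot_waveform(w, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 2.5))
    t = np.arange(w.n_samples) * w.dt * 1e3
    ax.plot(t, w.samples * 1e3, lw=1)
    ax.axvline(w.refocus_time * 1e3, color="0.6", ls="--", lw=0.8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("effective gradient (mT/m)")
    ax.set_title(w.describe(), fontsize=8)
    return ax


def plot_spectra(spectra, scheme=None, ax=None, f_max_hz=100.0):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for s in spectra:
        f = s.omega / TWO_PI
        keep = f <= f_max_hz
        ax.plot(f[keep], s.power[keep], lw=1, label=s.label)
    if scheme is not None:
        for e in scheme.edges_hz:
            ax.axvline(e, color="0.8", lw=0.6)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel(r"$|Q(\omega)|^2$")
    ax.legend(fontsize=6)
    return ax


def plot_srfs(srfs, ax=None, f_max_hz=100.0):
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    f = srfs.omega / TWO_PI
    keep = f <= f_max_hz
    for n, lbl in enumerate(srfs.scheme.labels()):
        ax.plot(f[keep], srfs.values[n, keep], lw=1, label=lbl)
    ax.axhline(0, color="0.7", lw=0.6)
    for e in srfs.scheme.edges_hz:
        ax.axvline(e, color="0.85", lw=0.6)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("SRF")
    ax.legend(fontsize=6)
    return ax


def plot_estimates(model_curve, report, scenario, ax=None, f_max_hz=80.0):
    """D(omega) curve with linear-model and single-frequency estimate
    markers at their reference frequencies."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    f = np.linspace(0, f_max_hz, 400)
    ax.plot(f, model_curve(TWO_PI * f), color="C0", lw=1.2, label="D(omega)")
    lin = report.linear[report.linear.scenario == scenario]
    sf = report.single[report.single.scenario == scenario]
    ax.plot(lin.ref_freq_hz, lin.d_hat, "o", color="C1", ms=4,
            label="linear encoding model")
    ax.plot(sf.assigned_freq_hz, sf.d_hat, "s", color="C2", ms=4,
            label="single-frequency")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel(r"D (mm$^2$/s)")
    ax.set_title(scenario, fontsize=9)
    ax.legend(fontsize=6)
    return ax
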