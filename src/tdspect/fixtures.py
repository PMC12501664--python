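"""Deterministic toy objects for tests and demonstrations.

The toy library spans all three waveform families at a coarsened frequency
resolution so exhaustive-enumeration cross-checks of the greedy selection
run in seconds; the synthetic measurement tables are forward-model products
E D (plus optional seeded noise), so round-trip recovery is exact by
construction.
"""

from __future__ import annotations

import numpy as np

from .encoding import IntervalScheme, LinearEncodingModel
from .selection import SpectrumLibrary, _common_grid
from .waveforms import (HardwareConstraints, S_MM2_PER_S_M2,
                        make_double_bipolar, make_og_trapcos, make_pg,
                        scale_to_b)

TOY_CONSTRAINTS = HardwareConstraints(dt=2e-5)


def toy_waveforms(n_members: int = 10, constraints: HardwareConstraints = TOY_CONSTRAINTS):
    """Up to 12 feasible waveforms spanning PG, OG and double-bipolar."""
    c = constraints
    recipes = [
        lambda: make_pg(c.g_max, 10e-3, 40e-3, dt=c.dt, slew=c.slew_max),
        lambda: make_pg(c.g_max, 20e-3, 55e-3, dt=c.dt, slew=c.slew_max),
        lambda: make_og_trapcos(20, 1, c.g_max, dt=c.dt, slew=c.slew_max,
                                gap=c.refocus_gap),
        lambda: make_og_trapcos(30, 2, c.g_max, dt=c.dt, slew=c.slew_max,
                                gap=c.refocus_gap),
        lambda: make_double_bipolar(c.g_max, 16e-3, dt=c.dt, slew=c.slew_max,
                                    gap=c.refocus_gap),
        lambda: make_og_trapcos(40, 3, c.g_max, dt=c.dt, slew=c.slew_max,
                                gap=c.refocus_gap),
        lambda: make_og_trapcos(45, 2, c.g_max, dt=c.dt, slew=c.slew_max,
                                gap=c.refocus_gap, polarity="unmatched"),
        lambda: make_double_bipolar(c.g_max, 10e-3, dt=c.dt, slew=c.slew_max,
                                    gap=c.refocus_gap, polarity="unmatched"),
        lambda: make_og_trapcos(55, 4, c.g_max, dt=c.dt, slew=c.slew_max,
                                gap=c.refocus_gap),
        lambda: make_og_trapcos(35, 1, c.g_max, dt=c.dt, slew=c.slew_max,
                                gap=c.refocus_gap, gap_fill=False),
        lambda: make_og_trapcos(25, 1, c.g_max, dt=c.dt, slew=c.slew_max,
                                gap=c.refocus_gap),
        lambda: make_og_trapcos(50, 3, c.g_max, dt=c.dt, slew=c.slew_max,
                                gap=c.refocus_gap),
    ]
    out = []
    for recipe in recipes[:n_members]:
        out.append(scale_to_b(recipe(), c.b_value, constraints=c))
    return out


def toy_library(n_members: int = 10, df: float = 0.5,
                constraints: HardwareConstraints = TOY_CONSTRAINTS
                ) -> SpectrumLibrary:
    """Small deterministic spectrum library (coarse grid for speed)."""
    waveforms = toy_waveforms(n_members, constraints)
    spectra = [w.spectrum(df=df) for w in waveforms]
    omega_max = max(s.coverage_omega() for s in spectra)
    omega, power = _common_grid(spectra, omega_max)
    return SpectrumLibrary(
        omega=omega, power=power * S_MM2_PER_S_M2,
        bvalue=float(np.mean([s.bvalue_mm2 for s in spectra])),
        waveforms=waveforms,
        provenance=[{"family": w.family, **w.params} for w in waveforms],
    )


def toy_scheme(n_primary: int = 2, width_hz: float = 25.0) -> IntervalScheme:
    return IntervalScheme.uniform(width_hz, n_primary * width_hz)


def toy_measurement_table(
    model: LinearEncodingModel,
    n_rows: int = 20,
    tensor: bool = False,
    noise_sd: float = 0.0,
    seed: int = 1234,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic per-voxel measurement tables from the forward model E D.

    Returns ``(table, truth)``: the per-measurement ADC (or tensor-element)
    table and the interval ground truth it was synthesised from.
    """
    rng = np.random.default_rng(seed)
    N, M = model.n_intervals, model.n_measurements
    base = 0.7e-3 + 1.5e-3 * rng.random((n_rows, N))
    d_interval = np.sort(base, axis=1)  # increasing D(omega), tissue-like
    if tensor:
        diag_scale = np.array([1.3, 1.0, 0.7])
        truth = np.zeros((n_rows, N, 6))
        truth[:, :, :3] = d_interval[:, :, None] * diag_scale
        signals = np.einsum("mn,vnj->vmj", model.E, truth)
        table = signals / np.mean(model.bvalues)
        table = table.reshape(n_rows, 6 * M)
        truth = truth.reshape(n_rows, 6 * N)
    else:
        signals = d_interval @ model.E.T
        table = signals / np.mean(model.bvalues)
        truth = d_interval
    if noise_sd > 0:
        table = table + noise_sd * rng.standard_normal(table.shape)
    return table, truth
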