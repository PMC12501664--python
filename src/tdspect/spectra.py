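"""Theoretical frequency-dependent diffusivity models D(omega).

Two model families cover the standard simulation scenarios for
frequency-dependent diffusion in tissue:

* power-law dispersion, D(omega) = D0 + Lambda * omega^theta, arising from
  short-range structural disorder (theta = 0.5 in one dimension, theta = 1
  in two dimensions);
* restricted diffusion inside impermeable spheres, from the eigenmode
  expansion of the velocity autocorrelation spectrum, optionally mixed with
  a frequency-independent extracellular compartment.

Diffusivities are in mm^2/s and omega in rad/s. For the power law,
``frequency_unit`` selects whether Lambda multiplies angular frequency
(rad/s, default) or ordinary frequency (Hz); the choice only rescales
Lambda.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Dict

import numpy as np
from scipy.optimize import brentq
from scipy.special import spherical_jn

TWO_PI = 2.0 * np.pi

UM2_TO_MM2 = 1e-6  # Lambda tables are quoted in um^2 s^(theta-1) ... um^2/s^theta


class SpectrumModelError(ValueError):
    pass


def power_law(omega, d0: float, lam_um2: float, theta: float,
              frequency_unit: str = "rad/s"):
    """Power-law dispersion D(omega) = D0 + Lambda * omega^theta (mm^2/s).

    Parameters
    ----------
    omega : angular frequency grid (rad/s), non-negative.
    d0 : zero-frequency diffusivity (mm^2/s).
    lam_um2 : dispersion coefficient Lambda in um^2 / s^(1-theta) per
        (frequency unit)^theta; converted internally to mm^2.
    theta : dispersion exponent (0.5 for 1-D, 1 for 2-D short-range disorder).
    frequency_unit : "rad/s" (Lambda multiplies omega^theta) or "Hz"
        (Lambda multiplies (omega / 2 pi)^theta).
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise SpectrumModelError("omega must be non-negative")
    if frequency_unit == "rad/s":
        x = omega
    elif frequency_unit == "Hz":
        x = omega / TWO_PI
    else:
        raise SpectrumModelError(f"unknown frequency unit {frequency_unit!r}")
    return d0 + lam_um2 * UM2_TO_MM2 * np.power(x, theta)


@lru_cache(maxsize=8)
def sphere_eigenvalues(k: int) -> np.ndarray:
    """First ``k`` positive roots mu of d/dx j_1(x) = 0.

    These are the radial eigenvalues of diffusion in an impermeable sphere
    with reflecting boundary. Roots are simple and separated by roughly pi;
    they are bracketed by a scan and polished with Brent's method.
    """
    f = lambda x: spherical_jn(1, x, derivative=True)
    grid = np.linspace(0.5, (k + 2) * np.pi, int((k + 2) * np.pi / 0.01))
    vals = f(grid)
    roots = []
    for i in np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]:
        roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-14))
        if len(roots) == k:
            break
    if len(roots) < k:
        raise SpectrumModelError(f"found only {len(roots)} of {k} sphere eigenvalues")
    return np.array(roots)


def sphere_spectrum(omega, radius_um: float, d_in: float, k_modes: int = 20,
                    tail_completion: bool = True):
    """Velocity-autocorrelation spectrum of diffusion restricted in an
    impermeable sphere (mm^2/s).

    D(omega) = sum_k B_k a_k D_in omega^2 / (a_k^2 D_in^2 + omega^2), with
    a_k = mu_k^2 / r^2 and B_k = 2 r^2 / (mu_k^2 (mu_k^2 - 2)), mu_k the
    k-th positive root of j_1'(x) = 0. The spectrum vanishes as omega^2 at
    low frequency and approaches the intrinsic D_in as omega -> inf.

    Parameters
    ----------
    omega : angular frequency (rad/s).
    radius_um : sphere radius (um).
    d_in : intracellular (intrinsic) diffusivity (mm^2/s).
    k_modes : number of explicit eigenmode terms.
    tail_completion : because B_k a_k = 2 D_in / (mu_k^2 - 2) and
        sum_k 2/(mu_k^2 - 2) = 1 (the free-diffusion limit), the weight lost
        by truncating after ``k_modes`` is known exactly; by default it is
        lumped into one extra term at the (k_modes+1)-th eigenmode rate so
        D(inf) = D_in is preserved to the identity's accuracy. The
        correction is omega^2-suppressed at low frequency.
    """
    if radius_um <= 0 or d_in <= 0:
        raise SpectrumModelError("radius and D_in must be positive")
    if k_modes < 1:
        raise SpectrumModelError("need at least one eigenmode")
    omega = np.asarray(omega, dtype=float)
    r_mm = radius_um * 1e-3
    mu = sphere_eigenvalues(k_modes + 1)
    a = mu**2 / r_mm**2              # 1/mm^2
    weight = 2.0 / (mu**2 - 2.0)     # B_k a_k / D_in
    if tail_completion:
        weight[-1] = 1.0 - np.sum(weight[:-1])
    else:
        a, weight = a[:-1], weight[:-1]
    w2 = omega[..., None] ** 2
    return np.sum(weight * d_in * w2 / (a**2 * d_in**2 + w2), axis=-1)


def two_compartment(omega, radius_um: float, d_in: float, d_ex: float,
                    f_in: float, f_ex: float, k_modes: int = 20):
    """Spherical cells in extracellular water:
    D(omega) = f_in * D_sphere(omega) + f_ex * D_ex."""
    if abs(f_in + f_ex - 1.0) > 1e-9:
        raise SpectrumModelError("compartment fractions must sum to 1")
    return f_in * sphere_spectrum(omega, radius_um, d_in, k_modes) + f_ex * d_ex


@dataclass(frozen=True)
class DiffusionSpectrumModel:
    """An evaluable D(omega) with a name and parameter record."""

    name: str
    kind: str  # "power_law" | "sphere_compartment"
    params: dict
    _func: Callable[[np.ndarray], np.ndarray]

    def __call__(self, omega):
        return self._func(np.asarray(omega, dtype=float))


def scenario(name: str, frequency_unit: str = "rad/s",
             k_modes: int = 20) -> DiffusionSpectrumModel:
    """Registry of the four standard simulation scenarios.

    1. short-range disorder in 1-D: D0 = 7e-4 mm^2/s, theta = 0.5,
       Lambda = 8.5 um^2/s^0.5
    2. short-range disorder in 2-D: D0 = 7e-4 mm^2/s, theta = 1,
       Lambda = 0.48 um^2
    3. impermeable spheres r = 5 um in extracellular water
       (f_in = f_ex = 0.5, D_in = 3e-3, D_ex = 2.2e-3 mm^2/s)
    4. as scenario 3 with r = 10 um
    """
    defs: Dict[str, tuple] = {
        "scenario1": ("power_law", dict(d0=7e-4, lam_um2=8.5, theta=0.5)),
        "scenario2": ("power_law", dict(d0=7e-4, lam_um2=0.48, theta=1.0)),
        "scenario3": ("sphere_compartment",
                      dict(radius_um=5.0, d_in=3e-3, d_ex=2.2e-3,
                           f_in=0.5, f_ex=0.5)),
        "scenario4": ("sphere_compartment",
                      dict(radius_um=10.0, d_in=3e-3, d_ex=2.2e-3,
                           f_in=0.5, f_ex=0.5)),
    }
    if name not in defs:
        raise SpectrumModelError(
            f"unknown scenario {name!r}; choose from {sorted(defs)}")
    kind, base = defs[name]
    if kind == "power_law":
        func = lambda w, p=dict(base): power_law(w, frequency_unit=frequency_unit, **p)
        params = dict(base, frequency_unit=frequency_unit)
    else:
        func = lambda w, p=dict(base): two_compartment(w, k_modes=k_modes, **p)
        params = dict(base, k_modes=k_modes)
    return DiffusionSpectrumModel(name=name, kind=kind, params=params, _func=func)


def all_scenarios(frequency_unit: str = "rad/s", k_modes: int = 20):
    return [scenario(f"scenario{i}", frequency_unit, k_modes) for i in (1, 2, 3, 4)]
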