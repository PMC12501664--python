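"""Encoding-spectrum library construction and greedy subset selection.

A library of experimentally feasible gradient waveforms (pulsed gradient,
trapezoidal-cosine oscillating gradient, double-bipolar) is generated over
parameter grids, normalised to a common b-value, and scored against an
interval scheme with the objective

    O = [ sum_n (R R^T)_nn ] x [ sum_n int_{outside interval n} SRF_n^2 ],

the product of total noise amplification and total spectral contamination.
Subsets are selected per measurement count M by two greedy variants: pruning
(remove the member whose exclusion minimises O, from the full library down
to N) and growing (exhaustive best pair, then add the member minimising O).
The winner per M is the lower-objective set of the two.

The interval-restricted Gram matrices G^{(j)}_{mm'} = int_{interval j}
P_m P_m' domega are cached once per (library, scheme); all greedy candidate
evaluations are rank-one updates on top of them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .encoding import (IntervalScheme, _common_grid,
                       _cumulative_interval_integrals)
from .waveforms import (EncodingSpectrum, HardwareConstraints, Waveform,
                        WaveformError, make_double_bipolar, make_og_trapcos,
                        make_pg, scale_to_b, S_MM2_PER_S_M2)

logger = logging.getLogger(__name__)

INFEASIBLE = np.inf


class SelectionError(ValueError):
    pass


@dataclass(frozen=True)
class LibraryGrids:
    """Parameter grids iterated when building the waveform library.

    Times in seconds, frequencies in Hz. Defaults span the protocol envelope
    of a 90 ms encoding window; the exact grids are a package choice.
    """

    pg_delta: tuple = tuple(np.arange(5e-3, 41e-3, 5e-3))
    pg_Delta_step: float = 5e-3
    og_f_osc: tuple = tuple(range(15, 61))
    og_n_periods: tuple = (1, 2, 3, 4, 5)
    db_lobe_widths: tuple = tuple(np.arange(2e-3, 21e-3, 2e-3))


@dataclass
class SpectrumLibrary:
    """Normalised encoding spectra on a common frequency grid.

    ``power`` holds |Q(omega)|^2 rows in mm^2 units (power * 1e-6) so that
    interval integrals are b-values in s/mm^2; all members share ``bvalue``.
    """

    omega: np.ndarray            # common grid (rad/s)
    power: np.ndarray            # K x G, mm^2-unit spectral power
    bvalue: float                # shared b (s/mm^2)
    waveforms: List[Waveform]
    provenance: List[dict]
    n_rejected: int = 0
    _cache: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return self.power.shape[0]

    def spectra(self, indices: Optional[Sequence[int]] = None) -> List[EncodingSpectrum]:
        idx = range(len(self)) if indices is None else indices
        return [
            EncodingSpectrum(
                omega=self.omega, power=self.power[i] / S_MM2_PER_S_M2,
                bvalue=self.bvalue / S_MM2_PER_S_M2,
                label=self.waveforms[i].describe(),
                family=self.waveforms[i].family,
                params=dict(self.waveforms[i].params),
            )
            for i in idx
        ]

    # -- scheme-specific caches -----------------------------------------
    def coefficients(self, scheme: IntervalScheme) -> np.ndarray:
        """K x N interval encoding coefficients (s/mm^2)."""
        key = ("coef", tuple(scheme.edges))
        if key not in self._cache:
            self._cache[key] = _cumulative_interval_integrals(
                self.omega, self.power, scheme.edges, self.omega[-1])
        return self._cache[key]

    def grams(self, scheme: IntervalScheme) -> List[np.ndarray]:
        """Interval-restricted Gram matrices G^{(j)} = int_j P P^T domega."""
        key = ("gram", tuple(scheme.edges))
        if key not in self._cache:
            bounds = np.concatenate([scheme.edges, [self.omega[-1]]])
            # trapezoid weights per grid point, then split at interval bounds
            w = np.empty_like(self.omega)
            d = np.diff(self.omega)
            w[0] = d[0] / 2
            w[-1] = d[-1] / 2
            w[1:-1] = (d[:-1] + d[1:]) / 2
            grams = []
            for j in range(scheme.n_intervals):
                lo, hi = bounds[j], bounds[j + 1]
                mask = (self.omega >= lo) & (self.omega <= hi)
                # interior trapezoid weights; boundary points shared between
                # neighbouring intervals get half weight on each side
                wj = np.zeros_like(w)
                idx = np.nonzero(mask)[0]
                if len(idx) > 1:
                    sub_d = np.diff(self.omega[idx])
                    wj[idx[0]] = sub_d[0] / 2
                    wj[idx[-1]] = sub_d[-1] / 2
                    wj[idx[1:-1]] = (sub_d[:-1] + sub_d[1:]) / 2
                a = self.power * np.sqrt(wj)
                grams.append(a @ a.T)
            self._cache[key] = grams
        return self._cache[key]


def build_library(
    constraints: HardwareConstraints,
    grids: LibraryGrids = LibraryGrids(),
    df: float = 0.1,
    f_eval_max: float = 2000.0,
) -> SpectrumLibrary:
    """Generate all feasible waveforms over the parameter grids, normalise
    each to the protocol b-value, and collect their spectra on a common grid.

    Members that cannot reach the protocol b within the amplitude/slew/
    duration constraints are silently excluded (a count is logged).
    """
    c = constraints
    candidates: List[Waveform] = []

    for delta in grids.pg_delta:
        ramp = c.g_max / c.slew_max
        Delta_min = delta + ramp + c.refocus_gap
        Delta_max = c.t_dw_max - delta - ramp
        for Delta in np.arange(Delta_min, Delta_max + 1e-9, grids.pg_Delta_step):
            try:
                candidates.append(make_pg(c.g_max, delta, float(Delta), dt=c.dt,
                                          slew=c.slew_max))
            except WaveformError:
                pass

    for f_osc in grids.og_f_osc:
        for n in grids.og_n_periods:
            for gap_fill in (True, False):
                for polarity in ("matched", "unmatched"):
                    try:
                        candidates.append(make_og_trapcos(
                            float(f_osc), n, c.g_max, dt=c.dt, slew=c.slew_max,
                            gap=c.refocus_gap, gap_fill=gap_fill,
                            polarity=polarity, t_dw_max=c.t_dw_max))
                    except WaveformError:
                        pass

    for width in grids.db_lobe_widths:
        for polarity in ("matched", "unmatched"):
            try:
                candidates.append(make_double_bipolar(
                    c.g_max, float(width), dt=c.dt, slew=c.slew_max,
                    gap=c.refocus_gap, polarity=polarity,
                    t_dw_max=c.t_dw_max))
            except WaveformError:
                pass

    members: List[Waveform] = []
    rejected = 0
    for w in candidates:
        try:
            members.append(scale_to_b(w, c.b_value, constraints=c))
        except WaveformError:
            rejected += 1
    if not members:
        raise SelectionError(
            "empty library: no waveform reaches the protocol b-value under "
            "the stated constraints"
        )
    logger.info("library: %d members, %d infeasible candidates excluded",
                len(members), rejected)

    spectra = [w.spectrum(df=df, f_max=f_eval_max) for w in members]
    omega_max = max(s.coverage_omega() for s in spectra)
    omega, power = _common_grid(spectra, omega_max)
    return SpectrumLibrary(
        omega=omega,
        power=power * S_MM2_PER_S_M2,
        bvalue=float(np.mean([s.bvalue_mm2 for s in spectra])),
        waveforms=members,
        provenance=[{"family": w.family, **w.params} for w in members],
        n_rejected=rejected,
    )


# ---------------------------------------------------------------------------
# objective function
# ---------------------------------------------------------------------------

def objective(
    member_indices: Sequence[int],
    library: SpectrumLibrary,
    scheme: IntervalScheme,
    cond_limit: float = 1e10,
) -> Tuple[float, float, float]:
    """Evaluate the selection objective for a subset of library members.

    Returns ``(O, noise_term, contamination_term)`` with
    noise = sum_n (R R^T)_nn and contamination = sum_n of the squared-SRF
    integral outside interval n. Rank-deficient subsets (including M < N
    sets leaving an interval without encoding power) score +inf.
    """
    idx = np.asarray(member_indices, dtype=int)
    if len(idx) < 1:
        raise SelectionError("empty subset")
    E = library.coefficients(scheme)[idx]
    grams = library.grams(scheme)
    n_int = scheme.n_intervals
    if np.any(np.max(np.abs(E), axis=0) <= 0):
        return INFEASIBLE, INFEASIBLE, INFEASIBLE
    s = np.linalg.svd(E, compute_uv=False)
    rank_needed = min(E.shape)
    if s[rank_needed - 1] <= s[0] / cond_limit:
        return INFEASIBLE, INFEASIBLE, INFEASIBLE
    R = np.linalg.pinv(E)
    noise = float(np.sum(R * R))
    g_sub = [g[np.ix_(idx, idx)] for g in grams]
    g_tot = sum(g_sub)
    contamination = 0.0
    for n in range(n_int):
        g_out = g_tot - g_sub[n]
        contamination += float(R[n] @ g_out @ R[n])
    return noise * contamination, noise, contamination


@dataclass
class SelectionResult:
    """Per-M greedy selections: member indices, objective, and its terms."""

    variant: str  # "prune" | "grow"
    per_m: Dict[int, dict]  # M -> {indices, objective, noise, contamination}

    def best(self, m: int) -> Tuple[int, ...]:
        return tuple(self.per_m[m]["indices"])

    def objective_at(self, m: int) -> float:
        return self.per_m[m]["objective"]

    @property
    def m_values(self) -> List[int]:
        return sorted(self.per_m)


def _contamination_matrices(library, scheme, idx):
    """Subset Gram matrices and their E-projections for fast updates."""
    E = library.coefficients(scheme)[idx]
    grams = [g[np.ix_(idx, idx)] for g in library.grams(scheme)]
    return E, grams


def _evaluate_removals(E, grams, cond_floor=1e-12):
    """Objective after removing each row of E, via rank-one downdates.

    Returns (objectives, noise_terms, contamination_terms) arrays of length
    M. Requires M - 1 >= N.
    """
    M, N = E.shape
    W = np.linalg.inv(E.T @ E)
    U = E @ W                                  # rows e_m^T W
    d = 1.0 - np.einsum("mn,mn->m", U, E)      # 1 - e_m^T W e_m
    valid = d > cond_floor
    d_safe = np.where(valid, d, 1.0)
    # W' per candidate: W + u u^T / d
    Wp = W[None] + U[:, :, None] * U[:, None, :] / d_safe[:, None, None]
    noise = np.trace(W) + np.einsum("mn,mn->m", U, U) / d_safe

    g_tot = sum(grams)
    GE_tot = g_tot @ E
    H_tot = E.T @ GE_tot
    contamination = np.zeros(M)
    for n, g in enumerate(grams):
        GE = g @ E
        H = E.T @ GE
        Ho = H_tot - H
        GEo = GE_tot - GE
        go_diag = np.diag(g_tot) - np.diag(g)
        # H'_out per candidate m: Ho - e_m (GEo_m)^T - GEo_m e_m^T + go_mm e_m e_m^T
        v = Wp[:, n, :]                        # M x N rows of W'
        t1 = np.einsum("mi,mij,mj->m", v, np.broadcast_to(Ho, (M, N, N)), v)
        ve = np.einsum("mi,mi->m", v, E)
        vg = np.einsum("mi,mi->m", v, GEo)
        contamination += t1 - 2 * ve * vg + go_diag * ve**2
    obj = np.where(valid, noise * contamination, INFEASIBLE)
    return obj, np.where(valid, noise, INFEASIBLE), \
        np.where(valid, contamination, INFEASIBLE)


def greedy_prune(
    library: SpectrumLibrary,
    scheme: IntervalScheme,
    m_min: Optional[int] = None,
) -> SelectionResult:
    """Whittle the library down one member at a time.

    Each iteration evaluates the objective for all single-member exclusions
    and keeps the subset with the minimum value (ties broken by removing the
    lowest library index). The trace of locally optimal sets is recorded for
    every M from the full library size down to ``m_min`` (default N); sets
    are nested across M within the run.
    """
    N = scheme.n_intervals
    m_min = N if m_min is None else max(m_min, N)
    K = len(library)
    if K < N:
        raise SelectionError(f"library of {K} members cannot encode {N} intervals")
    idx = np.arange(K)
    per_m: Dict[int, dict] = {}
    o, n_t, c_t = objective(idx, library, scheme)
    per_m[K] = dict(indices=tuple(int(i) for i in idx), objective=o,
                    noise=n_t, contamination=c_t)

    while len(idx) > m_min:
        E, grams = _contamination_matrices(library, scheme, idx)
        if len(idx) - 1 >= N:
            objs, noises, contams = _evaluate_removals(E, grams)
        else:  # pragma: no cover - m_min >= N prevents this
            break
        k = int(np.argmin(objs))  # argmin returns the first (lowest) index on ties
        if not np.isfinite(objs[k]):
            logger.warning("prune stopped at M=%d: all removals rank-deficient",
                           len(idx))
            break
        idx = np.delete(idx, k)
        # re-evaluate exactly to avoid accumulation of update error
        o, n_t, c_t = objective(idx, library, scheme)
        per_m[len(idx)] = dict(indices=tuple(int(i) for i in idx), objective=o,
                               noise=n_t, contamination=c_t)
        logger.debug("prune M=%d objective=%.6e", len(idx), o)
    return SelectionResult(variant="prune", per_m=per_m)


def _best_pair(library: SpectrumLibrary, scheme: IntervalScheme,
               chunk: int = 200_000) -> Tuple[int, int]:
    """Exhaustive search for the pair of members minimising the objective.

    For M = 2 < N the pseudoinverse acts on the rank-supported subspace:
    R = E^T (E E^T)^{-1}, noise = trace((E E^T)^{-1}) and the contamination
    sum is evaluated with the same 2 x 2 inverse, all in closed form.
    """
    E = library.coefficients(scheme)
    grams = library.grams(scheme)
    g_tot = sum(grams)
    K = len(library)
    ia_all, ib_all = np.triu_indices(K, k=1)
    best = (np.inf, None)
    for s in range(0, len(ia_all), chunk):
        ia = ia_all[s:s + chunk]
        ib = ib_all[s:s + chunk]
        ea, eb = E[ia], E[ib]
        aa = np.einsum("pn,pn->p", ea, ea)
        bb = np.einsum("pn,pn->p", eb, eb)
        ab = np.einsum("pn,pn->p", ea, eb)
        det = aa * bb - ab**2
        good = det > np.finfo(float).tiny * 1e6
        det_safe = np.where(good, det, 1.0)
        noise = (aa + bb) / det_safe
        # R row n = inv([[aa,ab],[ab,bb]]) @ [ea_n, eb_n]
        x = (bb[:, None] * ea - ab[:, None] * eb) / det_safe[:, None]
        y = (aa[:, None] * eb - ab[:, None] * ea) / det_safe[:, None]
        contamination = np.zeros(len(ia))
        for n, g in enumerate(grams):
            gaa = g_tot[ia, ia] - g[ia, ia]
            gbb = g_tot[ib, ib] - g[ib, ib]
            gab = g_tot[ia, ib] - g[ia, ib]
            contamination += (x[:, n]**2 * gaa + 2 * x[:, n] * y[:, n] * gab
                              + y[:, n]**2 * gbb)
        obj = np.where(good, noise * contamination, INFEASIBLE)
        k = int(np.argmin(obj))
        if obj[k] < best[0]:
            best = (float(obj[k]), (int(ia[k]), int(ib[k])))
    if best[1] is None:
        raise SelectionError("no feasible pair found")
    return best[1]


def greedy_grow(
    library: SpectrumLibrary,
    scheme: IntervalScheme,
    m_max: Optional[int] = None,
) -> SelectionResult:
    """Grow a selection from the exhaustive best pair.

    Each subsequent iteration adds the single remaining member that minimises
    the objective (ties broken by lowest library index). For M below the
    number of intervals the objective uses the pseudoinverse on the
    rank-supported subspace, guarded by +inf when an interval combination is
    unencoded; estimates are fully determined only once M >= N.
    """
    K = len(library)
    if K < 2:
        raise SelectionError("grow requires at least two library members")
    N = scheme.n_intervals
    m_max = min(K, (N + 6) if m_max is None else m_max)
    pair = _best_pair(library, scheme)
    idx = list(pair)
    per_m: Dict[int, dict] = {}
    o, n_t, c_t = objective(idx, library, scheme)
    per_m[2] = dict(indices=tuple(idx), objective=o, noise=n_t, contamination=c_t)
    while len(idx) < m_max:
        remaining = np.setdiff1d(np.arange(K), idx)
        objs = np.full(len(remaining), INFEASIBLE)
        for i, cand in enumerate(remaining):
            objs[i], _, _ = objective(idx + [int(cand)], library, scheme)
        k = int(np.argmin(objs))
        if not np.isfinite(objs[k]):
            logger.warning("grow stopped at M=%d: no feasible extension", len(idx))
            break
        idx.append(int(remaining[k]))
        o, n_t, c_t = objective(idx, library, scheme)
        per_m[len(idx)] = dict(indices=tuple(idx), objective=o,
                               noise=n_t, contamination=c_t)
        logger.debug("grow M=%d objective=%.6e", len(idx), o)
    return SelectionResult(variant="grow", per_m=per_m)


def select_best(prune: SelectionResult, grow: SelectionResult
                ) -> Dict[int, dict]:
    """Per-M winner: the lower-objective set among both greedy variants."""
    out: Dict[int, dict] = {}
    for m in sorted(set(prune.per_m) | set(grow.per_m)):
        entries = []
        if m in prune.per_m:
            entries.append(dict(prune.per_m[m], variant="prune"))
        if m in grow.per_m:
            entries.append(dict(grow.per_m[m], variant="grow"))
        out[m] = min(entries, key=lambda e: e["objective"])
    return out
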