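# Methods

This note records the model, the numerical choices, and the assumptions
behind `tdspect`, in the spirit of a package's model documentation. All
internal computation is SI (T/m, s, rad/s, rad/m, s/m²); interfaces use
mm²/s for diffusivities, s/mm² for b-values, and Hz for frequencies.

## Signal model and the interval-wise linear encoding

Under the Gaussian phase approximation, a diffusion-weighted measurement
with q-space trajectory q(t) = γ∫g(t')dt' attenuates as
ln(S₀/S) = (1/π)∫₀^∞ D(ω)|Q(ω)|² dω with Q(ω) the Fourier transform of
q(t). Partitioning the frequency axis into N contiguous intervals — the
last one open-ended — and assuming D(ω) is representable by one value per
interval gives the linear system S = E D, with E the M×N matrix of
interval-integrated encoding powers. Estimation uses the Moore–Penrose
pseudoinverse R (computed by SVD, never by explicit (EᵀE)⁻¹Eᵀ; condition
numbers above 10⁸ raise an error naming the unencoded interval
combinations). Spectral response functions SRF_n = Σ_m R_nm|Q_m|² describe
the true frequency profile of each interval estimate; their interval-wise
areas are exactly δ_nj (a consequence of R E = I), they oscillate around
zero outside their interval, and each estimate is reported at its SRF's
signed centroid rather than at the interval centre.

The boxcar representation is an approximation: within an interval the
estimate is a power-weighted average of D(ω), so comparisons against ground
truth are made at the SRF centroid. This is also how accuracy is scored in
the simulation harness.

## Waveforms

Waveforms are stored as exact piecewise-linear breakpoints in the
*effective-gradient* convention (post-refocusing sign already inverted).
Raster samples are per-step averages of the exact curve, so the refocusing
integral ∫g dt = 0 holds to float precision and |q(T)|/max|q| < 10⁻⁶ for
every emitted waveform. Amplitude and slew are checked on the exact
breakpoints; infeasible requests raise — there is no clipping.

* **PG**: two trapezoidal lobes of area G·δ whose leading edges are Δ
  apart; δ is measured start-of-ramp-up to start-of-ramp-down. The
  closed-form rectangular b-value γ²G²δ²(Δ−δ/3) serves as an independent
  oracle in tests (with near-instant ramps).
* **Trapezoidal-cosine OG**: flat tops follow the sign of cos(2πf t) with
  slew-limited transitions; the end flats are extended by half a ramp so
  the net area vanishes exactly. Two realisations of the refocusing dead
  time are provided. *Gap-filled*: the oscillation is spliced at the
  q-trajectory zero crossing nearest the waveform centre, with the adjacent
  flat tops extended by half a ramp so q enters and leaves the gap at
  exactly zero — q-periodicity is bridged across the gap. Since each half
  then has zero net area, both matched (phase-continuing) and unmatched
  (sign-flipped) post-refocus polarities refocus and give distinct
  |Q(ω)|² lineshapes. *Two-burst*: one complete zero-area burst per side of
  the pulse, with the effective sign of the second burst set by the
  polarity. These constructions are this package's realisations; published
  gap-filled/polarity-matched designs are not specified to reproducible
  detail, and the selection stage operates only on the resulting spectra,
  so any refocused, constraint-satisfying realisation is admissible.
* **Double-bipolar**: one +/− trapezoid pair per side of the pulse
  (a half+half-period oscillation); wide lobes with unmatched polarity
  reach spectral centroids below 10 Hz, covering the range PGs map to 0 Hz.

The refocusing dead time is not part of the published protocol; the default
`refocus_gap` is 6 ms, a realistic 180°-plus-crusher duration for a
spin-echo sequence of this class, and is configurable.

Split waveforms (a gap between two coherent halves) show interference
structure in |Q(ω)|²: the spectral peak can sit several Hz off the nominal
oscillation frequency while the centroid stays close to it. This is
physical, not an artifact, and is why assigned frequencies use the centroid.

## Spectra and quadrature

Encoding spectra are computed by zero-padded FFT of the sampled q(t) at a
default resolution of 0.1 Hz (raster 10 µs) and truncated where the
cumulative power reaches 99.99% of the total. Parseval's identity,
(1/π)∫₀^∞|Q|²dω = ∫q²dt, holds within 0.1% for every stored spectrum and is
asserted across the library. Interval integrals use cumulative trapezoids
with edge interpolation, so the intervals partition the grid without double
counting; the open interval is truncated at a tail cutoff equal to the
largest coverage frequency in the spectrum set (at least 4× the highest
edge). Attenuation integrals add the exactly known residual power times
D at the grid end, which makes constant-D attenuation equal b·D to
quadrature precision and bounds the truncation bias for saturating spectra;
a warning fires when this correction exceeds 10⁻³ of the integral.

## Library and greedy selection

The library iterates parameter grids inside the hardware envelope
(defaults: G_max = 200 mT/m, slew 600 T/m/s, T_DW ≤ 90 ms, b = 1000 s/mm²):
PG δ ∈ {5,…,40} ms with Δ in 5-ms steps; OG f ∈ {15,…,60} Hz ×
1–5 periods × {gap-filled, two-burst} × both polarities; double-bipolar
lobe widths in 2-ms steps × both polarities. Every member is rescaled to
the protocol b-value; members that cannot reach it within the constraints
are excluded (counted and logged). The exact grids are a package choice —
the resulting library has a few hundred members, and selections are
expected to drift slightly with grid granularity.

The selection objective is the product of total noise amplification
Σ_n (RRᵀ)_nn and total spectral contamination Σ_n ∫_outside SRF_n², with
SRFs unnormalised; since all members share one b-value, the ranking is
invariant to the spectral unit convention. Contamination integrals are
evaluated through cached interval-restricted Gram matrices
G⁽ʲ⁾_mm' = ∫_j P_m P_m' dω, so greedy candidate scoring reduces to rank-one
Sherman–Morrison updates of (EᵀE)⁻¹ and 6×6 quadratic forms; each step's
chosen subset is re-scored from scratch to prevent update drift, and tests
verify the cached path against direct SRF quadrature (≤10⁻⁶ relative).

Two greedy variants run: *prune* (from the full library down to N, sets
nested across M) and *grow* (exhaustive best pair, then single-member
additions; for M < N the objective uses the pseudoinverse on the
rank-supported subspace with a +∞ guard when an interval has no encoding
power). Ties break toward the lowest library index for reproducibility.
The per-M winner is the lower-objective set of the two variants. Greedy
selection is locally optimal only; on fixture libraries of ≤ 8 members
every step is verified against exhaustive enumeration. The choice of M
itself is left to the user, from the per-M report of noise, contamination
and SRFs; the default report highlights M = 7 for the six 10-Hz-resolution
intervals, where one member typically splits its power over two intervals
to sharpen the hardest (10–20 Hz) response.

## Theoretical diffusion spectra

Power-law dispersion D(ω) = D₀ + Λωᶿ models short-range disorder (θ = 0.5
in 1-D, θ = 1 in 2-D). The frequency-unit convention for Λ is not
universal; by default Λ multiplies angular frequency (rad/s)ᶿ — under this
convention the two standard disorder scenarios produce dispersions of
comparable magnitude over the 0–50 Hz band, which is the physically
sensible reading — and a `frequency_unit="Hz"` switch provides the
alternative (the choice only rescales Λ).

Restricted diffusion in impermeable spheres uses the eigenmode expansion of
the velocity autocorrelation spectrum with a_k = μ_k²/r² and
B_k = 2r²/(μ_k²(μ_k²−2)), μ_k the positive roots of dj₁(x)/dx = 0 (found by
bracketed Brent iteration and cached). The weights B_k a_k = 2/(μ_k²−2)
sum to 1, giving D(∞) = D_in; because a K-term truncation loses ~2/(π²K) of
that weight, the exactly known residual is lumped into one extra term at
the (K+1)-th eigenmode rate (`tail_completion`, on by default), which
preserves the free-diffusion limit at any K while leaving the ω²
low-frequency behaviour untouched. The two-compartment scenario adds a
frequency-independent extracellular term f_ex·D_ex.

## Simulation harness

Noiseless measurements integrate D(ω) against each encoding spectrum.
Estimates are scored as percent errors against D at the SRF centroid
(linear model) or at the assigned frequency (single-frequency attribution:
0 Hz for PG, spectrum centroid otherwise). Noisy measurements draw, per
encoding and scenario, 16 diffusion-weighted Gaussian signals with mean 1
and 5 unweighted signals with mean e^{ln(S₀/S)}, all with one common
absolute SD (`sigma_rel`, default 0.02 — the in vivo noise level the
protocol emulates is not published; the SD-inflation ratio reported by the
harness is insensitive to this choice in the small-noise regime, which the
tests exercise). The signal entry is ln(mean S₀ / mean S); repetitions with
non-positive means are discarded and counted. SDs over repetitions
(default 3000) are reported as percentages of ground truth, and a
delta-method propagation of ln(mean S₀/mean S) through the reconstruction
serves as the analytic cross-check (Monte-Carlo agreement within 5% at 10⁴
repetitions). The headline precision penalty is the ratio of
interval-and-scenario-averaged SD percentages (linear / single-frequency −
1), matching how the width-versus-performance summary tabulates both
paradigms. Because each spectrally selective measurement has a different
true signal level while the noise model assumes one level, the realised
amplification runs slightly above the equal-noise prediction — expected,
and visible in the simulations.

Dispersion parameters (D₀, Λ) are recovered by ordinary least squares in
the basis {1, ωᶿ} with θ fixed at the scenario's true value, using SRF
centroids (linear model) or assigned frequencies (single-frequency) as
abscissae. The interval-width study re-runs selection per scheme
(2×25 Hz … 6×8.3 Hz primary intervals, each plus the open 50+ interval)
and emits a width × paradigm table of average absolute errors and SDs.

In the protocol-level summaries, the "primary-interval power fraction"
averages each member's largest interval coefficient over b after excluding
the least single-interval-dominant member of an M = N+1 set (the one
deliberately bimodal encoding).

## What the synthetic benchmarks do and do not show

The simulated measurements use scalar D(ω), Gaussian signal noise, and
exact adherence to the Gaussian phase approximation. They do not emulate
Rician magnitude statistics, kurtosis or perfusion bias, diffusion
anisotropy, gradient-nonlinearity or b-value miscalibration, or any
image-space artifact — all of which affect in vivo data. Passing benchmarks
therefore validate the encoding/reconstruction algebra, the selection
machinery, and the relative accuracy/precision trade-off between the two
representation paradigms under the stated noise model, not in vivo
performance. Re-derived selections depend on the library grids: summary
statistics (average errors, SD inflation, power fractions, SRF peak
locations) are expected to drift by tens of percent relative with grid
granularity, which is the tolerance the end-to-end tests assert.

## Problem sizes

The default pipeline uses the full 0.1-Hz spectral resolution, a library of
a few hundred members, 3000 noisy repetitions, and completes in about a
minute on one CPU; the property suite uses a 12-member deterministic toy
library (0.5-Hz resolution) so exhaustive-enumeration oracles run in
seconds. Noise-propagation cross-checks use 10⁴ repetitions.

## Known limitations

Single-axis encoding only (no tensor-valued waveforms); no concomitant
field or eddy-current modelling; no weighted or regularised reconstruction;
greedy selection offers no global-optimality guarantee; the open interval
is numerically truncated at the coverage limit of the spectrum set; scan
time is not part of the objective — M is a user decision.
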