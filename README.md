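# tdspect

Interval-wise linear encoding for temporal diffusion spectroscopy (TDS):
gradient waveform synthesis, encoding-spectrum selection, and estimation of
the frequency-dependent diffusivity D(ω) from diffusion MRI measurements.

## The problem

Oscillating- and pulsed-gradient diffusion MRI probes tissue microstructure
through the temporal frequency spectrum of diffusion, D(ω). Conventionally
each measurement is attributed to a single frequency (0 Hz for pulsed
gradients, the spectral peak or centroid otherwise), even though its true
spectral sensitivity — the encoding power spectrum |Q(ω)|² — is broad and
often asymmetric. Under the Gaussian phase approximation the signal
attenuation is

    ln(S₀/S) = (1/π) ∫₀^∞ D(ω) |Q(ω)|² dω,      Q(ω) = F{q(t)},  q(t) = γ∫g(t')dt',

so subdividing the frequency axis into N contiguous intervals (the last one
open-ended) turns a series of M ≥ N spectrally distinct measurements into a
linear system **S** = **E D** with

    E_mn = (1/π) ∫_{ω_{n-1}}^{ω_n} |Q_m(ω)|² dω,

and interval diffusivities follow from the pseudoinverse reconstruction
**D̂** = **R S**, **R** = (**EᵀE**)⁻¹**Eᵀ**. Each interval's effective
frequency profile is its spectral response function SRF_n(ω) = Σ_m R_nm
|Q_m(ω)|², which is far more selective than any single |Q(ω)|², at the cost
of noise amplification σ_n^D = σ^S √((RRᵀ)_nn).

`tdspect` implements this model end to end:

- **waveforms** — slew- and amplitude-constrained pulsed gradient (PG),
  trapezoidal-cosine oscillating gradient (OG, gap-filled or two-burst,
  matched/unmatched polarity) and double-bipolar waveforms; q-space
  trajectories, b-values, encoding spectra, centroid/FWHM diagnostics.
- **encoding** — `LinearEncodingModel` (statsmodels-style): built from
  encoding spectra and an `IntervalScheme`, exposes **E**, **R**, SRFs and
  noise amplification; `fit()` returns interval diffusivities with
  reference frequencies (SRF centroids) and propagated SDs; tensor-series
  input yields per-interval diffusion tensors with MD/AD/RD.
- **selection** — library generation over waveform parameter grids and a
  greedy optimizer (prune and grow variants) minimising the objective
  O = [Σ_n (RRᵀ)_nn] × [Σ_n ∫_outside SRF_n²], i.e. noise × spectral
  contamination.
- **spectra** — theoretical D(ω): power-law dispersion D₀ + Λωᶿ and
  restricted diffusion in impermeable spheres (eigenmode expansion), with a
  registry of four standard tissue scenarios.
- **simulate** — noiseless and noisy simulated measurements comparing the
  linear model against single-frequency attribution (errors, SDs,
  dispersion-parameter recovery, interval-width studies).

## Worked example

Three b = 1000 s/mm² encodings (one PG, two OGs) estimating D(ω) of a
short-range-disorder spectrum over 0–25, 25–50 and 50+ Hz:

```python
import numpy as np
import tdspect as td

c = td.HardwareConstraints()          # 200 mT/m, 600 T/m/s, T_DW <= 90 ms
waveforms = [
    td.make_pg(c.g_max, 0.015, 0.060, dt=c.dt, slew=c.slew_max),
    td.make_og_trapcos(30, 2, c.g_max, dt=c.dt, slew=c.slew_max, gap=c.refocus_gap),
    td.make_og_trapcos(55, 4, c.g_max, dt=c.dt, slew=c.slew_max, gap=c.refocus_gap),
]
spectra = [td.scale_to_b(w, 1000.0, constraints=c).spectrum(df=0.1) for w in waveforms]

model = td.LinearEncodingModel(spectra, td.IntervalScheme.uniform(25.0))
print(model.summary().to_string(index=False))

truth = td.scenario("scenario1")      # D(omega) = 7e-4 + 8.5e-6 sqrt(omega)
signal = np.array([td.attenuation(truth, s) for s in spectra])
print(model.fit(signal, sigma_s=0.02).summary().to_string(index=False))
```

prints

```
interval  encoding_power_fraction  noise_amplification  srf_centroid_hz  srf_peak_hz  srf_sidelobe_power
 0-25 Hz                 0.983753             1.031146         4.631775          0.0            0.000009
25-50 Hz                 0.524182             2.331959        44.738581         25.4            0.240843
  50+ Hz                 0.490310             3.142821        67.975816         48.5            0.463229

interval  ref_freq_hz  D_mm2_s  sd_mm2_s
 0-25 Hz     4.631775 0.000742  0.000021
25-50 Hz    44.738581 0.000864  0.000047
  50+ Hz    67.975816 0.000856  0.000063
```

Each interval's diffusivity maps to its SRF centroid: the estimates track
the true dispersion (7.4e-4 mm²/s near 5 Hz rising to ~8.6e-4 mm²/s above
50 Hz), and `sd_mm2_s` propagates the assumed measurement noise through the
reconstruction. A hand-picked three-encoding set like this one leaves
appreciable spectral contamination (`srf_sidelobe_power`); the `selection`
module exists to do better, e.g.

```python
lib = td.build_library(c)                          # ~330 feasible members
scheme = td.IntervalScheme.uniform(10.0)           # 0-10, ..., 40-50, 50+ Hz
winners = td.select_best(td.greedy_prune(lib, scheme),
                         td.greedy_grow(lib, scheme, m_max=12))
best7 = td.LinearEncodingModel(lib.spectra(winners[7]["indices"]), scheme)
```

The same pipeline is scriptable from the shell: `tdspect design`,
`tdspect simulate`, `tdspect apply` (voxel-wise tables of per-measurement
ADCs or tensor elements) and `tdspect fixtures`; see `tdspect --help`.

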