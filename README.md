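# cyblink

Photoisomerization blinking analysis for the cyanine dye Cy5: a
three-state kinetic model with **two emissive states**, and the forward
models and global fitters needed to analyze it with fluorescence
correlation spectroscopy (FCS), transient-state excitation-modulation
spectroscopy (TRAST), pulse-width-resolved emission spectra
(spectral-TRAST) and TCSPC fluorescence decays.

## The problem

Under the excitation intensities routine in single-molecule and
super-resolution microscopy, Cy5 spends a large fraction of its time in
photo-isomerized conformations.  The classic picture is a two-state
switch between the emissive all-trans form (N) and a dark mono-cis form —
but the observed blinking amplitude of Cy5 *depends on the emission band
detected*, which a single dark state cannot produce.  The resolution is a
second, double-cis isomer P2 that is itself emissive with a red-shifted
spectrum and relative detected brightness Q.  This package implements
that three-state chain,

    N  ⇄  P1(dark)  ⇄  P2 (emissive, red-shifted, brightness Q)

with effective rates k_iso1′ = kiso·σNΦ/k10N, k_biso1′ = σ_biso1Φ + k_th1,
k_iso2′ = σ_iso2Φ, k_biso2′ = σ_biso2Φ + k_th2 (Φ the excitation photon
flux), and propagates it into the observables:

* **FCS**: G(τ) = G_D(τ)·G_T(τ) + 1, with the blinking factor G_T built
  from the time-dependent populations, weighted by brightness *squared*
  (Q² for P2) and started from an initial condition that encodes which
  emitter produced the lag-zero photon;
* **TRAST**: normalized pulse-train averages ⟨F(w)⟩/⟨F(w0)⟩, with single-Q
  brightness weighting and a ground-state start for every pulse;
* **spectral-TRAST**: band-integrated, pulse-width-resolved spectra;
* **TCSPC**: mono/bi-exponential IRF reconvolution fits that expose the
  short-lifetime red component.

Global fits share the kinetic parameters {kiso, σ_biso1, σ_iso2, σ_biso2,
Q, (k_th1, k_th2)} across emission bands and excitation irradiances, with
σN and τf fixed; for FCS, Q also enters the initial condition and is
iterated to self-consistency.  Seeded synthetic-data generators with
recorded ground truth provide the test surface for every analysis path.

## Worked example

```python
import numpy as np
from cyblink import (FCS_FIT_PARAMS, ExcitationField, FcsDiffusionParams,
                     steady_state, relaxation_modes, default_lag_grid,
                     fcs_curve_three_state, fit_two_state)

ss = steady_state(FCS_FIT_PARAMS, 21.0)
lam_slow, lam_fast, _ = relaxation_modes(FCS_FIT_PARAMS, 21.0)
print(f"steady state at 21 kW/cm2: N={ss.pN:.3f} P1={ss.pP1:.3f} P2={ss.pP2:.3f}")
print(f"relaxation times: {1/abs(lam_slow):.2f} us and {1/abs(lam_fast):.3f} us")

field = ExcitationField(mode="uniform", intensity=21.0)
diffusion = FcsDiffusionParams(n_mean=1.0, tau_d=100.0)
lags = default_lag_grid()
for band, q in (("B", 0.0), ("R", 0.46)):
    curve = fcs_curve_three_state(FCS_FIT_PARAMS, field, q, diffusion, lags, band)
    fit = fit_two_state(curve)
    print(f"{band}-band two-state refit: Aiso={fit.params['a_iso']:.3f} "
          f"tau_iso={fit.params['tau_iso']:.2f} us")
```

prints

```
steady state at 21 kW/cm2: N=0.325 P1=0.301 P2=0.374
relaxation times: 0.62 us and 0.185 us
B-band two-state refit: Aiso=0.667 tau_iso=0.50 us
R-band two-state refit: Aiso=0.433 tau_iso=0.33 us
```

At 21 kW/cm² CW excitation roughly two thirds of the molecules sit in
photo-isomerized states.  Refitting the three-state curves with the
classic two-state model shows the band effect directly: in the blue
emission band (P2 invisible, Q = 0) the apparent isomerization amplitude
is 0.67, while in the red band (Q = 0.46) the partially emissive P2
weakens the blinking contrast to 0.43 — same kinetics, different
amplitude, purely an emission-detection effect.  The relaxation is
bi-exponential (0.62 µs and 0.185 µs); the single-exponential refit
compresses it to ~0.5 µs.

## Command line

```sh
cyblink synth fcs --seed 1 --out data/          # seeded dataset + ground truth
cyblink fcs-fit data/fcs_*.txt --out fit/       # global three-state fit
cyblink trast-fit data/trast_*.txt --out fit/
cyblink spectral-trast data/spectra.tsv --bands 645:680,690:750
cyblink tcspc-fit data/decay.txt --components 2
cyblink reproduce --seed 1 --out repro/         # full synthesize-and-refit round
```

Every run writes a resolved `config.json` next to its outputs; identical
config + seed gives byte-identical reports.

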