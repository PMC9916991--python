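# Methods

## The photophysical model

Cy5 (a pentamethine carbocyanine) in aqueous solution is modeled with three
lumped conformer states:

* **N** — the all-trans ground conformation, emissive, peak emission near
  670 nm;
* **P1** — a mono-cis photo-isomer, treated as non-emissive;
* **P2** — a double-cis photo-isomer formed from P1 in a second
  photo-driven step, emissive with a red-shifted spectrum and a relative
  detected brightness Q compared with N within any given emission band.

Transitions follow the chain N ⇄ P1 ⇄ P2 with no direct N ⇄ P2 channel.
Each state lumps its singlet ground and excited manifolds: ground/excited
equilibration ("anti-bunching") happens on nanoseconds while isomerization
kinetics play out on microseconds, so only effective rates appear:

    k_iso1' = kiso · σN Φ / k10N        N  → P1
    k_biso1' = σ_biso1 Φ + k_th1        P1 → N
    k_iso2' = σ_iso2 Φ                  P1 → P2
    k_biso2' = σ_biso2 Φ + k_th2        P2 → P1

with Φ the excitation photon flux (photons cm⁻² s⁻¹, from the irradiance
in kW/cm² at the excitation wavelength), kiso the excited-state
isomerization rate of N, k10N = 1/τf − kiso the remaining S1 deactivation
rate, σ's effective cross sections (cm²), and k_th1/k_th2 thermal
back-isomerization rates that act without light.  Triplet states,
photobleaching chemistry and anti-bunching are outside the model; the
torsional potential-energy-surface parameters behind these effective rates
(branching ratios, twisted-state yields) are deliberately not resolved.
The three coupled linear rate equations implied by the chain topology are
assembled in `rate_matrix` and solved by eigen-decomposition (the
N ⇄ P1 ⇄ P2 differential-equation system itself is reconstructed from the
state topology; see "Numerical choices").

Two excitation conventions are provided.  The default N→P1 pumping factor
σNΦ/k10N is linear in Φ; an opt-in saturated variant uses
σNΦ/(σNΦ + k10N), relevant above roughly 100 kW/cm² where the S1
population of N stops being negligible.  All steady states, FCS and TRAST
forward models accept either.

### Reference parameter sets

Two frozen parameter sets (638 nm excitation, PBS) ship with the package:

| parameter | FCS set | TRAST set | units |
|---|---|---|---|
| kiso | 36 | 33 | µs⁻¹ |
| σN (fixed) | 6.2e−16 | 6.2e−16 | cm² |
| σ_biso1 | 0.25e−16 | 0.26e−16 | cm² |
| σ_iso2 | 0.31e−16 | 0.30e−16 | cm² |
| σ_biso2 | 0.25e−16 | 0.25e−16 | cm² |
| k_th1 | 0 (fixed) | 0.015 | µs⁻¹ |
| k_th2 | 0 (fixed) | 0.08 | µs⁻¹ |
| τf (fixed) | 1.0 | 1.0 | ns |
| Q | 0.46 | 0.28 | — |

The FCS set fixes the thermal rates to zero because at the irradiances
used for FCS (tens of kW/cm²) photo-driven back-isomerization dominates;
the TRAST experiments run at 1–5 kW/cm² where the thermal rates are
observable and are therefore fitted.

## FCS model

G(τ) = G_D(τ)·G_T(τ) + 1 with the standard 3-D Gaussian diffusion factor
(aspect ratio S = ωz/ω0 = 6.8 by default) and a kinetic blinking factor.
The three-state blinking factor weights state populations by the *square*
of the detected brightness (an intensity correlation):

    G_T(τ) = Σ_r w²(r̄)[pN(r̄,τ) + Q² pP2(r̄,τ)]
           / Σ_r w²(r̄)[p̄N(r̄) + Q² p̄P2(r̄)],

with w(r̄) ∝ CEF·Φ(r̄) (uniform collection efficiency by default) and the
populations propagated from a lag-zero state that encodes which emitter
produced the detected photon: (1,0,0) when P2 is invisible in the band
(Q = 0), and the brightness-weighted steady state
(p̄N, 0, Q·p̄P2)/(p̄N + Q·p̄P2) otherwise.  The single-Q weighting in the
initial condition together with the Q² weighting of the lag-τ populations
is the model convention adopted throughout (it is what the global fits and
the reference Q values are defined against).  The blinking factor is only
evaluated for τ ≥ 1 ns, the validity floor of the lumped-state
approximation.

Spatial averaging defaults to a single "uniform" node at the curve's
stated mean irradiance — with the FCS set's thermal rates at zero the
steady state is independent of irradiance, so spatial averaging mainly
smears the relaxation eigenvalues rather than changing amplitudes — and a
3-D Gaussian quadrature (Gauss–Legendre, 32×32 nodes over 3ω0 × 3ωz) is
available for sensitivity checks.

### Two-state refits

The classic two-state trans/cis model
G(τ) = G_D(τ)[1 − A + A e^(−τ/τiso)]/(1 − A) + 1 is retained both as a
fit model in its own right and as the reduction used to quantify
band-dependent blinking amplitudes.  Refitting noiseless three-state
B-band curves (21 kW/cm², FCS set) with the two-state model compresses
the underlying bi-exponential relaxation (eigenvalues ≈ −1.6 and
−5.4 µs⁻¹) into A ≈ 0.67, τiso ≈ 0.5 µs; the R band (Q = 0.46) gives
A ≈ 0.43.  The B-band value sits slightly above the reference
experimental amplitude (0.61): the three-state parameter set predicts a
B-band contrast of 1/p̄N ≈ 3.07 whereas a measured amplitude of 0.61
corresponds to 2.56, and because the zero-thermal-rate steady state is
irradiance-invariant no excitation-profile convention closes that gap.
The package reports what the model produces.

### Global FCS fitting

`fit_three_state_global` shares {kiso, σ_biso1, σ_iso2, σ_biso2, Q}
across a two-band (B: Q fixed 0; R: Q fitted), multi-irradiance curve
set with per-curve diffusion nuisances {Nm, τD}.  σN and τf are fixed
inputs.  Because Q also determines the lag-zero state of the R-band
curves, an outer iteration refits with the initial condition evaluated at
the current Q until |ΔQ| < 1e−4 (at most 50 outer loops).  The bare
fixed-point map Q_ic → Q_fit can have slope < −1 and oscillate, so the
update is damped by a factor 0.5, which makes it contractive in practice
(3–5 outer iterations on the default synthetic sets).  The inner solver
is a bounded trust-region least squares (all rates and cross sections
≥ 0, kiso < 1/τf) with cross sections internally scaled to ~1 (units of
1e−16 cm²) and a deterministic 3-start multistart.

## TRAST model

A rectangular pulse of duration w starts with all molecules in N (the
low duty cycle, 0.001–0.01, guarantees full thermal recovery between
pulses; a guard warns outside [0.0005, 0.05]).  The detected signal
weights populations by a single brightness factor,
F(t) ∝ Σ_r CEF·Φ(r̄)[pN + Q pP2], and the TRAST curve is the normalized
pulse average ⟨F⟩(w)/⟨F⟩(w0), computed in closed form from the
eigen-expansion (time averages of exponentials, expm1(λw)/(λw)), never by
numeric time quadrature.  w0 defaults to 0.1 µs; if the model predicts
more than 0.5% dark-state build-up within w0 the violation is recorded in
the curve metadata.  The default wide-field geometry averages a 2-D
Gaussian beam (1/e² radius 20 µm) over a 20 µm-radius detection disc with
a 32-node radial quadrature; a uniform shortcut exists.  Permanent
bleaching tracked by short-pulse reference frames is corrected by
piecewise-linear interpolation of the reference signal versus acquisition
index (warning above 10% total loss).

`fit_trast_global` shares {kiso, σ_biso1, σ_iso2, σ_biso2, k_th1, k_th2,
Q} across the two-band multi-irradiance set.  Normalized TRAST curves
carry no per-curve amplitude nuisances, and the (1,0,0) initial condition
does not involve Q, so no outer iteration is needed.

## Spectral-TRAST

Detector-corrected emission spectra recorded per pulse width are reduced
to band-integrated TRAST curves.  Band integrals are closed-interval
trapezoids on the native wavelength grid (no resampling); adjacent bands
sharing an edge are exactly additive, and a degenerate single-point band
reduces to a pointwise ratio.  Two display normalizations are provided:
against the shortest-pulse peak (absolute bleed-off) or per-curve peak
(red-shift of the shape).

## TCSPC

Decay histograms are fitted by iterative reconvolution: Gaussian-IRF (or
measured-IRF) convolution of one or two exponentials with fitted shift,
background and scale, on a 4 ps / 25 ns grid by default.  The first pass
uses Neyman (counts-based) weights, variance = max(counts, 1); the
solution is then refined with variances taken from the fitted model
(iteratively reweighted least squares, weights frozen per pass, 3
passes).  The refinement matters: at 4 ps binning most bins hold few
counts, and pure counts-based weighting systematically underweights
upward fluctuations, biasing the recovered minor amplitude of the
1.0/0.5 ns pair by ≈ 0.08; the reweighted fit removes the bias while
remaining a least-squares procedure.  Two-component fits whose lifetimes
agree within 5% are flagged as collapsed.  Model preference between one
and two components requires both a reduced-χ² improvement factor (> 1.2)
and structured mono-fit residuals (lag-1 autocorrelation > 0.2); these
thresholds are package conventions.

## Synthetic data

The generators are pure functions of (configuration, seed); per-curve
noise comes from child generators keyed by (seed, curve index).  The
study conditions they emulate:

* **FCS**: two bands {B: Q=0, R: Q=0.46(truth)}, irradiances
  5.25/10.5/21/42 kW/cm² (a doubling ladder around the printed
  21 kW/cm², inside the regime where thermal rates are negligible),
  Nm = 1, τD = 100 µs, 200 log-spaced lags 1e−3–1e4 µs.  Noise is
  heteroscedastic Gaussian with SD ∝ (G−1+1/Nm)/√(Δτ·T), T a 60 s
  acquisition proxy — the standard bin-averaged FCS noise shape — with a
  default scale giving ≈ 2% relative noise at the shortest lags,
  comparable to the residual scatter of typical confocal FCS runs.
* **TRAST**: bands {B: 0, R: Q=0.28(truth)}, irradiances
  1.2/2.4/3.6/4.7 kW/cm², 30 widths 0.1 µs–10 ms, wide-field disc
  geometry, additive Gaussian noise SD = 1%·f_norm (camera-limited
  precision), optional exponential bleaching trace.
* **Spectra**: 3.9 kW/cm², duty 0.002, two-component mixture
  S(λ,w) = ⟨pN⟩_w B_N(λ) + Q·⟨pP2⟩_w B_P2(λ) with log-normal bases
  peaking at 670 nm (N) and 710 nm (P2, 10% broader).  The basis width
  (σ = 0.04 in log-λ, ≈ 63 nm FWHM) intentionally includes the red
  vibronic shoulder of the real N emission; a narrow 40 nm band would
  leave the 690–750 nm window P2-dominated and make its TRAST amplitude
  negative, contrary to the behavior being emulated.  Poisson noise at
  1e5 peak counts.
* **Decays**: Poisson draws of the reconvolved model, 1e6 total counts,
  noise-free Gaussian IRF of 0.2 ns FWHM (an IRF-width convention; the
  reference measurement does not state one).

What the synthetic data do **not** contain: detector afterpulsing and
dead time, photobleaching chemistry, triplet blinking, scattering
background, spectrometer wavelength-calibration error, diffusion-kinetics
coupling beyond the multiplicative FCS factorization.  Passing recovery
tests therefore demonstrate identifiability and correctness of the
fitting machinery under the model's own assumptions, not robustness to
every artifact of real data.

## Numerical choices

* One internal unit convention: µs, µs⁻¹, cm², kW/cm², nm; conversion only
  in `photon_flux` and at I/O boundaries.
* Populations propagate by eigen-decomposition; eigenvalues within
  1e−10·|λmax| of zero are snapped to zero and positive numerical real
  parts clamped, so stationary modes survive asymptotic evaluation
  exactly; (near-)degenerate relaxation eigenvalues (gap < 1e−9·|λ3|)
  fall back to a scaling-and-squaring matrix exponential.
* The steady state in the blinking-term normalization is taken as the
  t→∞ limit of the same eigen solution, making G_T(∞) = 1 to machine
  precision rather than to eigen-solver precision.
* Fits use `scipy.optimize.least_squares` (TRF, bounds) behind a
  deterministic multistart (first start = initial guess, further starts
  log-normally perturbed by a seeded generator); non-convergence is
  flagged in the returned result, never raised.
* 1σ uncertainties come from the Jacobian-based covariance at the
  solution.

## Problem sizes

The default analyses run on desk-scale problems: 8 FCS curves × 200 lags,
8 TRAST curves × 30 widths, 6250-bin decay histograms, 12×171-point
spectra.  A full synthesize-and-refit round of all four measurement types
(the `reproduce` command, or `scripts/acceptance.py`) completes in about
a minute on one core.

## Known limitations

* The rate-equation topology is reconstructed from the three-state model
  diagram; the lumped-state reduction is inherited as-is, so any physics
  outside it (triplets, photo-ionization, direct N ⇄ P2) is invisible.
* With thermal rates fixed to zero the FCS steady state is
  irradiance-invariant; multi-irradiance FCS sets then constrain rates
  through relaxation times only, and the B-band blinking contrast is
  pinned at 1/p̄N (see "Two-state refits").
* σ_iso2 and σ_biso2 are weakly identified from normalized TRAST curves
  at 1% noise (they trade against Q); kiso, k_th2 and the FCS-side Q are
  the robustly recoverable quantities.
* The spectral-TRAST module quantifies band amplitudes; it does not fit
  kinetic parameters from spectra.
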