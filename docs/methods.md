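# Methods

This note documents the models, conventions and numerical choices behind
`flickerlab`, in the order the pipeline runs: synthetic generator →
imaging chain → real-space statistics → spectra → microrheology → fits.

## Contour fluctuation model

The observable is the equatorial contour displacement field
δh_i(l_i, t) = R_i(t) − R̄ on N emplacements of size L = 2πR̄/N. The
canonical acquisition is 2 kHz over ≥ 5 s (≥ 10⁴ frames), N up to 2048.

### Passive ring-mode bank

Ring modes q_n = n/R̄ evolve as independent overdamped Ornstein–Uhlenbeck
processes with dispersion rate ω(q) = (γq + κq³)/(4η) and stationary
variance ⟨|h_q|²⟩ = kB·T/(2πR̄(γq + κq³)). Two conventions matter:

- **Equatorial-section normalization.** The 1D contour observable of a
  fluctuating quasi-2D membrane decays one power of q slower than the
  surface modes themselves (q⁻¹ tension / q⁻³ bending, not q⁻²/q⁻⁴).
  Only this pairing reproduces the bimodal spectrum
  PSD ≈ kB·T/(ωG_eff(ω)) — a 1/ω tension window and the Zilman–Granek
  ω^(−5/3) bending window with MSD ∼ τ^(2/3). It also makes the per-mode
  power plateau σ_q²ω_q = kB·T/(8πηR̄) mode-independent, the correct
  fluctuation–dissipation pairing with the dispersion rate. (With q⁻²/q⁻⁴
  variances the 1D Lorentzian sum is tail-dominated and decays as ω⁻²,
  measured slope −1.91 — incompatible with the bending scaling.)
- **Modes start at n = 2.** The n = 1 radial mode is a rigid translation
  to first order and is exactly what barycenter drift correction removes;
  the deformation observable therefore begins with the elliptical mode.
  The n = N/2 ring-Nyquist mode has no sine quadrature on the site grid
  and is likewise excluded (`n_modes ≤ N/2 − 1`).

Each quadrature (cos and sin) of a mode carries the full mode variance;
since cos²(nθᵢ) + sin²(nθᵢ) = 1 at any fixed site, the per-site variance
is exactly the mode sum. The OU update is the exact discretization
h ← h·e^(−ω dt) + N(0, σ²(1 − e^(−2ω dt))), initialized from the
stationary law, so statistics are unbiased at any frame interval;
undersampling a fast mode only aliases its spectrum (a warning is
emitted).

### Default parameters

| parameter | default | rationale |
|---|---|---|
| R̄ | 3.6 µm | discocyte equatorial radius |
| T | 310.15 K | homeostatic bath temperature |
| κ_eff | 2.9×10⁻¹⁸ J | *effective ring modulus*: calibrated once so the passive default reproduces the healthy ensemble scale Σ ≈ 25 nm (→ G = kB·T/Σ² ≈ 6.9 µN/m) over modes n ≥ 2 |
| η | 0.5 Pa·s | effective microviscosity placing many bending-mode rates inside the 2 kHz band (ω_n ≈ 0.031·n³ rad/s) |
| γ | 0 | bending-dominated default; tension sets a low-frequency plateau when nonzero |
| Σ₀ | 8 nm | basal (rigidized) scale defining G₀ = kB·T/Σ₀² ≈ 67 µN/m |

The 1D ring mode bank compresses the full 2D membrane mode sum, so κ_eff
and η are renormalized effective parameters, not molecular ones; with a
molecular bending modulus (~2×10⁻¹⁹ J) the ring normalization cannot
produce tens-of-nanometer amplitudes at this geometry.

### Active kickers

A fraction φ of sites (default 0.3) adds an independent excursion x(t)
relaxing through the local solvent friction ζ = 6πL·η_solvent toward a
telegraph target ±Λ₀ (spring constant f₀/Λ₀, relaxation rate
f₀/(Λ₀ζ) ≈ 8×10³ rad/s — fast compared with all switching rates).
Defaults: Λ₀ = 50 nm (= 2Σ of the default membrane), f₀ = 0.34 pN chosen
as kB·T·Λ₀/Σ² so that the Gov identity T_eff/T = 1 + φf₀Λ₀/kB·T holds
exactly; ε_kick = f₀Λ₀ ≈ 4 kB·T. Switching corner rates are either a
single rate ω_A (default 50 rad/s) or — the default —
log-uniform over two decades (50–5000 rad/s), whose Lorentzian
superposition is pink (1/ω) inside the span:

S(ω) = (2σ²/π ln(r₂/r₁)) · [arctan(r₂/ω) − arctan(r₁/ω)]/ω.

`p_on` gates each kicker through an independent on/off Markov chain with
duty cycle p_on; the product φ·p_on scales ensemble activity. The
frequency-dependent active temperature uses the kernel
K(x) = 2(1 − cos x)/x², normalized so K(0) = 1 and hence
T_eff(0) = T + φf₀Λ₀/kB.

## Imaging chain

Frames are rendered as a dark ring of Gaussian radial cross-section
centered on R(θ, t), 16-bit, with optional blur and additive noise;
default pixel size 20 nm/px so nanometer fluctuation scales are about a
tenth of a pixel. Segmentation casts N rays from the intensity
barycenter, cubic-interpolates the radial profile in 0.5 px steps, takes
the ring extremum and refines it with a parabolic vertex fit (round-trip
RMS ≈ 0.1 px at 2% noise, < 0.001 px noiseless). Rays without an interior
extremum are flagged missing and linearly interpolated across (≤ 1% per
frame, else the frame is rejected).

Drift correction re-centers each frame on the polygon **area** centroid
(the vertex average is biased by the angular sampling density) and can
register rotation by maximizing circular cross-correlation against a
running mean profile. Rotational registration is **off** in the default
chain: on a freely fluctuating contour the phase diffusion of the
dominant n = 2 mode is mathematically degenerate with rigid rotation, and
registration would remove ~30% of real variance. Enable it for stacks of
genuinely tumbling cells. R̄ is the global time-and-angle mean; per-frame
means are retained so the breathing mode survives.

## Real-space statistics

σ_i² is the per-site time variance; Σ² its site mean; 2Σ the
characteristic displacement scale; G = kB·T/Σ² the equipartition
elasticity. The effective-temperature map is T_eff,i = G₀σ_i²/kB,
normalized so a site at the basal variance kB·T/G₀ maps to T. Hot spots
are σ_i² ≥ k²Σ²_ref (k = 2, boundary inclusive), tying the criterion to
the 2Σ displacement scale; the default reference is the **median** site
variance, a passive-background estimate that the hot spots themselves do
not inflate. Green–Kubo diffusivities integrate the velocity
autocovariance (trapezoid) to the interpolated first zero crossing,
capped at 100 lags; for memoryless input this equals MSD(Δt)/2Δt, for OU
input the short-time limit σ²ω_r.

## Spectra

Welch estimation per site (Hann, 50% overlap, per-segment mean removal),
one-sided, expressed on an angular-frequency grid with
psd(ω) = S_f(f)/2π so that the integral over ordinary frequency equals
the series variance (2% check on in-band processes; ultra-slow modes are
partially suppressed by detrending, as in any finite acquisition).

## Microrheology (GSER)

The Mason–Weitz local power-law inversion, computed from the spectral
MSD:

1. MSD is evaluated on the sampling-lag grid τ_k = k·dt, where the
   aliased in-band spectrum integrated against (1 − cos ωτ_k) reproduces
   the time-domain MSD exactly (discrete-time spectral theorem) — no
   out-of-band correction is needed for measured spectra. For synthetic
   continuous grids the above-grid power is added as a constant tail.
2. The local exponent β(τ) ∈ [0, 1] and a smoothed MSD come from a
   half-decade moving log-log regression (this averages out the ringing
   of the band-limited cosine transform). A small loss-angle floor
   (β ≥ 0.005) keeps the viscous branch defined on elastic plateaus,
   where it decays as ω⁻¹ (the lubrication limit).
3. |G_eff(ω)| = 2·kB·T/(MSD(1/ω)·Γ(1+β)), with the calibration constant
   2 fixed analytically by the OU-trap identity G_trap = kB·T/Var — the
   plateau of a trapped bead is recovered exactly by construction and is
   verified to 5% on simulated traps. G′ = |G|cos(πβ/2),
   G″ = |G|sin(πβ/2), η_eff = G″/(6πLω) (Pa·s).

Output is restricted to ω ≤ 1/dt; the estimate near the band top is
intrinsically less reliable and fits should stay below about a third of
it.

Crossovers: ω_D is the Maxwell crossing G′ = G″ (log-interpolated; exact
on a pure Maxwell element; reported as a band edge when no crossing
exists). The noise-floor onset ω_C is found by estimating the floor level
from the top octave (when its slope is flatter than −0.2) and locating
where the spectrum falls to twice that level.

## Fractional viscoelastic fits

`FractionalRigidityModel` / `FractionalViscosityModel` /
`BicomponentSpectrumModel` are Model classes whose `.fit()` returns a
results object with parameters, standard errors, `summary()` and
`plot()`. Fits are weighted log-space least squares with a fixed,
deterministic multistart grid (no random restarts); the bicomponent model
is parametrized in log10 because its natural parameter scales span ~20
decades, and it compares the full model against a passive-only null by
AIC (flagging `passive_only` when the active amplitude is not
identifiable).

On measured spectra the relaxation knee is much broader than the
Cole-Cole form, making free fits degenerate; `fit_fractional_rigidity`
therefore stages the fit, estimating the crossovers first and holding
them fixed: locate the knee from the β profile (first sustained crossing
of 1/3), take the
tension plateau G_γ as the median G′ below knee/3, and regress the
branch G′ − G_γ between 3·knee and the floor onset, i.e. the
sub-saturation limit G_γ + G_κ(ωτ_D)^(2α) with τ_D = 1/ω_knee. On the
tension+bending simulation this recovers the analytic plateau
kB·T/Σ²(γ, κ) within ~10% and α = 1/3 ± 0.01; the rising branch of the
α = 1/4 curve has exponent 1/2.

## What the generator does and does not emulate

The generator reproduces: Gaussian stationary passive fluctuations with
per-mode equipartition; the −5/3 bending and −1 kicker spectral slopes;
τ^(2/3) MSD growth; the Gov effective-temperature relation; hot-spot
fractions; passivation ordering of spectra with decreasing φ; and
pointwise active softening of the GSER rigidity (−ΔG). It does **not**
reproduce: donor-population absolute values (Σ = 25 ± 4 nm across donors
etc. parameterize the defaults, they are not measurements); the drop of
the ratio ωG′/G″ under activity (the kicker band is spectrally shallower,
so the Mason phase *rises* even as |G| softens 70-fold — the softening
ordering is asserted instead); and the measured −1/2 viscosity slope of
active cells, which in the model algebra follows from α = 1/4 but in the
generator's kicker band is a mixture of telegraph ω⁻² tails and bending
−5/3. Passing tests therefore validate the estimators and the model
algebra, not organism-level values.

## Problem sizes

Test and acceptance runs use N = 512 emplacements with 10⁵ frames at
2 kHz for spectral measurements (a few seconds each), N = 64–128 with
longer, faster-relaxing runs for tightly converged averages, and 40–100
rendered 512×512 frames for imaging round trips. Statistical tolerances
are derived where possible from exact OU sampling-variance formulas
(e.g. Var of a sample variance of an AR(1) square process) rather than
fixed percentages.

## Known limitations

- The ring normalization compresses the 2D mode sum; κ_eff and η are
  effective, and no hydrodynamic coupling beyond the local friction of
  the dispersion rate is modeled.
- Rotational registration cannot distinguish rigid rotation from
  coordinated mode-phase drift; it is opt-in.
- GSER output near the grid Nyquist is trimmed and still least reliable
  just below the trim.
- The bicomponent decomposition is degenerate when the active corner
  rate leaves the measured band; the passive-only flag reports this.
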