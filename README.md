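# flickerlab

Membrane **flickering spectroscopy** of red blood cells: contour
fluctuation statistics, active/passive spectral decomposition, and
fractional microrheology — together with a synthetic membrane-fluctuation
generator and a ring-image rendering/segmentation chain, so that every
stage of the analysis can be validated end-to-end at desk scale.

## Who this is for

Healthy erythrocytes "flicker": their membrane fluctuates around the
discocyte shape with submicron amplitude, driven partly by thermal noise
and partly by ATP-dependent cytoskeletal kicking. Quantifying these
fluctuations along the equatorial contour — variances, power spectra,
effective temperatures and frequency-dependent viscoelastic moduli — is a
standard route to single-cell mechanics. `flickerlab` implements that
analysis chain for videomicroscopy-style data and ships a physically
explicit simulator that stands in for experimental image stacks.

## The model

The equatorial contour is tracked as N displacement series
δh_i(l_i, t) = R_i(t) − R̄ at emplacements of lateral size L = 2πR̄/N.

**Passive membrane.** Ring Fourier modes q_n = n/R̄ (n ≥ 2; n = 1 is rigid
translation) relax as overdamped Ornstein–Uhlenbeck processes with the
viscoelastic dispersion rate

    ω(q) = (γ q + κ q³) / (4η)

and equatorial-section equipartition variance

    ⟨|h_q|²⟩ = kB T / (2πR̄ (γ q + κ q³)).

This pairing yields the bimodal fluctuation spectrum
PSD(ω) ≈ kB T / (ω G_eff(ω)): a 1/ω decay in the tension window and the
Zilman–Granek ω^(−5/3) decay in the bending window, with point MSD ∼ τ^(2/3).

**Active kickers.** A fraction φ of emplacements carries a dichotomous
(telegraph) force ±f0, relaxed through the local solvent friction toward
excursions ±Λ0. With switching rates drawn log-uniformly over a span of
corner rates the ensemble spectrum is pink (1/ω) inside the span, and the
ensemble variance obeys the Gov relation T_eff/T = 1 + φ f0 Λ0 / kB T.

**Analysis.** Local variances σ_i², ensemble Σ², equipartition elasticity
G = kB T/Σ², effective-temperature maps with hot-spot detection, frame
velocities and Green–Kubo diffusivities; Welch PSDs; the generalized
Stokes–Einstein (Mason–Weitz) inversion to G′(ω), η_eff(ω); and
statsmodels-style model classes for the fractional Maxwell rigidity

    G_eff(ω) = γ/R + G_κ (ωτ_D)^(2α) / (1 + (ωτ_D)^(2α)),   0 ≤ α ≤ 1,

its conjugate fractional viscosity, and the passive+active bicomponent
spectral decomposition. Morphotyping classifies contours as discocyte /
elliptocyte (c = R1/R2 ≤ 0.95) / echinocyte (Δ = (D − 2πR̄)/2πR̄ > 0.1) /
ghost (low ring contrast).

## Worked example

```python
from flickerlab import (MembraneParams, ActivityParams, simulate_active_contour,
                        simulate_passive_contour, compute_psd, fit_powerlaw,
                        compute_flicker_stats, gser_modulus)
from flickerlab.rheology import fit_fractional_rigidity

m = MembraneParams()                      # healthy-discocyte defaults
a = ActivityParams()                      # phi = 0.3 kicker ensemble
cell = simulate_active_contour(m, a, N=512, T_frames=20_000, dt=0.5e-3, seed=0)

stats = compute_flicker_stats(cell, T=m.T, G0=m.basal_rigidity)
print(stats.summary())

spectrum = compute_psd(cell, segment_length=4096)
slope, err = fit_powerlaw(spectrum, (150.0, 1500.0))
print(f"PSD slope in the kicker window: {slope:.2f} +- {err:.2f}")

mem_x = MembraneParams(gamma=1.15e-4)     # tension + bending membrane
passive = simulate_passive_contour(mem_x, N=512, T_frames=100_000, dt=0.5e-3, seed=1)
rheo = gser_modulus(compute_psd(passive, segment_length=16384), passive.L, mem_x.T)
fit = fit_fractional_rigidity(rheo.band(0.8, 1500.0), R_bar=mem_x.R_bar, T=mem_x.T)
print(fit.summary())
```

prints

```
{'Sigma_nm': 34.14, 'two_Sigma_nm': 68.28, 'G_eff_uN_per_m': 3.674,
 'phi_est': 0.301, 'mean_Teff_K': 5648.27, 'mean_D_um2_per_s': 0.378}
PSD slope in the kicker window: -0.98 +- 0.00
fractional rigidity (staged) fit
================================
   parameter         value        stderr
     G_gamma    0.00028884     2.522e-06
     G_kappa    0.00010492           ---
       tau_D      0.010775           ---
       alpha       0.37155      0.000186
  omega_knee        92.806           ---
     omega_C          None           ---
   gamma_eff    1.0398e-09     9.081e-12
residual norm: 0.01458
```

Reading the numbers: the active cell fluctuates at Σ ≈ 34 nm
(equipartition elasticity ≈ 3.7 µN/m); the hot-spot detector recovers the
generator's active fraction (φ̂ = 0.301 vs 0.3); the mean effective
temperature sits far above the 310 K bath, the signature of nonequilibrium
kicking; and the kicker-band spectral slope is −0.98, the pink-noise
fingerprint of a telegraph-rate ensemble. The passive tension+bending
membrane shows a low-frequency tension plateau (G_gamma) crossing over at
ω_knee ≈ 93 rad/s to an anomalous bending branch with exponent
2α ≈ 0.74, i.e. α ≈ 1/3, the pure-bending value.

A CLI mirrors the library:
`flickerlab simulate|render|segment|morphotype|stats|spectrum|rheology|run`.

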