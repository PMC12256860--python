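"""Physical constants and shared defaults (SI units throughout)."""

#: Boltzmann constant (J/K)
KB = 1.380649e-23

#: Physiological bath temperature used in all defaults (K); 37 degC.
T_BODY = 310.15

#: Mean equatorial radius of a discocyte (m).
R_BAR_RBC = 3.6e-6

#: Basal (rigidized, cross-linked) fluctuation scale (m); Sigma_0 ~ 8 nm.
SIGMA0_RBC = 8e-9

#: Canonical acquisition: 2 kHz frame rate over >= 5 s.
DT_FRAME = 0.5e-3
DELTA_T_ACQ = 5.0

#: Canonical number of contour emplacements.
N_EMPLACEMENTS = 2048
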