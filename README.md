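# iondose

A desk-scale condensed-history Monte Carlo dose engine for therapeutic
ion beams — protons, helium, carbon and oxygen — in voxelized phantoms.
It is aimed at medical-physics researchers and students who need a
transparent, scriptable sandbox for ion-beam dosimetry: stopping-power
physics you can read, a transport loop you can instrument, and the
biological-dose and range-verification bookkeeping used in particle
therapy, without the footprint of a production Monte Carlo code.

## What it computes

**Stopping power.** The corrected Bethe–Bloch mass stopping power

    S/ρ = (2π n_e r_e² m_e c²/ρ) (z_eff²/β²) [ ln(2 m_e c² β² T_max / (I²(1−β²)))
          − 2β² + 2zL₁ + 2z²L₂ + K_M − 2C/Z − δ ]

with density (δ), shell (C/Z), Barkas (L₁), Bloch (L₂) and Mott (K_M)
corrections, effective charge for partially stripped ions, the full
kinematic T_max, restricted stopping for a delta-ray threshold, and
CSDA ranges.

**Transport.** Vectorized condensed-history stepping through voxel
phantoms: energy-loss caps and voxel-chord step control, Bohr
(Gaussian) straggling, Highland multiple scattering, nuclear
attenuation with a forward fragment-tail surrogate, and an energy
ledger that closes to float precision. Dose grids, laterally
integrated depth-dose curves with batch uncertainties, lateral
profiles, fluence spectra.

**CT calibration.** Hounsfield units from attenuation coefficients and
a Schneider-style stoichiometric segmentation (24 materials, 41 HU
intervals over [−1000, 3500]) with continuous density scaling;
user-replaceable via CSV; optional DICOM CT import.

**Biological dose.** Mixed-field linear-quadratic bookkeeping with
dose-weighted ᾱ, β̄ per voxel, RBE-weighted dose against a photon
reference (α/β = 2 Gy: α_ph = 0.1 Gy⁻¹, β_ph = 0.05 Gy⁻²), the
clinical constant proton RBE of 1.1, and spread-out-Bragg-peak weight
optimization to a flat D_RBE prescription.

**Metrics.** Bragg-peak position (sub-bin), dose-weighted dose
difference, weighted χ², distal ranges, DVH statistics (D50, V10).

**Monitoring.** β⁺-emitter maps (¹⁵O, ¹¹C) from fluence × cross
sections, decay/acquisition windows, PET ring coincidence scoring with
energy/time windows and dead time, sinogram binning, and prompt-signal
depth profiles with a 2 MeV gate and detector-resolution convolution.

See `docs/methods.md` for models, assumptions and surrogate choices.

## Worked example

A 150 MeV proton pencil beam in water (`examples/02_proton_bragg_curve.py`):

```
Bragg peak depth :  157.45 mm
distal R80       :  159.08 mm
CSDA range       :  158.63 mm
peak/entrance    :    4.55
energy ledger    : closure 2.17e-15 (deposited 98.5%)
```

The Bragg peak lands ~1 mm short of the continuous-slowing-down range
(straggling pulls it inward), the peak-to-entrance dose ratio is the
familiar ~4–5 for protons, and every MeV of beam energy is accounted
for. A biologically optimized carbon SOBP
(`examples/04_carbon_sobp_biodose.py`):

```
components              : 12 (161-243 MeV/u)
mean D_RBE in target    : 2.997 Gy (RBE)
max |D_RBE - 3 Gy(RBE)| : 0.152 Gy (RBE)
mean absorbed dose      : 1.860 Gy
alpha_bar proximal/distal: 0.279 / 0.639 Gy^-1
```

The optimizer flattens the *RBE-weighted* dose at the 3 Gy (RBE)
prescription over the 60–120 mm target; the absorbed dose it needs is
well below 3 Gy and falls toward the distal edge, where the slow,
high-LET carbon ions (rising ᾱ) are biologically more effective — the
signature of biological optimization.

The other `examples/` scripts cover stopping tables, HU calibration,
PET monitoring and curve metrics; each prints a few numbers and says
what they mean. A thin CLI (`iondose simulate|depthdose|biodose|
monitor|compare|make-phantom`) wraps the same pipelines for shell use.

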