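# Methods

`iondose` is a desk-scale condensed-history Monte Carlo engine for
therapeutic ion beams (protons, helium, carbon, oxygen) in voxel
phantoms. This note records the physics models, the parameter choices
that matter, the surrogates that replace full nuclear/fluctuation
theory, and the limits of what the synthetic test inputs can
demonstrate.

## Electronic stopping power

The mass electronic stopping power is the corrected Bethe–Bloch form

    S/ρ = (2π n_e r_e² m_e c² / ρ) · z_eff²/β² ·
          [ ln( 2 m_e c² β² T_max / (I² (1−β²)) ) − 2β²
            + 2 z L₁ + 2 z² L₂ + K_M − 2 C/Z − δ ]

with the maximum single-collision energy transfer

    T_max = 2 m_e c² β² γ² / (1 + 2γ m_e/M + (m_e/M)²)

kept in full — the m_e/M terms are *not* dropped, so the expression is
exact for light projectiles too. Terms and their provenance:

| term | role | implementation |
|------|------|----------------|
| δ | density effect (medium polarization) | Sternheimer: published liquid-water coefficients packaged; all other materials use the generic Sternheimer–Peierls prescription from I and the plasma energy |
| C/Z | shell correction (atomic binding at low E) | Barkas–Berger η-power fit (η = βγ), derived from proton stopping tabulations; clamped below η = 0.13 with a warning |
| L₁ | z³ Barkas correction | Jackson–McCarthy-style surrogate in the scaled velocity V = βγ/(α√Z̄); **surrogate** — the exact fit behind production codes is not public |
| L₂ | z⁴ Bloch correction | exact standard series ψ(1) − Re ψ(1+iy), y = z_eff α/β, via the complex digamma |
| K_M | Mott-cross-section correction | rational surrogate in the Born parameter χ = z_eff α/β; off by default for z ≤ 2, on for z ≥ 3; **surrogate** |
| z_eff | electron pickup at low velocity | z for protons/alphas at all energies; z(1 − exp(−kβz^(−2/3))) with k = 125 (config-exposed) for z ≥ 3 |

The mean excitation energy of water defaults to **78 eV**
(user-overridable; echoed in every run header); compound I values come
from Bragg additivity over Berger–Seltzer elemental values. With these
choices the proton-in-water stopping agrees with the packaged
ICRU-49/PSTAR-style reference grid to better than 1% over 10–250 MeV
(the regression guard allows 2%; the reference tabulation itself uses
I = 75 eV, which accounts for about half the residual).

Below **0.5 MeV/u** the Bethe bracket is unreliable; a Ziegler-style
velocity-proportional stopping S ∝ √E matched at that point is
substituted. The residual range below the switch is micrometres, far
under the millimetre voxel scale. The accepted energy domain is
0.01–1000 MeV/u.

Restricted stopping replaces T_max → T_up = min(T_max, T_cut) in the
logarithm and −2β² → −β²(1 + T_up/T_max); it equals the unrestricted
value when the threshold clears T_max. The delta-ray threshold floor is
1 keV. Delta rays are **not** transported: the default transport uses
unrestricted stopping deposited locally (local delta absorption), which
is the correct closure at the ≥ 1 mm voxel scale and keeps the energy
ledger exact.

CSDA ranges integrate A·dE/S by adaptive quadrature (rtol 1e-6) plus the
closed-form √E tail; transport uses log-spaced tables (200 points per
decade, monotone interpolation).

## Condensed-history transport

Primaries advance in vectorized lockstep. Each step is the minimum of
the energy-cap step (ΔE ≤ 2% of the current kinetic energy, config max
5%) and the chord to the next voxel face (half-open voxel boxes, beam
axis +z, positions in mm, physics in cm/g).

* **Energy-loss straggling** — Gaussian with the Bohr variance
  σ² = 0.1569 z_eff² (Z/A) ρ Δx (1−β²/2)/(1−β²) MeV², truncated to
  [0, E]. This is a deliberate surrogate for cumulant/Vavilov-class
  fluctuation models, which are not reproducible from public
  information; the model enum reserves a future `vavilov` option. The
  Gaussian approximation is good for the many-collision steps taken
  here and positions the peak correctly at the millimetre level.
* **Multiple Coulomb scattering** — Gaussian Highland angle
  θ₀ = (13.6 MeV/βcp)·z·√(t/X₀)·(1+0.038 ln(t/X₀)) per step,
  independent x/y kicks; radiation lengths from the per-element
  PDG-style formula combined by mass fraction (water: 36.3 g/cm² vs
  36.08 published). A surrogate for Molière theory; accurate to a few
  percent for the small per-step thicknesses used.
* **Nuclear interactions** — exponential removal with mean free path
  1/λ = Σ n_i σ_i(E). Default cross sections are a Bradt–Peters
  geometric form (r₀ = 1.35 fm) with a smooth 8 MeV/u threshold;
  per-(projectile, element) tables can be supplied. On interaction the
  primary is removed and its residual energy split: 60% deposited
  locally, 30% spread exponentially forward (decay length 2 cm) down
  the voxel column — the *fragment-tail surrogate* reproducing the
  qualitative dose tail beyond the Bragg peak — and 10% booked as
  escaped. All three fractions are config-exposed; they are
  phenomenological placeholders, never a substitute for an intranuclear
  cascade, and the CLI warns whenever they are active.
* **Termination** — below 0.25 MeV/u the residual energy (sub-keV to
  keV scale per nucleon, micrometre residual range) is deposited in the
  current voxel.
* **RNG** — counter-based Philox; primaries are split into batches
  (default 10), each with its own substream keyed on (seed, batch).
  Identical seed ⇒ bit-identical output; the batch spread provides the
  statistical uncertainty estimate on depth-dose curves.

The energy ledger (deposited + escaped + tail-escaped = beam energy) is
asserted to close to 0.1% in tests; in practice it closes to float
precision.

Scoring: per-voxel energy deposit; depth-binned primary track-length
spectra per species (the input to emitter production and mixed-field
biology); primary plane-crossing counts (for attenuation checks); and,
when an LQ table is attached, per-voxel dose-weighted α and β sums.

## Hounsfield-unit calibration

HU = 1000 (μ_x − μ_water)/(μ_water − μ_air). The packaged calibration
is a **synthetic Schneider-style table**: 24 tissue compositions over
41 half-open HU intervals tiling [−1000, 3500], each interval carrying
a nominal density at its centre plus a linear density slope, so density
is continuous inside intervals while composition is piecewise constant.
The compositions are ICRU-44-like (air, lung, adipose, water, soft
tissue, muscle, liver-like, marrow, and 16 soft-tissue/cortical-bone
mixtures); they are *not* the published Schneider values, which are why
the table is user-replaceable via two CSVs (segments + compositions)
for facility-specific calibrations. HU outside the table is clamped to
the nearest bound with a warning. Density scaling applies identically
to electronic and nuclear processes (separate multipliers are left as a
future config split).

## Mixed-field biological dose

Per voxel the LQ coefficients of a mixed field are dose-weighted
averages over all contributions: ᾱ = Σ dᵢαᵢ / Σ dᵢ and likewise β̄.
The RBE-weighted dose inverts the photon LQ response at equal effect
E = ᾱD + β̄D²:

    D_RBE = √( (α_ph/2β_ph)² + E/β_ph ) − α_ph/(2β_ph)

(the standard quadratic-root inversion; the positive branch is the only
physical one). The default photon reference is α_ph = 0.1 Gy⁻¹,
β_ph = 0.05 Gy⁻² (α/β = 2 Gy). Proton plans may instead apply the
clinical constant RBE of 1.1. LQ tables interpolate log-linearly in
energy per nucleon and clamp outside their grid (warned once). The
averaging uses total deposited dose per contributing species.

**SOBP optimization** minimizes the squared effect mismatch
Σ_z (E(z; w) − E*)² over non-negative component weights by NMF-style
multiplicative updates (deterministic, projection-free; 20k iteration
cap, 1e-12 relative tolerance). In `physical` mode the same update
flattens the absorbed dose and converges to the non-negative
least-squares solution. The fixture generator produces 12 carbon
components whose CSDA ranges span the target (60–120 mm by default)
with a 1.2% relative energy spread emulating the ripple filter used
clinically for carbon — without it the millimetre-wide carbon peaks
would leave large dose ripples between components. The distal-edge
infeasibility check allows a two-bin grace for half-bin peak sampling.

## Comparison metrics

The two similarity estimators are named in the benchmarking literature
but rarely written out; the forms fixed here (one function each, so
alternates can be swapped) are:

* dose-weighted dose difference: Σ w|D_sim − D_ref| / Σ w D_ref with
  w = D_ref, on a common grid;
* weighted χ²: Σ D_ref (D_sim − D_ref)² / Σ D_ref after normalizing
  both curves to unit mean over the common grid. The normalization
  makes the statistic unit- and grid-density-independent and places
  sub-percent discrepancies in the conventional 1e-5..1e-4 decade.
  Dose weights (not statistical weights) are used; the report metadata
  records this choice.

Curves are resampled to the finer of the two grids with monotone PCHIP
interpolation. Bragg-peak positions use parabolic interpolation through
the maximum bin (ties break shallow). DVHs are cumulative with exact
quantile accessors (D50, V10).

## PET / prompt-signal monitoring

β⁺-emitter production folds the depth-binned primary track-length
spectra with reaction cross sections and target-nuclide densities
(production = Σ_E L(z,E) σ(E) n_target — no volume factor needed since
track length × number density already gives interactions). Depth yields
are distributed over the transverse voxels of each slice proportionally
to that slice's dose pattern — a localization surrogate for full 3D
fluence scoring, adequate for pencil beams. Packaged fixture cross
sections are threshold-plateau surrogates of ¹⁶O(p,x)¹⁵O (17 MeV,
~70 mb) and ¹²C(p,x)¹¹C (20 MeV, ~80 mb); EXFOR-derived tables are
user-supplied CSVs.

Decay windows use N(e^{−λt₀} − e^{−λ(t₀+Δt)}) with an optional uniform
washout rate added to λ. The ring detector is a geometric cylinder:
crystals are perfect absorbers on two opposed azimuthal arcs each
spanning 2×`opening_angle`, so 180° closes the ring and 0° removes all
detectors; module substructure reduces to angular segmentation for
dead-time bookkeeping. Energy resolution is Gaussian with FWHM
frac·√(E·E_ref) (√E scaling; a config switch makes it
energy-independent). Positron range defaults to zero (annihilation in
the production voxel) and acollinearity to off; both have optional
Gaussian blurs with user-set widths, since no public parameters exist
to calibrate them here. Sinogram binning canonicalizes each line of
response to the upper half-plane direction before computing the signed
radial offset, so (s, φ) is independent of photon labelling; counts are
conserved into an overflow tally.

## Numerical choices and degenerate inputs

* Voxel chords get a 10 nm nudge so particles never stick to faces;
  steps have a 10 nm floor and transport aborts (never hangs) after a
  step-count safety cap.
* Zero-dose voxels return ᾱ = β̄ = 0 (defined null, no NaN).
* The γ–β consistency check on kinematic states widens as γ³ because
  recovering γ from β is ill-conditioned.
* Energy-grid fluence histograms span [0, 1.05·E₀ + 5σ_E] in 64 bins.
* Zero-density voxels drift (no loss, no scattering).

## What the synthetic inputs do and do not show

The generators produce water/layered slab phantoms, analytic Bragg-like
curves, carbon-like LQ tables (α rising from 0.1 to ~1.1 Gy⁻¹ as the
ion slows, shaped like LEM-derived databases) and threshold-plateau
cross sections. Passing tests therefore demonstrate internal
consistency — correct formula assembly, conservation, the documented
sampler moments, and the qualitative clinical shapes (Bragg peak short
of the CSDA range, ᾱ rising to the distal edge, activity falloff a few
mm before the peak). They do **not** demonstrate agreement with
measured depth-dose data, real fragment spectra, real radiobiological
databases, or scanner-specific PET performance: those require the
proprietary inputs and full nuclear models explicitly out of scope.

## Problem sizes

Default study conditions: 10⁴ primaries per mono-energetic beam on
1 mm voxel grids (40×40×200 mm water for protons at 150 MeV); SOBP
workflows use 12 carbon components × 10⁴ primaries; sampler-moment
checks use 10⁶ draws; coincidence checks use 2×10⁴ decays. A full
SOBP optimization runs in well under a minute on one CPU.

## Known limitations

* No secondary-particle transport (deltas, fragments, neutrons); the
  fragment tail is a 3-parameter phenomenology.
* Gaussian straggling underestimates the skewness of energy-loss
  distributions for very short steps (not a regime the step controller
  enters).
* The Barkas and Mott surrogates are accurate only at the sub-percent
  level they contribute; heavy-ion (z > 8) stopping would need the real
  fits.
* The packaged HU table is structurally faithful but numerically
  synthetic; clinical use requires a facility calibration CSV.
* Sinogram binning is 2D transaxial (no ring-difference /
  3D-acquisition parameters), and no image reconstruction is included.
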