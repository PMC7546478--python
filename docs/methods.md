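# Methods

`magbrachy` simulates how a uniform magnetic field reshapes the dose
deposited by the electrons and photons of an ¹⁹²Ir HDR brachytherapy
source in low-density lung tissue, and provides the downstream
dosimetry analysis (iso-dose geometry, TG-43 parameters, DVH metrics).
This note records the physics model, its parameters and the design
choices, so that the limits of what the package can and cannot show are
explicit.

## Transport model

**Electrons.** Condensed-history transport with:

- *Continuous energy loss*: the Berger–Seltzer mass collision stopping
  power evaluated from each material's composition and mean excitation
  energy (water 75 eV, lung 75.3 eV, air 85.7 eV; alloys by Bragg
  additivity). The density-effect correction is omitted — below 1 MeV
  in low-Z media it is under ~2% and only rescales the millimetre scale
  of every scenario equally. Radiative losses are neglected (< 2% of
  the total below 1 MeV in tissue) and no bremsstrahlung photons are
  generated.
- *CSDA range* by quadrature of 1/S_col on a 1200-node log grid;
  step length = `dr_over_range` (default 0.2) × residual geometric
  range, capped by `max_step`.
- *Multiple scattering*: Highland's Gaussian width
  θ₀ = 13.6 MeV/(βcp)·√(x/X₀)·(1 + 0.038 ln(x/X₀)) applied once per
  condensed step, with X₀ from the PDG mixture rule. This is a Gaussian
  (small-angle) model: it has no Mott/Rutherford large-angle tail, which
  is the main known fidelity gap versus Goudsmit–Saunderson transport
  (see *Limitations*).
- *Magnetic field*: between deflections the electron follows the
  **exact analytic helix** for the uniform field — position and
  direction are rotated about B̂ with curvature k = 0.29979·B[T]/pc[MeV]
  per mm. A classical RK4 integrator would merely approximate this
  closed form, so the helix is used directly; the `chord_tolerance`
  parameter (default 0.05 mm) retains its meaning as the maximum
  sagitta of the straight chords used for voxel deposition, enforced by
  sub-stepping. With B = 0 the step degenerates to a straight line.
- *Voxel deposition*: each chord is marched through the grid with a 3D
  DDA and the continuous loss is apportioned to voxels by exact path
  length (grid indices 0-based; voxel *i* spans
  `[origin + i·spacing, origin + (i+1)·spacing)`).
- *Termination*: electrons are absorbed on the spot when the residual
  range falls below `final_range` (10 μm) or the energy below
  `electron_cutoff` (10 keV). Electrons leaving the grid escape; the
  world is the phantom, as in the emulated setup.
- *δ-ray production* (optional, on in the canned study scenarios):
  hard Møller collisions above a per-material threshold equivalent to a
  0.05 mm range cut are sampled discretely (1/ε² majorant rejection on
  the full Møller factor), with the restricted Berger–Seltzer stopping
  power used for the continuous part. The restricted + discrete pieces
  reconstruct the unrestricted stopping power to < 0.1% (tested). The
  δ-ray's polar angle follows binary-collision kinematics; the
  primary's deflection in the collision is neglected.
- *Energy-loss straggling* (optional, off by default): Gaussian Bohr
  straggling applied to the soft continuous loss.

**Photons.** Analog transport with Woodcock (majorant) tracking across
the voxel grid; at a real interaction the channel is chosen between
free-electron Klein–Nishina Compton scattering (Geant4-style
composition–rejection sampling of ε = E'/E; binding ignored) and a
parametrized photoelectric absorption
τ/ρ ∝ Σᵢ wᵢ(N_A/Aᵢ)Zᵢ⁴·⁵·E⁻³, anchored so that the photoelectric and
Compton components of water cross at 26 keV. Rayleigh scattering is off
(elastic, no energy deposit; a percent-level transport perturbation at
these energies). Pair production is impossible (all source lines are
below 1.022 MeV). Photons are insensitive to the field; their
secondary electrons are transported with it. Tracking cutoff 5 keV.

Per-history energy bookkeeping (deposit + escape + in-seed absorption =
emission) is exact by construction and asserted to 10⁻⁹ relative in the
test suite.

**Reproducibility.** All kernels draw from a splitmix64 generator with
one substream per (seed, batch); runs are bit-identical for a given
seed and configuration and independent of how batches are scheduled.
Dose grids carry per-voxel batch means and the SEM over batches.

## Sources

- **Point electron sources**: isotropic; monoenergetic (432 keV — the
  Compton edge of the 612 keV gamma line, i.e. the maximum energy an
  ¹⁹²Ir photon can transfer to a secondary electron in one collision)
  or spectral.
- **Secondary-electron spectrum**: regenerated rather than digitized —
  a gamma line is drawn with probability ∝ intensity × total water
  cross section, the channel chosen by the water branching ratio, and
  the electron energy sampled (Klein–Nishina) or taken whole
  (photoelectric). Lines above the 612 keV group (0.3% of emissions)
  and the ~10⁻⁴ photoelectric events above the Compton edge are
  excluded so the spectrum keeps its kinematic support [0, 432 keV].
  A user-supplied two-column CSV overrides the generated spectrum.
- **Encapsulated seed**: iridium core (0.17 mm radius, two 2.5 mm
  cylinders) inside a 6.59 × 0.59 mm Ti–Ni (44:56, 6.5 g/cm³) casing
  with a 2 mm drive-wire stub on the −axis side (the stub is shown only
  pictorially in the source literature; its length is configurable).
  Emission points are uniform over the core cylinder, directions
  isotropic, energies from the embedded principal-gamma-line table
  (intensity-weighted mean 0.372 MeV; the 1.06 MeV line at 0.05%
  intensity is omitted). First-flight attenuation through core, casing
  and stub is computed by analytic ray–cylinder intersection; photons
  scattered *within* the seed are treated as absorbed. This biases the
  absolute output per decay by a few percent but cancels in all
  normalized distributions.
- **Plans**: dwell positions with weights; a history's dwell position
  is drawn from the weight CDF, which reproduces "histories ∝ dwell
  weight" in expectation. The default plan is the embedded 4-position,
  −152°, 20 Gy configuration. An algebraic combinator
  (`combine_plan_doses`) is provided for exactly-linear weighted sums
  of separately scored per-dwell grids.

## Analysis conventions

- **Reference-point normalization**: dose grids from the ideal studies
  are normalized to 100% at (1 mm, 0, 0), averaged over the 3×3×3
  voxel neighborhood (the neighborhood suppresses single-voxel Monte
  Carlo noise; the reference must have < 5% relative SEM).
- **Iso-dose distances**: outermost crossing of the level along the
  ±x/±y axis rays through the source (3-voxel-wide tube averaging,
  linear interpolation between bracketing voxels), reported as
  mean ± SEM over directions. An azimuthal-average mode is available;
  the two agree on radially symmetric fields (tested).
- **Difference maps**: 100·(B−A)/A, masked where |diff| ≤ 2% or below
  one combined standard deviation.
- **DVH**: Vx by exact voxel counting, Dx by interpolated percentile,
  D2cc by exact partial sort (a sort-oracle equality is asserted in
  tests); curves binned at 0.5% of prescription.
- **Prescription normalization**: anchored on D90(PTV) — the standard
  interstitial prescription surrogate; the anchor is recorded in the
  grid metadata. For field-comparison pairs the scale factor is derived
  once from the no-field run and applied to both grids: the plan's
  dwell times are fixed, so renormalizing each field separately at desk
  scale would fold sampling noise of the anchor into a spurious global
  offset between the grids.

## TG-43

The line-source geometry function uses the closed form
G_L = β/(L·r·sinθ) with the on-axis limit (r² − L²/4)⁻¹; the active
length L = 0.5 cm follows from the two 2.5 mm core cylinders. The
water dose-rate table is scored in (r, z) bins of 0.05 cm inside a
15 cm-radius, 15 cm-height water cylinder, by default with a
track-length collision-kerma estimator (E·μ_tr/ρ per path length, with
μ_tr from the package's own Compton mean-energy-transfer fraction and
photoelectric channel) — valid where transient electron equilibrium
holds, i.e. beyond ~0.5 cm for these energies; an analog
interaction-site estimator is available behind a flag. Air-kerma
strength is scored in vacuo on a 100 cm sphere with 1° polar bins; the
two bins straddling 90° are weighted with the embedded air μ_en/ρ
table (5 keV cutoff) and multiplied by d². With both quantities per
emitted history, Λ = Ḋ(1 cm, 90°)/S_K is numerically on the
cGy·h⁻¹·U⁻¹ scale. At 2×10⁵ histories the package computes
Λ ≈ 1.14 cGy·h⁻¹·U⁻¹, g(r) ≈ 1 slowly decreasing, and F(r, θ) < 1
near the long axis with a stronger dip on the wire side.

## Synthetic phantoms

- **Lung cube**: 1 cm³, 0.05 mm voxels (the studies are typically run
  at 0.1 mm to halve memory and time; the mm-scale iso-dose geometry is
  unchanged, which was verified against 0.05 mm runs), uniform
  0.26 g/cm³ ICRP-composition lung — the average of inflated and
  deflated states.
- **Thorax**: CT-like grid (0.69 × 0.69 × 1.0 mm, 60 slices). Two
  elliptic-cylinder lungs sized to hold ≈895 cm³ jointly, filled with
  a correlated Gaussian density field (5 mm correlation length, σ =
  0.12, clipped to [0.01, 0.6] g/cm³, mean ≈ 0.26) inside a
  muscle-density body. The tumor is a water-density **prolate
  ellipsoid**: its long axis (2.8 cm) follows the catheter and its
  volume is grown voxel-wise to exactly 3.9 cm³ — the only shape
  consistent with both stated tumor numbers, and the natural geometry
  of a lesion threaded by a single catheter (a 3.9 cm³ sphere would be
  narrower than the 2.1 cm dwell span). A plain-sphere fallback with
  the stated diameter is available. The PTV is grown from the tumor
  surface by Euclidean distance to exactly 12.8 cm³. HU→density
  conversion is a documented piecewise-linear (Schneider-style)
  mapping with HU = 0 → 1.000 g/cm³ by definition; densities are
  mapped to air/lung/water/muscle for cross-section lookup while the
  continuous density scales the mass.

What the thorax phantom does **not** emulate: real contoured anatomy
(ribs, vessels, airways), breathing, CT noise/beam hardening, or the
actual patient's density histogram. Clinical-analog results therefore
test the *procedures* (plan weighting, prescription normalization, DVH
and difference-map analysis) and the qualitative field effects, not
patient-specific values.

## Problem sizes

The reference study used 2×10⁸ (ideal) and 3×10¹⁰ (clinical)
histories on a cluster. The package's canned runs use sizes chosen so
the whole reproduction completes in minutes on one core while keeping
the mm-scale geometry stable across seeds: 5×10⁵ electron histories on
a 0.1 mm grid for each ideal run, and 4×10⁶ photon histories per field
for the thorax plan — the smallest size at which every tumor/PTV voxel
of the 0.69 mm CT grid is sampled and the D90(PTV) anchor is stable.
Field pairs share one seed: photons are field-independent, so common
random numbers give identical interaction sites and isolate the
electron-transport difference.

## Known limitations

- The Gaussian (Highland) multiple-scattering model lacks the
  large-angle single-scattering tail and the path-length corrections of
  Goudsmit–Saunderson condensed-history transport. The field-free
  iso-dose geometry is insensitive to this; the **with-field 10%
  iso-dose of the 432 keV study is not** — its radius is set by the
  dose-weighted reach of first-gyration orbits (2·r_g = 1.76 mm at
  3 T), and the package obtains ≈1.9–2.0 mm where
  Goudsmit–Saunderson-based transport reports ≈1.4 mm. The value is
  insensitive to step size, δ-ray production and straggling (all
  probed), so it is reported as a genuine model limitation rather than
  tuned away. The spectrum study, whose electrons are softer, does not
  suffer from this.
- Photoelectric cross sections are a one-anchor power law; adequate in
  tissue at ¹⁹²Ir energies (sub-percent channel), crude inside the
  high-Z seed, where it perturbs self-absorption by a few percent and
  cancels in normalized quantities.
- No atomic relaxation, no Rayleigh by default, no positrons, no
  electron re-entry from outside the phantom (pad the world if the
  electron-return effect at the boundary matters).
- Kerma ≈ dose is assumed by the TG-43 track-length estimator within
  ~0.5 cm of the seed; use the analog mode there.
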