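# Methods

`fibrilmd` simulates the tensile response of a collagen fibril as a
coarse-grained bead–spring bundle: each tropocollagen (TC) molecule is a
chain of beads (one bead per ~5 residues, mass 1358.7 amu), chains are
packed on a triangular cross-section lattice with the collagen-specific
D-period stagger, cross-links of three kinds join neighbouring chains, and
the bundle is pulled apart between two rigid clamps while forces, bond
ruptures and molecular sliding are recorded.

## Interaction model

**Bonds (trilinear, breakable).** The tension between two bonded beads is
piecewise linear in the separation r:

    F(r) = k0 (r − r0)                       r < r1
         = k0 (r1 − r0) + k1 (r − r1)        r1 ≤ r < r_break
         = F_peak · (1 − (r − r_break)/a)    r_break ≤ r < r_break + a
         = 0                                 r ≥ r_break + a

with the regularization ramp width a = z (r_break − r1), z = 0.05. The
printed form of this law is discontinuous at r1 (both sub-laws pass through
r0) and gives a negative a under a literal reading; the implementation uses
the unique continuous reading above, which preserves the role of z as a
numerical regularization of rupture. Per-species constants (backbone,
reinforced end extensions, divalent and trivalent enzymatic cross-links,
glucosepane-like AGEs) ship in `src/fibrilmd/data/forcefield.yaml`; every
field can be overridden from the experiment config. A bond is *counted*
broken at its first crossing of `r_break` (onset of softening) and removed
from force evaluation permanently beyond `r_break + a`; broken bonds never
re-form, and dead bonds contribute their rupture-work plateau to the energy.

**Angles.** Harmonic bending E = k_B (φ − φ_i)² about per-triplet
equilibrium angles φ_i read off the as-built geometry (170°–180°). Whether
k_B absorbs the factor 2 (E = k Δφ² vs ½ k Δφ²) is genuinely ambiguous in
the source literature; the factor-2-free convention (moment 2 k_B Δφ) is
the default and the other is exposed as `AngleLaw.convention_factor = 0.5`.
Cross-link bonds carry no angle terms with adjacent backbone beads.

**Pairs.** 12-6 Lennard-Jones (ε = 6.87 kcal/mol, σ = 14.72 Å) with a soft
core: below λσ (λ = 0.9) the force is capped at its value at λσ and the
energy continues linearly. The cutoff is 2.5 σ with the energy shifted to
zero there (standard truncation; the residual force at the cutoff is
~0.02 kcal mol⁻¹ Å⁻¹). Directly bonded pairs — backbone/extension 1–2
neighbours and cross-linked pairs — are excluded from the pair sum; 1–3 and
beyond are not, so a perfectly straight chain feels a weak axial LJ
contraction (documented in the tests).

**Units.** Energies kcal/mol, lengths Å, time fs, masses amu. One constant
(4.184e-4 amu Å² fs⁻² per kcal/mol) converts force/mass to acceleration;
stress is computed natively in kcal mol⁻¹ Å⁻³ (1 ⇒ 6947.7 MPa, applied only
at reporting). A pulling speed of 1e-4 Å/fs is 10 m/s.

## Geometry generator

The axial window has length W = L_mol + 0.6 D (molecule contour plus one
gap zone, D = 670 Å). Each lattice site hosts one molecule whose start is
offset by (site index mod n_periods)·D, wrapped into the window; a wrapped
molecule becomes two bonded chain pieces sharing one molecule id. Chain
faces that terminate at a window boundary are continued by reinforced
extension beads (same law, r_break = 70 Å) and the outermost 10 beads of
each extension form the two rigid clamp groups. Natural chain ends carry
the 4-bead telopeptide flag and are the only enzymatic cross-linking sites.
Note one known inconsistency of the published numbers: 218 beads at 14.0 Å
plus a 0.6 D gap spans 5.134 D, so in the full geometry four of the five
circular banding intervals are exactly D and one absorbs the slack.

Molecule waviness is a two-component sinusoidal transverse undulation
(amplitude 1.2 Å, period 5 beads, random phases) laid out with *exact*
14.0 Å chord spacing; the per-triplet angles of the generated path become
the equilibrium angles, so the as-built fibril is stress-free in its bonded
terms and all φ_i stay within [170°, 180°]. An optional reader for a
PDB-format reference structure can replace the synthetic waviness by
spline-derived control points.

The cross-section lattice spacing defaults to 15.45 Å, which meshes the
20.2 nm disc with 151 molecules (the published count is 155; the exact mesh
spacing behind that count is not stated, so the count is treated as a tuned
default, not a law).

**Cross-link capture radius (24 Å).** "Neighbouring molecules" must mean
adjacent lattice lines. At 15.45 Å spacing the second-neighbour shell sits
at 26.8 Å, so the naive 2 r0 = 28 Å radius would admit second-shell,
same-stagger partners; 24 Å separates the first shell (≤ ~21 Å including
waviness and thermal swell) from the second and is the default for both ECL
and AGE insertion.

## Simulation protocol

Velocity Verlet with a Langevin thermostat (damping 1000 fs, impulsive OU
velocity update every 10 steps) at 300 K. Clamp groups are kinematic rigid
bodies: fixed during minimization (steepest descent then conjugate
gradients) and equilibration, displaced symmetrically at ±v/2 during the
tensile test. Cross-links are inserted only after the first equilibration,
followed by a re-equilibration, matching the staged protocol. Initial
velocities are Maxwell–Boltzmann at the run seed; all randomness derives
from config seeds and reruns are bit-identical.

During steered pulling the thermostat is *profile-unbiased* in the axial
direction: each bonded chain's axial damping is taken relative to the
chain's mean axial velocity. Without this, the drag γ m v on beads advected
with the clamps sums to a spurious stress floor (~0.05 in mini-fibril
stress units) that never decays and masks failure.

The load signal is the average of the two signed clamp tensions (not of
their magnitudes: the magnitude of a thermally fluctuating net force has a
positive mean that, like the drag, never decays). Engineering strain is the
relative change of clamp separation from the start of pulling; engineering
stress divides by the as-built cross-section area π d²/4. A run ends when
the smoothed stress falls below 5% of its running peak, or at the strain
cap.

Neighbour lists are Verlet lists (cutoff + 6 Å skin) rebuilt by an O(N²)
pass whenever any bead moves more than a conservative fraction of the half
skin; an O(N²) reference summation validates the neighbour-list forces in
the tests. The integrator aborts if any per-step displacement exceeds half
the skin (timestep guard).

## Problem sizes and timesteps

Two presets exist. `full` mirrors the published system (218-bead molecules,
20.2 nm diameter, 5 D-periods, 80 ns equilibration at Δt = 10 fs, tensile
Δt = 1 fs) and is provided for completeness; it is cluster-scale and not
exercised by the tests. `mini` is the desk-scale system every test, sweep
and acceptance computation uses: 7 lattice sites, 68-bead molecules (so the
window is exactly 2 D), 2 stagger classes, 15 extension beads per loaded
end, ~630 beads in total. Equilibration runs 0.1 ns at Δt = 10 fs,
re-equilibration 0.05 ns, and the tensile test uses Δt = 20 fs at the
published 10 m/s. The 20 fs step is ~1/40 of the stiffest bond period
(k1 = 97.66 kcal mol⁻¹ Å⁻² at reduced mass m/2) and ~1/8 of the descending
rupture-ramp timescale; the ramp is a softening branch, so the occasional
overshoot merely completes a rupture that is already under way, and the
thermostat absorbs the bounded energy error. One mini tensile run takes
roughly half a minute of one-CPU time.

## What the mini fibril does and does not reproduce

Reproduced (see `tests/test_acceptance.py`): the strong increase of peak
stress and work to failure with AGE density; the near-coincidence of curves
below the elastic limit with divergence beyond it; a detected
departure-from-linearity strain near 0.15; Δσ ≈ 0 at low AGE density vs a
large stiffened regime at N_AGE = 40; the switch from cross-link-dominated
failure (zero backbone breaks) at low density to backbone rupture with
reduced cross-link failure fractions at high density; the drop of the mean
per-AGE force (to less than half) at matched strain when density rises
80-fold; and growing intermolecular sliding (ε_TC lagging ε) past ε₀ at low
density.

Known desk-scale limitations, visible as quantitative shifts rather than
qualitative changes:

* With only 2 stagger classes on a 7-site triangular lattice, ~45% of
  admissible AGE site pairs join same-stagger (never-sliding) molecules and
  only ~27% sit on the single sliding interface, capping the AGE broken
  fraction at failure near ~29% (the full 5-period fibril, with essentially
  no same-stagger neighbours, reaches 40–60%). The corresponding acceptance
  check is intentionally left failing rather than re-tolerated.
* At 25% ECL content the mini fibril carries 4 enzymatic cross-links, so
  broken-ECL fractions are quantized to 25-point steps (observed median
  50%, vs ≈40% at full scale).
* The mini system carries a small equilibrium prestress (~0.01 stress
  units) from holding the thermalized bundle at fixed clamp separation, and
  its elastic limit sits slightly earlier (~0.11–0.17 across seeds) than
  the full-scale 0.15.

The synthetic generator emulates geometry and connectivity, not sequence-
or residue-level chemistry: cross-link sites are uniform over admissible
pairs, one AGE species (glucosepane-like constants) represents all AGEs,
divalent and trivalent ECLs are not mixed within one run, and there is no
solvent, mineral phase or radius-dependent cross-link density. Passing
tests therefore demonstrate the mechanics of the idealized cross-linked
bundle, not predictions for any specific tissue.

## Numerical choices

* Stress smoothing: centered moving average over a 0.002-strain window
  before peak extraction (raw curves always archived); summary metrics use
  trapezoidal W_f up to the failure strain (first post-peak σ < 5% σ_peak),
  linear interpolation for σ(ε₀), and Δσ clipped at zero.
* ε₀ policy: `fixed` (0.15) by default; the `detect` policy estimates the
  tangent on 0.005-strain bins, requires the >10% deviation from the
  [0.02, 0.10] secant modulus to be sustained over three consecutive bins,
  and refines the change point by a continuous two-segment least-squares
  fit (exact to one bin on noiseless piecewise-linear input).
* Angle forces use the standard harmonic three-body formulation with the
  sine clamped at 1e-8 to handle exactly collinear triplets.
* Minimization accepts the conjugate-gradient result only if it does not
  increase the energy reached by steepest descent.
* Sweep cells are seeded by a CRC of the cell coordinates, making results
  independent of execution order and resumable from archives.
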