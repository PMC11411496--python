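# Methods

## Units and constants

Lengths in nm, charges in elementary charges *e*, masses in Da, energies
in kJ/mol, forces in kJ mol⁻¹ nm⁻¹, times in ps (MD step sizes are given
in fs).  The Coulomb factor 1/(4πε₀) is hard-coded to
138.935458 kJ mol⁻¹ nm e⁻², the MD-community value, so results are
directly comparable with mainstream MD engines.  File coordinates (PQR,
PDB, XYZ) are Ångström on disk and converted on read/write.  Everything
is computed in double precision.

## Direct oracle

`coulomb_direct` evaluates Coulomb's law over all pairs with no cutoff
and no periodicity, tiled over upper-triangular position blocks so each
pair is computed once and forces stay antisymmetric to round-off (net
force ~10⁻¹³ relative).  Coincident particles raise an error naming the
pair.  Every accuracy statement in the package is made against this
oracle; `fmm_forces` with depth 0 *is* this code path, so the two agree
bit for bit.

## FMM formulation

Scaled solid harmonics are used throughout: regular
R_l^m(r) = r^l P_l^m(cos θ) e^{imφ}/(l+m)! and irregular
I_l^m(r) = (l−m)! P_l^m(cos θ) e^{imφ}/r^{l+1}, computed by stable
recurrences (no factorials materialize).  They satisfy
1/|b−a| = Σ R_l^m(a)·conj(I_l^m(b)), an exact finite convolution identity
for translating regular expansions (M2M, L2L), and a convergent one for
irregular translations (M2L).  All four identities are verified to
machine precision in the unit tests.  The five operators are materialized
as dense matrices per translation vector and applied to batches of
expansions by matrix multiplication; local-expansion forces come from the
analytic gradient shift relations of the regular harmonics, never from
finite differences (which would contaminate the error metric).

Conventions: the monopole coefficient equals the enclosed charge;
coefficient tables store m ≥ 0 only in the public dataclasses (conjugate
symmetry c(l,−m) = (−1)^m conj(c(l,m)) reconstructs the rest), while the
solver works on full flat tables internally.

The octree is uniform (depth *d*, 8^d deepest cells, cell assignment by
coordinate floor with upper-boundary clamping).  "Directly neighboring"
means the full face+edge+corner 26-neighborhood.  Far-field work at each
level uses the classical well-separated interaction list (children of the
parent's neighborhood minus the cell's own neighborhood, ≤ 189 cells);
there is no periodic wrap.  Degenerate depths behave as documented:
d = 0 is explicit summation; d = 1 routes everything to the near field
because all eight cells are mutually adjacent.  Empty cells carry no
expansions and appear in no work list.  Traversal follows sorted cell
indices, so identical inputs give bit-identical outputs.

Energies use the same near/far split: exact pair energies in the near
field, ½ Σ qφ over the local expansions in the far field.

## Force-error metric

The error of an approximate force set against the oracle is the average
relative difference over all 3N per-atom Cartesian components.  The
default normalization is global: the mean absolute component deviation
divided by the mean absolute reference component,
Δ = Σ|f̂−f| / Σ|f|, in percent.  A per-component variant (mean of
|f̂−f|/|f| with components below 10⁻⁶ × RMS excluded and counted) and an
RMS-normalized variant are available.

The global form is the package default for a substantive reason: the
0.016 % accuracy budget originates as the round-off discrepancy between
two independent explicit-summation codes, and round-off or truncation
noise evaluated as a raw mean of per-component ratios is dominated by the
handful of components whose reference value happens to pass near zero
(observed: the top 0.1 % of ratios reach ~10⁰–10¹ even when the global
error is ~10⁻⁵).  Under the global reading, single- versus
double-precision explicit summation on the benchmark system differs by
~0.001 %, and the recommended (d, p) combinations land below the budget
with the expected margins; under the raw per-component reading neither
reproduction holds.

## Accuracy benchmark and the plateau

`accuracy_grid` computes Δ for a (d, p) grid against one oracle
evaluation, reusing the p-independent near field per depth.  On the
2×10⁴-particle globular benchmark system the budget is met from p = 4–5
at d = 2, p = 6–7 at d = 3 and p = 7–8 at d = 4: deeper trees shrink the
explicitly summed near field and so demand better far-field expansions.

`plateau_onset` operationalizes "the error levels off" on a log-scale
error-versus-order curve: the onset is the smallest p beyond which the
error never again improves by 2× in one step.  In double precision the
measured decay is cleanly geometric (per-step ratio drifting from ~0.40
to ~0.52 by p = 18) and the onset falls at p ≈ 15–16; codes that
accumulate forces in single precision instead hit their round-off floor
(~10⁻⁴ %) at p ≈ 8–12 — our curve passes through that error magnitude in
exactly that order range — and flatten there.  This package deliberately
keeps the solver in double precision (the oracle must dominate the FMM
error) and treats 0.016 % as an accuracy budget, not as a precision
artifact to reproduce, so the single-precision plateau is *not*
reproduced; the corresponding check in the acceptance tests documents
this and fails by design.

## Operation tallies, scaling, settings selection

`count_operations` tallies, from occupancy grids alone (no force math):
near-field pair interactions, M2L translations between occupied cells per
level, M2M/L2L translations, and per-particle expansion passes.  The
counts match the work the force pipeline actually performs (asserted in
tests).  The scalar used for scaling fits and settings selection is a
flop-unit total: 25 per near pair (difference, dot, rsqrt, scale,
accumulate), 8(p+1)⁴ per cell translation and 8(p+1)² per per-particle
pass (8 = one complex multiply-add).  These weights are part of the cost
model, not tunables; they make one unit mean one floating-point operation
in every term, which is what a hardware-free analogue of wall-clock time
requires.

`best_settings` picks the cheapest member of the accurate-settings ladder
(2,5), (3,7), (4,8), (5,9), (6,10) by that total.  The first three are
the recommended combinations for proteins up to a few MDa; the deeper two
extend the same depth-to-order progression so that selection stays O(N)
beyond that range (at fixed density and capped depth the near field grows
quadratically).  Both extensions are verified below the 0.016 % budget on
the 2×10⁴-particle system in the test suite (measured 0.0026 % and
0.0017 %).  `scaling_study` generates globular systems across sizes
(default 10³–10⁶, net charge growing ~√N as in positive-mode ESI), fits
log₁₀(tally) against log₁₀(N) excluding the smallest size, and lands at
slope ≈ 1.24 with best-per-size settings versus 2.000 for the explicit
d = 0 control.

`recommend_settings` maps system size to the three recommended
combinations via mass bands of <330 kDa, 330 kDa–1.5 MDa and >1.5 MDa,
using 135 all-atom sites per kDa (≈7.4 Da per atom, a defensible protein
composition average); the band edges derive from performance measurements
on specific hardware, so they are indicative rather than sharp.

## Synthetic systems

The generator emulates the one property of protein ions the solver
actually feels: a compact all-atom charge distribution at ~100 atoms/nm³.
Envelopes are a uniform ball (globular), a prolate spheroid of given
aspect ratio (extended) or a spherical shell (hollow), filled uniformly;
composition is H/C/N/O at 50/30/10/10 % with element-table masses and
radii; partial charges are uniform on [−0.5, 0.5] e (typical force-field
magnitudes — the solver is charge-distribution-agnostic) and the residual
to the integer target net charge is spread over sites in the outer 20 %
of the envelope, mimicking surface protonation.  Everything is bitwise
deterministic per seed.

What the generator does *not* emulate: bonded structure and the strong
charge correlations of real force fields, side-chain chemistry (the
"residue" is collapsed to a particle; negative sites are not preferred
protonation targets), and sterically relaxed packing — randomly placed
atoms overlap, so the synthetic systems are valid electrostatics and CCS
benchmarks but are not Lennard-Jones-stable starting points for MD.
Passing tests therefore demonstrate solver accuracy and scaling on
protein-*like* charge distributions, not force-field realism; MD
demonstrations use lattice toys or externally prepared structures.

For file-based systems, `assign_net_charge` protonates (+1 e) randomly
chosen distinct sites whose Shrake–Rupley solvent-accessible surface area
exceeds 5 Å² (probe 0.14 nm, 960 sphere points by default; SASA itself is
delegated to biotite's Shrake–Rupley implementation behind the package's
own surface).

## Collision cross sections

`pa_ccs` implements the projection approximation: the CCS is the mean
over uniformly random orientations (seeded quaternion sampling) of the
projected area of the union of disks with radius atom radius + probe
radius, multiplied by the empirical calibration factor 1.14 that aligns
PA values of protein ions with drift-tube measurements.  The default
probe radius is 0.1 nm (a nitrogen-like effective hard sphere); both
probe and scale are explicit arguments, and since the "true" atomic radii
set of any given reference tool is a calibration choice, absolute values
are comparable only within one radii convention — trends and ratios are
the robust output.  Shadow areas are computed deterministically per
orientation by hit-testing a uniform grid (pitch 0.1× the smallest disk
radius; atoms grouped by quantized radius and rasterized by binary
dilation), giving a single-sphere area correct to ~1 %.  The reported
stderr is the orientation-sampling standard error and shrinks as
1/√n_orientations.  `ccs_series` adds the conventional
trailing-half-of-trajectory mean.

Full-scale cage-protein CCS values (hundreds of nm², microsecond
trajectories of ~0.5 MDa complexes) are outside desk scale; the tests
exercise the same machinery on scaled-down shells and check the
structural signal (hollow > compact at equal mass).

## Dynamics

`run_md` integrates velocity Verlet with per-label 12-6 Lennard-Jones
(all pairs, open boundaries — at toy scale this is affordable and avoids
periodicity entirely) plus Coulomb forces from either the direct oracle
or the FMM solver; with FMM the system is re-centered in a fresh cubic
box (default 3 nm clearance) before every force evaluation.  The default
time step is 1 fs: without bond constraints or virtual hydrogen sites
there is no basis for longer steps.  Temperature control is stochastic
velocity rescaling (canonical-sampling form, default τ = 0.2 ps), which
leaves velocities untouched as τ→∞ and resamples the kinetic energy
canonically as τ→0.  Center-of-mass translation (linear) or translation
plus rigid rotation (angular, via the inertia tensor; collinear mass
distributions are rejected) is removed every `comm_stride` steps, the
standard hygiene for a molecule spinning freely in vacuum; the removed
degrees of freedom are excluded from the temperature definition.
Velocities initialize from the Maxwell–Boltzmann distribution, seeded;
runs are bitwise deterministic and abort with the step index if forces,
energies or positions turn non-finite.

## Numerical choices and degenerate inputs

* Particle exactly on the upper box face → clamped into the last cell.
* d = 0 bypasses the tree entirely (same code path as the oracle);
  d = 1 has empty interaction lists at every level.
* `m2l` enforces well-separateness when given the cell edge; `l2p`
  checks the particle lies in its cell; multipole evaluation inside the
  bounding sphere emits a divergence warning but still returns the
  truncated value.
* Per-component error ratios use a denominator floor of 10⁻⁶ × RMS
  component magnitude; excluded components are counted in the report.
* The v-rescale update guards the non-negativity of the sampled kinetic
  energy; zero kinetic energy passes through unchanged.

## Known limitations

* The classical operator chain does not conserve momentum exactly: the
  two directions of an M2L pair truncate differently, so the net-force
  error accumulates with system size instead of cancelling.  Measured
  drift obeys |ΣF|/mean|F| < √(3N) × Δ_component with ≥4× margin; a
  momentum-symmetrized M2L is not implemented.
* Boxes must be exactly cubic; non-cubic behavior is not characterized.
* The tree is uniform (no adaptivity); very nonuniform occupancy wastes
  depth.
* The far-field separation criterion is the classical one-buffer list;
  implementations using other separation criteria will show different
  absolute Δ values at the same (d, p), though the same qualitative
  structure.
* The single-precision error plateau at p ≈ 8–12 is intentionally not
  reproduced (see above).
* Rotation-accelerated O(p³) translations and error-driven automatic
  p selection are not implemented.
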