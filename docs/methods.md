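# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `mtmd`. Notation: `s` are fractional (scaled) atomic
coordinates with Cartesian positions `R = h s`, `h` is the 3×3 cell matrix
(columns = lattice vectors), `p_s` and `p_h` the conjugate momenta, `M(q)`
the position-dependent mass matrix, and `G = (I⊗h)ᵀ M (I⊗h)` the
mass-weighted metric tensor. Internal units are u / Å / eV; the derived
time unit is √(u·Å²/eV) ≈ 10.1805 fs. Femtoseconds, Kelvin and GPa appear
only at interfaces.

## The model

Mass-tensor molecular dynamics (MTMD) replaces the constant atomic masses
by a configuration-dependent, symmetric positive-definite matrix `M(q)`.
The Hamiltonian in the variable-cell (Parrinello–Rahman) setting is

    H(s, h, p_s, p_h) = ½ p_sᵀ G(s,h)⁻¹ p_s + (1/2W) Tr(p_hᵀ p_h)
                        + U(s, h) + P det h

with cell mass `W` (u) and external pressure `P`. The dynamics samples the
NpH (isobaric–isoenthalpic) ensemble; `H` — an enthalpy — is the conserved
quantity. Provided `det M(q)` is held constant, integrating the momenta
out of the canonical distribution shows that the configurational
distribution remains ∝ exp(−βU): the mass matrix changes the dynamics (and
any time scale), not the sampled configurational ensemble.

The freedom in `M(q)` is used to assign larger masses to the fastest
intramolecular vibrations, which lowers their frequencies and enlarges the
usable time step. `M` is block diagonal, one block per molecule, so the
construction is local and costs scale linearly in the number of molecules.

### Mass models

* **Constant** — physical per-atom masses, or mass repartitioning
  `M_p = (1/N)(Σᵢ mᵢ) I₃N` (total mass conserved; the fast modes of light
  atoms slow down, everything else speeds up).
* **Diatomic mode decomposition** — each 6×6 molecular block is split
  along the bond direction `d̂` into three translational, two rotational
  and one vibrational mode, with independent masses
  `m_trans, m_rot, m_vib`. The determinant `m_trans³ m_rot² m_vib` is
  independent of `d̂`, so the determinant constraint is satisfied
  identically and the rescale factor is exactly 1.
* **Internal-coordinate Hessian model** — per molecule,

      A(q) = w · Bᵀ(q) H_{q,0} B(q) + M_p,     M(q) = c(q) · A(q)

  where `B` is the Wilson B matrix of the redundant internal coordinates
  (bonds, angles, dihedrals) at the *current* geometry, `H_{q,0}` is the
  reference Hessian in internal coordinates computed **once** at a local
  minimum by the thresholded-pseudoinverse forward transform
  `H_{q,0} = B₀ᵀ⁺ H_{x,0} B₀⁺`, and `w` (u·Å²/eV) weights the Hessian
  term. Because the reference is a minimum, the gradient-weighted
  second-derivative (K-matrix) term of the exact transform vanishes
  there; it is also omitted in the backward direction, which keeps the
  back-transformed Hessian positive semidefinite at every geometry.
  `M_p` (physical or repartitioned) supplies inertia to the zero-curvature
  modes (molecular translations/rotations). Singular values of `B` below
  10⁻² of the largest are treated as zero in the pseudoinverse. `H_{q,0}`
  is symmetrized and numerically negative eigenvalues are clipped at 0;
  an optional variant zeroes its off-diagonal couplings. Angles within
  10⁻³ rad of π at the reference geometry are pruned from the coordinate
  set (their B rows are singular).

### The determinant constraint

`c(q) = (D₀ / det A(q))^{1/3N}` with `D₀ = det A(q₀)`, so `det M = D₀`
exactly and `c(q₀) = 1`: the Hessian term is added on top of the physical
masses without rescaling them at the reference, and `c` fluctuates
around 1 along trajectories (about a percent on the bundled fixtures).
Determinants are accumulated as log-determinants per molecule block; the
constraint exponent uses the full matrix dimension 3N. Derivatives use
`∂ ln c/∂x = −(1/3N) tr(A⁻¹ ∂A/∂x)`.

### Derivatives of the metric tensor

All force terms need `∂G⁻¹/∂s` and `∂G⁻¹/∂h`, obtained from
`∂G⁻¹ = −G⁻¹(∂G)G⁻¹`. `∂G/∂h` has an explicit congruence part plus the
chain through `X = h s` in `M`; `∂G/∂s` goes through the Wilson-B first
*and second* derivatives (`∂B/∂x`, assembled from analytic per-coordinate
Hessians of bond lengths, angles and dihedrals — angles via arccos of a
clamped cosine, dihedrals via an atan2 form whose numerator/denominator
are polynomial in the three bond vectors). Everything is evaluated
blockwise per molecule; `G` itself is never formed. A dense reference
implementation (`mtmd.massmatrix.dGinv_derivatives`) exists for
verification, and the test suite checks both paths against central finite
differences at relative tolerance 10⁻⁵ and against each other.

## The symplectic integrator

The generalized Störmer–Verlet (leapfrog) scheme evaluates the momentum
half-kick with derivatives at the old positions and the second half-kick
at the advanced positions:

1. **Momentum half-kick** (implicit in `p_s`, since the kinetic force
   `−½ p_sᵀ (∂G⁻¹/∂s) p_s` involves the unknown half-step momenta):
   solved by fixed-point iteration from `p_s⁽ⁿ⁾`, typically a handful of
   iterations, capped at 30. If the iteration diverges (which happens
   near hard collisions at very large time steps, where the map stops
   being contractive), the same equation is handed to a Newton solver —
   the propagator is defined by the *solution* of the implicit equation,
   not by the solver, so symplecticity is unaffected. The cell half-kick
   is then explicit.
2. **Drift**: `h` explicitly from `p_h`; `s` implicitly, because
   `G⁻¹` must be re-evaluated at the new positions — one fixed-point
   step followed by Newton–Raphson (about four G-rebuilds per step in
   practice). The Newton matrix is block diagonal over molecules plus a
   rank-one determinant-constraint term, folded in with the
   Sherman–Morrison identity.
3. **Second half-kick**: explicit at the advanced positions.

Both solvers converge to 10⁻¹² (relative max-norm). One force evaluation
per step is needed: the derivatives at the advanced positions are reused
for the next step's first half-kick. With a constant mass matrix both
implicit equations degenerate and the scheme reduces to standard
velocity Verlet exactly (the suite asserts agreement to round-off).

Properties verified by the test suite: time reversibility under momentum
negation; preservation of the canonical two-form (`JᵀΩJ = Ω` to 10⁻⁶ for
a finite-difference Jacobian of one step in the full 42-dimensional
variable-cell phase space of a two-molecule system); bounded conserved
quantity with error band scaling as Δt²; exact uniform-scaling constraint.

**Uniform-scaling constraint.** Cell-momentum increments are orthogonally
projected (Frobenius inner product) onto span{h}, and initial `p_h` is
chosen in that subspace; the cell then only breathes isotropically. This
prevents the large shear excursions Parrinello–Rahman cells exhibit in
small systems.

**Explicit variant.** For comparison, a second-order explicit,
non-symplectic integrator is provided: velocity Verlet on the Lagrangian
equations of motion (variables `s, ṡ, h, ḣ`), with the velocity-dependent
part of the acceleration (the `Ġṡ` and `½ṡᵀ(∂G/∂s)ṡ` terms) closed by a fixed corrector pass. Over a few thousand steps its energy error is
similar to the symplectic scheme; over long horizons it develops a slow
secular drift that the symplectic integrator does not.

## Force fields

* **N₂**: harmonic bond (r₀ = 1.0977 Å, K_r = 138.331 eV/Å²) plus a 12-6
  Lennard-Jones term (ϵ = 0.003456 eV, r_m = 3.614 Å) over all
  intermolecular atom pairs. The Lennard-Jones term is truncated at a
  cutoff (default 10 Å, reduced to 45 % of the box for small cells) and
  shifted to zero there; ϵ is four orders of magnitude below the bond
  stiffness, so the spectra of interest are insensitive to the cutoff.
  Minimum-image convention in fractional coordinates (valid for the
  near-cubic cells used here; the uniform-scaling constraint keeps cells
  cubic in all bundled studies). Bonded terms use direct (unwrapped)
  differences — scaled coordinates are never wrapped during dynamics, so
  molecules stay whole.
* **Toy polyatomic**: harmonic bonds and angles, optional cosine torsion
  `k_d(1 − cos(φ − φ₀))`, intermolecular Lennard-Jones. Used by the toy
  crystal fixture.
* **Double-well bond**: `A((r−r₀)² − d²)²`, used to validate ensemble
  preservation under mass modification.

Analytic gradients with respect to both `s` and `h` are tested against
central finite differences at relative tolerance 10⁻⁶ (10⁻⁵ for cell
gradients). Cartesian Hessians are computed by symmetric central
differences of the energy (default step 10⁻³ Å, balancing truncation and
round-off at eV/Å² curvatures).

## Synthetic fixtures

* **Liquid N₂** — N molecules (default 512; the studies use 64) in a
  periodic cubic box scaled to the reference density of 512 molecules per
  (32 Å)³; jittered-lattice centers, random orientations, bonds at r₀.
  Initial Boltzmann momenta at 180 K virialize to ≈ 90 K, a slightly
  superheated liquid. External pressure 10⁻⁴ GPa, uniform-scaling NpH.
* **N₂ gas** — same construction at 512 molecules per (480 Å)³ and
  1750 K initial (≈ 1500 K after equipartition with the bond potential).
* **Toy molecular crystal** — two H–O–O–H-like chain molecules (masses
  1/16/16/1 u) stacked along z with alternating orientation in a fixed
  cell, relaxed to |∇U| < 10⁻⁶ eV/Å (so the K-matrix neglect is exact at
  the reference), bundled with its finite-difference Hessian. Stiffness
  scales (bonds ≈ 45–50 eV/Å², angles 14 eV/rad², torsion 6 eV) are
  chosen to produce a well-separated frequency ladder — bond stretch >
  angle bend > torsion > intermolecular — so that each enlargement of the
  internal-coordinate set of the mass model visibly lowers the top
  mass-weighted frequency (physical ≥ repartitioned ≥ bonds ≥
  bonds+angles ≥ full set). The torsion term exists precisely so that the
  dihedral coordinates have something to slow down.

What the fixtures do **not** emulate: electrostatics, hydrogen-bond
networks, bond breaking, or first-principles surfaces. Passing tests
therefore demonstrate the correctness of the mechanics (integrator, mass
matrices, transforms, measurement machinery) at force-field level, not
quantitative transferability to ab initio systems.

## Measurements

* **Mode-filtered spectra** — per-molecule scalar signals: center-of-mass
  coordinates (translation), the z-component of the unit bond axis
  (rotation; the *cosine* of the axis/z angle is used instead of the
  angle because the angle has reflection kinks at 0/π that leak
  broadband noise into derivative spectra), and bond length (vibration).
  The estimator is the Hann-windowed periodogram of the second time
  derivative (central differences on the sampling stride), averaged over
  molecules, smoothed with a 5-bin moving mean; the peak is the argmax
  away from the DC edge. Peak positions are the robust observable; band
  shapes are estimator-dependent.
* **Mass-weighted frequencies** — eigenvalues of `M^{-1/2} H M^{-1/2}`
  (cross-checked against a generalized eigensolve of `(H, M)`); negative
  curvatures are reported as imaginary-mode counts. The time-step rule is
  one tenth of the fastest oscillation period.
* **Maximum stable time step** — a run at Δt counts as stable when it
  completes the horizon with converging solvers, no overflow, and no
  secular growth: the median of the conserved quantity over the second
  half of the run must not shift from the first-half median by more than
  1 meV/atom. A near-edge symplectic run carries a large but stationary
  (Δt²-scaled, slowly beating) oscillation, which this criterion
  correctly accepts; drifts, energy jumps and blow-ups are rejected.
* **RDF** — ideal-gas-normalized minimum-image pair histogram.
* **Diffusion** — FFT-based MSD over all time origins; least-squares fit
  of ⟨|R(t)−R(0)|²⟩ = 6Dt + intercept over a configurable lag window,
  with a log-log slope diagnostic flagging ballistic (∝t²) regimes.
* **Transition detection** — order parameter: angle between two
  molecules' main axes (centroid-to-centroid of two atom groups), rolling
  trailing mean over 100 steps, events = upward crossings of 80°;
  crossings with an intramolecular kink above 30° or a failing
  user-supplied cell-shape predicate are excluded, not counted.

## Study conditions and measured numbers

The bundled studies run 64 molecules (the reference density is kept by
scaling the box; spectra and stability are local properties and already
converged at this size). Standard MD integrates at 1 fs, the accelerated
runs at 4 fs; production is 8 ps after 2 ps of equilibration. The cell
mass is set to the total system mass (~1793 u): a much lighter cell would
push the breathing mode itself across the integrator's stability bound at
the largest time steps scanned, turning the scan into a test of the
barostat parameter rather than of the molecular dynamics. With the
diatomic mass model at `m_vib = 100 m, m_rot = 4 m`:

* the vibrational spectrum peak moves from ≈ 70 ps⁻¹ (the harmonic
  stretch `√(K_r/μ)/2π ≈ 69.5 ps⁻¹`, slightly blue-shifted by the liquid
  environment) down by a factor of 10 to ≈ 7 ps⁻¹;
* the rotational band moves to roughly half its frequency. Measured
  peak ratios are ≈ 0.42–0.46 rather than exactly 0.5: the slowed rotor
  becomes more strongly hindered while the cage dynamics is unchanged,
  so the band does not purely rescale by √4;
* the maximum stable time step (stationarity criterion above, 5000-step
  horizon) is 4 fs for standard MD, 25 fs for MTMD in the liquid, and
  10 fs for MTMD in the hot gas — the gas limit is set by anharmonic
  Lennard-Jones collisions, which no bond-targeted mass matrix slows.

The symplectic-vs-explicit comparison integrates the toy crystal
microcanonically for 2·10⁴ steps at half the one-tenth-period step (at
the full rule step the single-pass explicit scheme heats this 8-atom
system out of its basin before the horizon completes): the symplectic
conserved quantity stays in a bounded band while the explicit variant
drifts secularly beyond it, with similar short-horizon error bands.

## Known limitations

* Bond topology is fixed at setup; no bond breaking (mass blocks would
  become discontinuous).
* Minimum image by fractional rounding limits cells to near-orthorhombic
  shapes; fine under the uniform-scaling constraint used throughout.
* The internal-coordinate model's cost per molecule grows steeply with
  molecule size (second-derivative tensors are O(m·(3n)²) per molecule);
  intended for small/medium molecules, as is the block-diagonal ansatz.
* The explicit integrator realization is one reasonable member of its
  class; only the qualitative symplectic/non-symplectic drift contrast is
  asserted.
* NpH cell dynamics of very small systems (a couple of molecules) is
  poorly conditioned — the "barostat" degree of freedom is then driven by
  a handful of interactions; the energy-conservation comparison on the
  toy crystal is therefore run microcanonically.
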