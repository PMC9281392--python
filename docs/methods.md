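# Methods

This note records the model, the numerical choices, and the limits of what
the test suite demonstrates. Notation: D is the spatial dimension (2 or 3),
G the symmetry group with order |G|, B the box matrix (lattice vectors as
rows, x = sB for fractional s), reduced Lennard-Jones units throughout
(ε = σ = m = 1, time unit τ = √(mσ²/ε)).

## Constrained dynamics

Only the n asymmetric-unit particles are integrated. Ghost positions are a
pure function of the state: convert to fractional coordinates, apply every
group element, wrap into [0,1), add every image offset, convert back. They
are rebuilt before each force evaluation and after each position update;
nothing is ever integrated for them. From a symmetric start the constrained
trajectory coincides with the full-system unconstrained trajectory of the
same particles (the suite checks agreement to 1e−8 over 100 velocity-Verlet
steps; in practice it is at machine precision), which is the central
correctness property of the whole construction.

Pair distances are evaluated at the *wrapped* asymmetric-unit positions.
A particle that diffuses out of the root cell still sees a complete,
correctly centered explicit environment; by lattice translation invariance
the forces are those of the unwrapped particle. Without this, a particle
crossing a cell boundary would exactly coincide with one of its own images
and the force loop would report a spurious overlap.

### Energy bookkeeping

The reported potential is the per-unit-cell energy
U = ½ Σ_i m_i Σ_{j≠self} u(r_ij), with m_i the orbit multiplicity (|G| for
general positions, the site multiplicity for Wyckoff-constrained
particles). Each cross-cell pair is half-owned by the root cell; this is
the quantity conserved by the dynamics and it equals a naive double loop
over all explicit particles, which the tests assert to 1e−10 for all 17
wallpaper groups. Reported kinetic energy is multiplicity-weighted the same
way, and the temperature uses dof = D·n − Σ(constraint-removed dof).

### Image window

With image radius a there are 3^a cells per dimension (3^(aD) total), so
cells may shrink to 1/a of the cutoff. Two exact geometric devices built on
the same primitive (the minimum Cartesian distance between the root cell
and cell k, computed by active-set enumeration of the bound-constrained
quadratic):

* cells that provably cannot reach the root cell within the cutoff are
  skipped in the force loop — a pure speedup, bit-identical energies;
* if any cell in the first shell *outside* the window could reach within
  the cutoff, the evaluation raises instead of silently truncating
  (and NPT proposals that would shrink the box below coverage are
  rejected). This matters: with an insufficient window the orbit members
  see differently truncated environments and the symmetric-dynamics
  equivalence itself breaks, not just the absolute energy.

## Group tables

Fixture files store, per group: name, dimension, Bravais class, the
general-position multiplicity, and generators as Jones-faithful triplets
("−y,x", "x+1/2,−y+1/2,z"), parsed with gemmi. Closure is computed at load
time, validated against the multiplicity, and (for the 3D groups) checked
element-by-element against gemmi's space-group tables in the tests.
Centering translations are kept as explicit elements, so |G| equals the
conventional-cell general multiplicity (cm → 4, cmm → 8).

Schema of a fixture file (`src/sgmd/data/groups/*.yaml`):

```yaml
name: p4g            # primary identifier (or "P4/mbm" for 3D)
hermann_mauguin: p4gm  # optional alias
number: 127          # 3D space-group number, optional
dimension: 2
bravais_class: square
multiplicity: 8      # general-position multiplicity, validates the closure
generators: ["-y,x", "-x+1/2,y+1/2"]
```

Wyckoff sites are *derived*, not transcribed: the fixed-point sets of all
non-identity elements are solved as affine subspaces modulo the lattice,
closed under pairwise intersection (a site whose stabilizer is generated by
several elements, e.g. point group 222, is an intersection, not a single
fixed set), grouped into orbits under G, and labeled mult+letter in order
of (multiplicity, dof, anchor). Labels therefore follow the standard
convention in spirit but are not guaranteed to reproduce the printed
Wyckoff letters; the suite pins the full inventories for p2, pg, p4, p6m
and the multiplicity spectrum of P4/mbm against the standard tables. Each
site carries an idempotent affine projector onto its locus and the list of
coset representatives used to expand a site particle into its (reduced)
orbit.

The asymmetric unit is the set of lexicographically minimal orbit
representatives — an exact fundamental domain of measure 1/|G| for any
group, with no per-group inequality tables to transcribe. Starting
configurations are drawn uniformly in the cell, mapped to their canonical
representative, and re-drawn until the fully expanded cell (Wyckoff orbits
included) has no pair closer than 0.9 σ; if a partial placement blocks
completion the whole set is re-drawn.

## Wyckoff constraints

For a site with projector P (linear part M_P) the residual is
σ(s) = U(I − M_P)(s − s₀), reduced by an orthonormal row basis U of
range(I − M_P) so the Jacobian has full row rank. σ is defined in
fractional coordinates and mapped through the current box, so the
constraint is exact under box moves; J = U(I − M_P)B⁻ᵀ is recomputed
whenever the box changes. A Wyckoff locus appears as parallel branches that
are identical modulo lattice translations; at assignment time the anchor
s₀ is snapped to the branch nearest the particle. Because σ is affine the
multiplier solve λ = (m/Δt²)(JJᵀ)⁻¹σ(q′) is exact in one linear solve — no
SHAKE iteration — and the suite verifies max |σ| stays below 1e−10 (in
practice 0) over a 1k-step NVT run. After each position correction the
velocity component normal to the site is removed; a point site therefore
pins its particle exactly.

## Integrators

Velocity Verlet for NVE; BAOAB for Langevin NVT with the exact
Ornstein-Uhlenbeck O-step (decay e^{−γΔt}, noise √(T(1−e^{−2γΔt})/m)); at
γ = 0 BAOAB is velocity Verlet to machine precision. Defaults follow the
reduced-unit conventions of the field: Δt = 0.005, γ = 0.1, cutoff 3.5 σ
(sharp truncation — no energy shift, no tail correction), image radius 2.
Velocities are initialized Maxwell-Boltzmann at the target temperature.
Net momentum is not removed (the symmetry constraint generally does not
conserve it anyway); divergence (non-finite coordinates or |v| > 10⁶) is
detected and reported with the step index.

**Energy-conservation fidelity.** The sharp cutoff makes the total energy
jump by u(3.5) ≈ −2.2e−3 ε whenever a pair crosses it, producing a bounded
fluctuation band roughly (pairs straddling the cutoff) × 2e−3 ε that does
not shrink with Δt; on top of it sits the usual O(Δt²) shadow-Hamiltonian
oscillation, which grows when random starts with near-contact pairs relax
and heat the system. At the standard conservation conditions (ρ = 0.2,
T₀ = 0.5, 5k steps) the band amounts to a relative deviation of order
10⁻³–10⁻², with no systematic trend (block-averaged drift is an order of
magnitude smaller); an independent plain-MD reimplementation reproduces
the same band, i.e. it is a property of the truncated potential at this
time step, not of the symmetry constraint machinery.

## NPT

Pressure enters only through the Metropolis rule — no virial. Working
boxes are kept canonical for the group's Bravais class: proposals are a
symmetric random walk in ln V (half-width `max_step`, default 0.01),
optionally combined with one free shape parameter of the class (relative
lengths log-scaled, angles/shears additive, half-width `shape_step`,
default 0.02), then projected. Free parameters are extracted by averaging
the quantities the class forces equal (cubic edge = mean vector length);
averaging keeps the projection continuous and idempotent and avoids the
large null spaces of pick-one conventions. The acceptance exponent is
−[ΔU + PΔV − (N+1)T ln(V′/V)]/T; the +1 is the Jacobian of the ln V walk,
and with it the ideal-gas (ε = 0) chain samples ⟨N/V⟩ = P/T exactly, which
the suite checks to three standard errors. N counts unit-cell particles.
Fractional coordinates are held fixed across a move (affine rescale), so
Wyckoff constraints stay satisfied; moves default to every 10 MD steps and
are non-adaptive to preserve detailed balance.

## Atlas protocol

Per (group, occupancy) job: NPT compression at P = 0.25, T = 0.1; NVT
anneal at T = 0.05; then the unit cell is expanded, all constraints are
dropped, and the full cell is integrated in NVE while recording the RMSD
from the stage-3 start (nearest-image displacements in the frozen stage-3
box, no superposition fitting). Classification: `diverged` on any stage
failure; `low_density` when the NPT stage ends at number density ≤ 0.5;
`unstable` when the RMSD rises above 0.5 σ; `stable` otherwise. ψ₆ (mean
modulus of the 6-fold bond-orientational phasor over the 6 nearest
neighbors, neighbors searched through explicit images) quantifies
hexagonal packing: 1 for the triangular lattice, ≈ 0 for a square lattice
on the 4-neighbor geometry, ~0.4 for random points.

Default step counts are 50k NPT / 10k NVT / 5k NVE per job (`--scale full`
raises them to 1M/100k/5k for production screens) —
and the job matrix enumerates unit-cell particle counts {k|G|, k = 1…4}
plus optional single-site Wyckoff occupancies. The reduced scale reproduces
the structural behavior (the unconstrained p1 job freezes into the
triangular ground state with ψ₆ > 0.9 and a flat release trace within
seconds) but makes no claim about exhaustiveness of the enumeration; with
one particle per p1 cell the release stage is trivially static
(the particle is a fixed point of its own image field), so its flat RMSD
validates the plumbing, not metastability in general.

## Known limitations

* Brute-force O(n·N_explicit) pair loop; fine for tens of asymmetric-unit
  particles, not for thousands.
* The 3D bundle covers P1, P-1 and P4/mbm only (the fixture format accepts
  any triplet-generated group).
* ψ₆ at the end of a finite-temperature run understates crystallinity for
  very small cells, where thermal box-shape fluctuations are relatively
  large (a 1-particle NPT cell at T = 0.1 spreads ψ₆ over roughly
  0.8–1.0 across seeds).
* The generator produces hot random starts (near-contact pairs at 0.9 σ);
  tests that depend on a literal starting temperature should be read with
  the relaxation-heating caveat above.
* Linear momentum is recorded, not corrected.
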