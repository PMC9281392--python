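# sgmd — molecular dynamics under a crystallographic symmetry group

`sgmd` is a small molecular dynamics engine in which the space or wallpaper
group of the simulated crystal is an *input*. Standard MD essentially never
visits point-group-symmetric configurations; `sgmd` makes symmetry exact by
construction, which turns MD into a generator of candidate crystal
structures: pick a group, compress and anneal under its constraint, then
release the constraint and watch whether the structure survives. It is aimed
at people studying crystal-structure prediction, 2D colloidal/LJ crystals,
and symmetric assemblies, at desk scale (tens of particles, pure Python/NumPy).

## The method

Let G be a planar or space group with |G| elements acting on fractional
coordinates as affine maps g·s = M_g s + t_g. A configuration q is symmetric
when g·q ~ q (row equivalence) for every g ∈ G. Assuming no particle sits on
a special position, the N unit-cell particles split into n = N/|G| orbits,
and symmetry is the holonomic constraint

    q_ij(t) = g_j · q_i0(t),   j = 1 … |G|−1,

so the asymmetric-unit particles q_i0 are the generalized coordinates. Only
they are integrated; orbit mates and all 3^(aD) periodic images (image
radius a, default 2) are *ghost particles*, rebuilt from the asymmetric unit
before every force evaluation. Because a pair potential is G-invariant, the
force field is G-equivariant and the asymmetric-unit equation of motion is
just m q̈ = F with F the plain physical force from every explicit neighbor.
The conserved unit-cell energy is

    U = ½ Σ_i m_i Σ_{j ≠ self} u(|x_j − x_i|),

with m_i the orbit multiplicity — equal to a brute-force sum over all
explicit pairs (verified to 1e−10 in the tests).

* **Bravais projection.** Constant-pressure moves are Metropolis
  Monte Carlo scaling moves in an unconstrained box matrix, projected onto
  the group's Bravais class (cubic, hexagonal, …) by an idempotent map
  before use; no virial is ever computed. Periodic boundaries as such are
  disabled — interactions go exclusively through explicit images, so cells
  may shrink below the interaction cutoff.
* **Wyckoff positions.** A particle on a special position (a line or point
  fixed by a subgroup) is held there by an analytic Lagrange-multiplier
  constraint σ[q] = (I − P)q − c = 0 with constant Jacobian; the solve is a
  single linear system per step, exact to machine precision, and stays
  exact under NPT box changes because σ is defined fractionally.
* **Integrators.** Velocity Verlet (NVE) and BAOAB Langevin (NVT), reduced
  LJ units, defaults dt = 0.005 τ, γ = 0.1, cutoff 3.5 σ.

All 17 wallpaper groups are bundled (generators in Jones-faithful triplet
notation, closed and validated at load time), plus space groups 1, 2 and
127 (P4/mbm); Wyckoff sites are derived automatically from the fixed-point
subspaces of the group elements and cross-checked against the standard
tables in the test suite.

## Worked example

```python
import sgmd
from sgmd.integrators import run_md, ThermoParams

g = sgmd.load_group("p6m", 2)
print(f"group {g.identifier}: |G| = {g.order}, Bravais class {g.bravais_class}")

state = sgmd.build_initial_state(g, n_general=2, density=0.4,
                                 temperature=0.5, seed=42)
print(f"asymmetric unit: {state.n} particles -> unit cell: "
      f"{state.cell_particle_count} particles")

for step, ke, pe, e, T in run_md(state, 2000, ThermoParams(dt=0.005),
                                 ensemble="nve", record_every=500):
    print(f"step {step:5d}  KE {ke:8.3f}  PE {pe:9.3f}  E {e:9.4f}  T {T:.3f}")
```

prints

```
group p6m: |G| = 12, Bravais class hexagonal
asymmetric unit: 2 particles -> unit cell: 24 particles
step     0  KE   19.008  PE   -30.429  E  -11.4209  T 0.792
step   500  KE   11.177  PE   -22.607  E  -11.4299  T 0.466
step  1000  KE   18.102  PE   -29.539  E  -11.4370  T 0.754
step  1500  KE   16.064  PE   -27.507  E  -11.4428  T 0.669
step  2000  KE   17.959  PE   -29.370  E  -11.4103  T 0.748
```

Two asymmetric-unit particles generate a 24-particle hexagonal unit cell;
the total unit-cell energy is conserved to a few parts in 10³ while kinetic
and potential energy exchange freely (the residual band comes from the
sharp 3.5 σ cutoff — see `docs/methods.md`).

A command-line interface mirrors the library:

```
sgmd groups list                 # bundled groups, orders, Wyckoff sites
sgmd groups validate             # re-derive closure for every group
sgmd run --config run.yaml       # one NVE/NVT/NPT run from a YAML config
sgmd atlas run --groups p1,p6 --scale reduced --out atlas/
```

`atlas run` executes the crystal-structure screen per group: NPT
compression (P = 0.25, T = 0.1) → NVT anneal (T = 0.05) → unconstrained NVE
of the expanded cell, classifying each job as stable / unstable / diverged /
low-density from its RMSD trace and final density.

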