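"""Experiment drivers: NVE conservation runs and the crystal-atlas screen.

The atlas protocol proposes a crystal structure for each symmetry group by
(1) compressing under the group constraint in NPT (P = 0.25, T = 0.1),
(2) annealing under constrained NVT at T = 0.05, then (3) expanding the
unit cell and integrating *all* particles unconstrained in NVE while
recording the RMSD from the stage-3 starting configuration. A flat RMSD
trace marks the structure as metastable; a rise means it collapsed. Jobs
whose NPT stage never exceeds number density 0.5, or that diverge at any
stage, are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from . import forcefield, integrators, lattice, npt as npt_mod
from .forcefield import LJParams, SystemState
from .groups import (
    SymmetryGroup,
    load_group,
    project_to_wyckoff,
    sample_asymmetric_unit,
)

__all__ = [
    "build_initial_state",
    "run_conservation",
    "AtlasJob",
    "AtlasResult",
    "AtlasStatus",
    "run_atlas_job",
    "enumerate_atlas_jobs",
    "rmsd",
    "hexatic_order",
]


def build_initial_state(
    group: SymmetryGroup | str,
    n_general: int,
    density: float,
    *,
    dimension: int | None = None,
    wyckoff_sites: list[str] = (),
    temperature: float = 0.0,
    lj: LJParams = LJParams(),
    image_radius: int = 2,
    seed=0,
    min_sep: float = 0.9,
) -> SystemState:
    """Random symmetric starting state at a target number density.

    ``wyckoff_sites`` lists site labels to occupy (one particle each, placed
    by projecting a random asymmetric-unit point onto the site); the
    remaining ``n_general`` particles are sampled from the asymmetric unit
    with a minimum expanded-cell pair separation of ``min_sep`` (in sigma).
    """
    if isinstance(group, str) or isinstance(group, int):
        group = load_group(group, dimension)
    D = group.dimension
    rng = np.random.default_rng(seed)
    sites = [group.site(lbl) for lbl in wyckoff_sites]
    n_cell = n_general * len(group) + sum(s.multiplicity for s in sites)
    box = lattice.box_from_density(group.bravais_class, D, n_cell, density)
    images = lattice.generate_images(image_radius, D)

    def _try_build():
        frac = []
        assignments = {}
        for k, site in enumerate(sites):
            assignments[k] = site.label
            frac.append(project_to_wyckoff(rng.random(D), site))
        if n_general:
            pts = sample_asymmetric_unit(
                group,
                n_general,
                rng.integers(2**31),
                box=box,
                min_sep=min_sep,
            )
            frac.extend(pts)
        frac = np.stack(frac)
        return SystemState(
            group=group,
            box=box,
            asym_pos=frac @ box,
            asym_vel=np.zeros_like(frac),
            mass=1.0,
            lj=lj,
            images=images,
            wyckoff_assignments=assignments,
        )

    def _min_pair_distance(st):
        ghosts = forcefield.ghost_positions(st)
        d = np.linalg.norm(
            st.asym_pos[:, None, :] - ghosts[None, :, :], axis=-1
        )
        d[d < 1e-9] = np.inf  # exact self copies
        return float(d.min())

    # the asymmetric-unit sampler enforces separation among general orbits;
    # Wyckoff occupants are placed independently, so re-draw until the whole
    # expanded cell (Wyckoff orbits included) respects the contact floor
    state = None
    for _ in range(200):
        state = _try_build()
        if not sites or _min_pair_distance(state) >= min_sep:
            break
    else:
        raise RuntimeError(
            "could not build a start satisfying the minimum separation; "
            "lower n, the density, or the Wyckoff occupancy"
        )
    if temperature > 0:
        integrators.maxwell_boltzmann_velocities(state, temperature, rng)
    return state


def run_conservation(
    group,
    n_asym: int = 5,
    density: float = 0.2,
    T0: float = 0.5,
    nsteps: int = 5000,
    *,
    dimension: int | None = None,
    dt: float = 0.005,
    seed: int = 0,
    image_radius: int = 2,
    record_every: int = 10,
):
    """NVE run from a random symmetric start; returns the (step, KE, PE, E, T)
    energy trace used for the conservation figure of merit."""
    state = build_initial_state(
        group,
        n_asym,
        density,
        dimension=dimension,
        temperature=T0,
        image_radius=image_radius,
        seed=seed,
    )
    params = integrators.ThermoParams(dt=dt, gamma=0.0, temperature=0.0)
    records = integrators.run_md(
        state, nsteps, params, ensemble="nve", record_every=record_every
    )
    return np.asarray(records)


def energy_drift(trace: np.ndarray) -> float:
    """Max relative deviation |E(t) - E(0)| / |E(0)| of a run_md trace."""
    e = trace[:, 3]
    return float(np.max(np.abs(e - e[0])) / abs(e[0]))


# ---------------------------------------------------------------------------
# atlas

class AtlasStatus(str, Enum):
    stable = "stable"
    unstable = "unstable"
    diverged = "diverged"
    low_density = "low_density"


@dataclass
class AtlasJob:
    group: str
    dimension: int = 2
    n_general: int = 1
    wyckoff_sites: list[str] = field(default_factory=list)
    npt_steps: int = 50_000
    nvt_steps: int = 10_000
    nve_steps: int = 5_000
    pressure: float = 0.25
    npt_temperature: float = 0.1
    nvt_temperature: float = 0.05
    start_density: float = 0.2
    seed: int = 0
    image_radius: int = 2

    @property
    def cell_count(self) -> int:
        g = load_group(self.group, self.dimension)
        return self.n_general * len(g) + sum(
            g.site(lbl).multiplicity for lbl in self.wyckoff_sites
        )


@dataclass
class AtlasResult:
    job: AtlasJob
    status: AtlasStatus
    rmsd_trace: np.ndarray | None = None
    final_density: float | None = None
    final_positions: np.ndarray | None = None  # expanded unit cell, Cartesian
    final_box: np.ndarray | None = None
    psi6: float | None = None


# stability threshold: an RMSD rise beyond half a particle diameter means
# the configuration changed
RMSD_RISE_THRESHOLD = 0.5
LOW_DENSITY_THRESHOLD = 0.5


def rmsd(config: np.ndarray, ref: np.ndarray, box: np.ndarray) -> float:
    """Root-mean-square displacement from ``ref``, per particle, taking each
    displacement through the nearest periodic image of the reference box.
    No rotational or translational fitting is applied."""
    config = np.atleast_2d(config)
    ref = np.atleast_2d(ref)
    if config.shape != ref.shape:
        raise ValueError("configurations must have equal particle counts")
    d = config - ref
    s = d @ np.linalg.inv(box)
    s -= np.round(s)
    d = s @ box
    return float(np.sqrt(np.mean(np.sum(d**2, axis=1))))


def hexatic_order(config: np.ndarray, box: np.ndarray, *, n_neighbors: int = 6,
                  image_radius: int = 1) -> float:
    """Bond-orientational order parameter psi6 of a 2D configuration.

    Per particle, the modulus of the average of exp(6 i theta) over its
    ``n_neighbors`` nearest neighbors (neighbors searched over explicit
    periodic images); averaged over particles. 1 for a perfect triangular
    lattice, ~0 for a square lattice or an ideal gas.
    """
    config = np.atleast_2d(config)
    if config.shape[1] != 2:
        raise ValueError("psi6 is defined for 2D configurations")
    offsets = lattice.generate_images(image_radius, 2).offsets
    env = (config[None, :, :] + (offsets @ box)[:, None, :]).reshape(-1, 2)
    vals = []
    for x in config:
        d = env - x
        r = np.linalg.norm(d, axis=1)
        order = np.argsort(r)
        nearest = order[r[order] > 1e-10][:n_neighbors]
        theta = np.arctan2(d[nearest, 1], d[nearest, 0])
        vals.append(abs(np.mean(np.exp(6j * theta))))
    return float(np.mean(vals))


def _expanded_cell_state(state: SystemState, image_radius: int) -> SystemState:
    """Unconstrained full-unit-cell copy of a constrained state (group p1/P1)."""
    cell_cart = forcefield.ghost_positions(state)
    # root-cell entries only: image offset == 0 for each (particle, element)
    n_img = state.images.count
    root = cell_cart.reshape(-1, n_img, state.dimension)[
        :, state.images.zero_index, :
    ]
    free_group = load_group("p1" if state.dimension == 2 else 1, state.dimension)
    # velocities: each orbit member inherits the transformed asym velocity;
    # starting stage 3 from rest is simpler and is what we do (T ~ 0 anneal)
    return SystemState(
        group=free_group,
        box=state.box.copy(),
        asym_pos=root,
        asym_vel=np.zeros_like(root),
        mass=1.0,
        lj=state.lj,
        images=lattice.generate_images(image_radius, state.dimension),
    )


def run_atlas_job(job: AtlasJob, *, record_every: int = 50) -> AtlasResult:
    """Three-stage metastability screen for one (group, occupancy) cell."""
    rng = np.random.default_rng(job.seed)
    try:
        state = build_initial_state(
            job.group,
            job.n_general,
            job.start_density,
            dimension=job.dimension,
            wyckoff_sites=job.wyckoff_sites,
            temperature=job.npt_temperature,
            image_radius=job.image_radius,
            seed=rng.integers(2**31),
        )
    except RuntimeError:
        return AtlasResult(job=job, status=AtlasStatus.diverged)

    thermo_npt = integrators.ThermoParams(
        dt=0.005, gamma=0.1, temperature=job.npt_temperature
    )
    npt_params = npt_mod.NPTParams(
        pressure=job.pressure, temperature=job.npt_temperature
    )
    try:
        npt_mod.run_npt(
            state, job.npt_steps, thermo_npt, npt_params,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
    except (integrators.DivergenceError, forcefield.OverlapError):
        return AtlasResult(job=job, status=AtlasStatus.diverged)

    density = state.cell_particle_count / lattice.volume(state.box)
    if density <= LOW_DENSITY_THRESHOLD:
        return AtlasResult(
            job=job, status=AtlasStatus.low_density, final_density=density
        )

    thermo_nvt = integrators.ThermoParams(
        dt=0.005, gamma=0.1, temperature=job.nvt_temperature
    )
    try:
        integrators.run_md(
            state, job.nvt_steps, thermo_nvt, ensemble="nvt",
            rng=np.random.default_rng(rng.integers(2**31)),
        )
    except (integrators.DivergenceError, forcefield.OverlapError):
        return AtlasResult(job=job, status=AtlasStatus.diverged)

    # stage 3: expand the unit cell, drop all constraints, integrate NVE
    free = _expanded_cell_state(state, job.image_radius)
    ref = free.asym_pos.copy()
    trace = []

    def _track(step, st):
        if step % record_every == 0 or step == job.nve_steps:
            trace.append(rmsd(st.asym_pos, ref, st.box))

    thermo_nve = integrators.ThermoParams(dt=0.005, gamma=0.0)
    try:
        integrators.run_md(
            free, job.nve_steps, thermo_nve, ensemble="nve", callback=_track
        )
    except (integrators.DivergenceError, forcefield.OverlapError):
        return AtlasResult(job=job, status=AtlasStatus.diverged)

    trace = np.asarray(trace)
    status = (
        AtlasStatus.stable
        if np.max(trace) < RMSD_RISE_THRESHOLD * free.lj.sigma
        else AtlasStatus.unstable
    )
    psi6 = (
        hexatic_order(free.asym_pos, free.box) if free.dimension == 2 else None
    )
    return AtlasResult(
        job=job,
        status=status,
        rmsd_trace=trace,
        final_density=density,
        final_positions=free.asym_pos,
        final_box=free.box,
        psi6=psi6,
    )


def enumerate_atlas_jobs(
    groups=None,
    *,
    count_multiples=(1, 2, 3, 4),
    include_wyckoff: bool = True,
    seed: int = 0,
    **job_kwargs,
) -> list[AtlasJob]:
    """The atlas job matrix: per planar group, one job per unit-cell particle
    count {k |G|} and, optionally, variants occupying each single Wyckoff
    site (with the remaining particles general)."""
    if groups is None:
        groups = [
            "p1", "p2", "pm", "pg", "cm", "pmm", "pmg", "pgg", "cmm",
            "p4", "p4m", "p4g", "p3", "p3m1", "p31m", "p6", "p6m",
        ]
    jobs = []
    for gname in groups:
        g = load_group(gname, 2)
        for k in count_multiples:
            jobs.append(
                AtlasJob(group=gname, n_general=k, seed=seed, **job_kwargs)
            )
        if include_wyckoff:
            for site in g.wyckoff_sites:
                # one particle on the site plus one general orbit
                jobs.append(
                    AtlasJob(
                        group=gname,
                        n_general=1,
                        wyckoff_sites=[site.label],
                        seed=seed,
                        **job_kwargs,
                    )
                )
    return jobs
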