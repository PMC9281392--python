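"""Velocity-Verlet (NVE) and BAOAB Langevin (NVT) integration of the
asymmetric unit.

Ghost positions are re-derived from the asymmetric-unit coordinates before
every force evaluation; Wyckoff position corrections are applied inside
every position (drift) update, and the corresponding velocity components
normal to each site are removed after every velocity update, so constrained
particles carry no kinetic energy in their frozen directions.

The BAOAB splitting is B (half kick) - A (half drift) - O (exact
Ornstein-Uhlenbeck: v -> c1 v + c2 xi with c1 = exp(-gamma dt),
c2 = sqrt(T (1 - c1^2) / m)) - A - B. With gamma = 0 the O step is the
identity and the scheme reduces to velocity Verlet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import forcefield, wyckoff_constraints as wc
from .forcefield import SystemState

__all__ = [
    "ThermoParams",
    "DivergenceError",
    "step_nve",
    "step_baoab",
    "temperature",
    "total_energy_report",
    "maxwell_boltzmann_velocities",
    "run_md",
]


@dataclass
class ThermoParams:
    """Integration and thermostat settings (reduced LJ units)."""

    dt: float = 0.005
    gamma: float = 0.1
    temperature: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        if self.dt <= 0 or self.gamma < 0 or self.temperature < 0:
            raise ValueError("require dt > 0, gamma >= 0, temperature >= 0")


class DivergenceError(RuntimeError):
    def __init__(self, step: int, reason: str):
        super().__init__(f"simulation diverged at step {step}: {reason}")
        self.step = step


def _constraints(state: SystemState) -> list[wc.WyckoffConstraint]:
    """Build (and cache on the state) the active Wyckoff constraints."""
    cached = getattr(state, "_constraints", None)
    if cached is not None:
        return cached
    cons = []
    s = state.frac_pos()
    for idx, label in sorted(state.wyckoff_assignments.items()):
        cons.append(wc.make_constraint(idx, state.group.site(label), s[idx]))
    state._constraints = cons
    return cons


def _apply_position_constraints(state: SystemState):
    for c in _constraints(state):
        i = c.particle_index
        state.asym_pos[i] = wc.project_position(state.asym_pos[i], c, state.box)


def _apply_velocity_constraints(state: SystemState):
    for c in _constraints(state):
        i = c.particle_index
        state.asym_vel[i] = wc.project_velocity(state.asym_vel[i], c, state.box)


def _check_finite(state: SystemState, forces: np.ndarray, step: int):
    if not np.all(np.isfinite(state.asym_pos)):
        raise DivergenceError(step, "non-finite position")
    if not np.all(np.isfinite(forces)):
        raise DivergenceError(step, "non-finite force")
    if np.max(np.abs(state.asym_vel)) > 1e6:
        raise DivergenceError(step, "runaway velocity")


def degrees_of_freedom(state: SystemState) -> int:
    return wc.degrees_of_freedom(state.n, state.dimension, _constraints(state))


def temperature(state: SystemState, dof: int | None = None) -> float:
    """Instantaneous reduced temperature 2*KE_asym/dof of the asymmetric unit."""
    if dof is None:
        dof = degrees_of_freedom(state)
    if dof <= 0:
        raise ValueError("degrees of freedom must be positive")
    ke = 0.5 * float(np.sum(state.mass[:, None] * state.asym_vel**2))
    return 2.0 * ke / dof


def total_energy_report(state: SystemState):
    """(kinetic, potential, total) per unit cell.

    Kinetic energy counts every orbit member (multiplicity-weighted), the
    potential is the unit-cell sum, so the total is the conserved quantity
    of the constrained NVE dynamics.
    """
    mult = state._plan.multiplicities
    ke = 0.5 * float(
        np.sum(mult * state.mass * np.sum(state.asym_vel**2, axis=1))
    )
    pe = forcefield.total_energy(state)
    return ke, pe, ke + pe


def maxwell_boltzmann_velocities(state: SystemState, T: float, rng) -> None:
    """Draw per-particle Maxwell-Boltzmann velocities at temperature T
    (in place); constrained particles get their normal components removed."""
    scale = np.sqrt(T / state.mass)[:, None]
    state.asym_vel = rng.standard_normal(state.asym_pos.shape) * scale
    _apply_velocity_constraints(state)


def _vv_step(state: SystemState, params: ThermoParams, f0, step: int):
    dt = params.dt
    m = state.mass[:, None]
    state.asym_vel += 0.5 * dt * f0 / m
    state.asym_pos += dt * state.asym_vel
    _apply_position_constraints(state)
    _, f1 = forcefield.energy_and_forces(state)
    state.asym_vel += 0.5 * dt * f1 / m
    _apply_velocity_constraints(state)
    _check_finite(state, f1, step)
    return f1


def step_nve(state: SystemState, params: ThermoParams) -> SystemState:
    """One velocity-Verlet step (in place; the state is also returned)."""
    _, f0 = forcefield.energy_and_forces(state)
    _vv_step(state, params, f0, step=0)
    return state


def _baoab_step(state, params, f0, rng, step: int):
    dt = params.dt
    m = state.mass[:, None]
    state.asym_vel += 0.5 * dt * f0 / m  # B
    state.asym_pos += 0.5 * dt * state.asym_vel  # A
    _apply_position_constraints(state)
    if params.gamma > 0:  # O (exact OU)
        c1 = np.exp(-params.gamma * dt)
        c2 = np.sqrt(params.temperature * (1.0 - c1 * c1) / state.mass)[:, None]
        state.asym_vel = c1 * state.asym_vel + c2 * rng.standard_normal(
            state.asym_vel.shape
        )
        _apply_velocity_constraints(state)
    state.asym_pos += 0.5 * dt * state.asym_vel  # A
    _apply_position_constraints(state)
    _, f1 = forcefield.energy_and_forces(state)
    state.asym_vel += 0.5 * dt * f1 / m  # B
    _apply_velocity_constraints(state)
    _check_finite(state, f1, step)
    return f1


def step_baoab(
    state: SystemState, params: ThermoParams, rng=None
) -> SystemState:
    """One BAOAB Langevin step (in place). The noise stream comes from
    ``rng`` if given, else from a generator seeded with ``params.seed``."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    _, f0 = forcefield.energy_and_forces(state)
    _baoab_step(state, params, f0, rng, step=0)
    return state


def run_md(
    state: SystemState,
    nsteps: int,
    params: ThermoParams,
    *,
    ensemble: str = "nve",
    rng=None,
    record_every: int = 0,
    callback=None,
):
    """Integrate nsteps with force reuse across steps.

    Returns a list of (step, KE, PE, E, T) tuples at the recording interval
    (always including step 0 and the final step when recording is on).
    """
    if ensemble not in ("nve", "nvt"):
        raise ValueError("ensemble must be 'nve' or 'nvt'")
    if ensemble == "nvt" and rng is None:
        rng = np.random.default_rng(params.seed)
    dof = degrees_of_freedom(state)
    records = []

    def _record(step):
        ke, pe, e = total_energy_report(state)
        records.append((step, ke, pe, e, temperature(state, dof)))

    _, f = forcefield.energy_and_forces(state)
    if record_every:
        _record(0)
    for step in range(1, nsteps + 1):
        if ensemble == "nve":
            f = _vv_step(state, params, f, step)
        else:
            f = _baoab_step(state, params, f, rng, step)
        if record_every and (step % record_every == 0 or step == nsteps):
            _record(step)
        if callback is not None:
            callback(step, state)
    return records
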