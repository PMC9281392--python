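"""Constant-pressure sampling via Metropolis box-scaling moves.

No virial is ever computed (pressure of an asymmetric unit is not a
meaningful virial pressure); pressure enters only through the Metropolis
acceptance rule. Box proposals are made in an unconstrained working matrix
and projected onto the group's Bravais class before use, so every working
box is Bravais-consistent. Periodic boundaries play no role: interactions
go exclusively through the explicit image ghosts, so cells may shrink
below the interaction cutoff.

Moves are a symmetric random walk in ln V, optionally combined with a
perturbation of one randomly chosen free lattice parameter of the Bravais
class (relative lengths in log-space, angles/shears additively); proposing
only within the projector's free directions avoids wasting moves in its
null space. The acceptance exponent uses (N+1) ln(V_new/V_old) — the +1 is
the Jacobian of the ln V random walk — which makes the sampled ideal-gas
density exactly P/T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import forcefield, integrators, lattice
from .forcefield import SystemState

__all__ = ["NPTParams", "propose_box", "accept_move", "run_npt"]


@dataclass
class NPTParams:
    pressure: float
    temperature: float
    move_interval: int = 10
    max_step: float = 0.01  # ln V step half-width
    shape_step: float = 0.02  # free-parameter step half-width
    seed: int | None = None

    def __post_init__(self):
        if self.pressure < 0 or self.move_interval < 1 or self.max_step <= 0:
            raise ValueError(
                "require pressure >= 0, move_interval >= 1, max_step > 0"
            )


def _shape_perturbation(B: np.ndarray, bravais_class: str, delta: float, rng):
    """Perturb one free lattice parameter beyond overall volume; identity for
    single-parameter classes (square, hexagonal 2D, cubic)."""
    D = B.shape[0]
    B = B.copy()
    if bravais_class in ("oblique", "triclinic"):
        i, j = rng.integers(0, D, size=2)
        B[i, j] += delta
    elif bravais_class in ("rectangular", "centered-rectangular", "orthorhombic"):
        B[rng.integers(0, D)] *= np.exp(delta)
    elif bravais_class in ("tetragonal",) or (
        bravais_class in ("trigonal", "hexagonal") and D == 3
    ):
        if rng.random() < 0.5:  # a (rows 0 and 1 together) or c
            B[:2] *= np.exp(delta)
        else:
            B[2] *= np.exp(delta)
    elif bravais_class == "monoclinic":
        which = rng.integers(0, 4)
        if which < 3:
            B[which] *= np.exp(delta)
        else:
            B[2, 0] += delta * np.linalg.norm(B[2])  # shear of v3 along x
    return B


def propose_box(B, rng, params: NPTParams, bravais_class: str) -> np.ndarray:
    """Symmetric proposal: ln V random walk plus an optional shape move,
    projected onto the Bravais class. Returns None for an invalid
    (non-right-handed) proposal, which the caller auto-rejects."""
    B = np.asarray(B, dtype=float)
    D = B.shape[0]
    proj = lattice.make_projector(bravais_class, D)
    dlnv = rng.uniform(-params.max_step, params.max_step)
    cand = B * np.exp(dlnv / D)
    if rng.random() < 0.5:
        cand = _shape_perturbation(
            cand, bravais_class, rng.uniform(-params.shape_step, params.shape_step), rng
        )
    if np.linalg.det(cand) <= 0:
        return None
    return proj(cand)


def accept_move(dU, V_old, V_new, N, params: NPTParams, rng) -> bool:
    """Metropolis decision for a box move proposed by a ln V random walk."""
    if V_old <= 0 or V_new <= 0:
        raise ValueError("volumes must be positive")
    T = params.temperature
    arg = -(
        dU
        + params.pressure * (V_new - V_old)
        - (N + 1) * T * np.log(V_new / V_old)
    ) / T
    return bool(arg >= 0 or rng.random() < np.exp(arg))


def run_npt(
    state: SystemState,
    nsteps: int,
    thermo: integrators.ThermoParams,
    npt_params: NPTParams,
    *,
    rng=None,
    record_every: int = 0,
):
    """Interleave BAOAB steps with box moves every ``move_interval`` steps.

    Mutates the state (positions rescale affinely with the box on accepted
    moves; fractional coordinates are held fixed). Returns a dict with the
    scalar records, the density trace at move attempts and the acceptance
    rate.
    """
    if rng is None:
        rng = np.random.default_rng(npt_params.seed)
    N = state.cell_particle_count
    cls = state.group.bravais_class
    records = []
    density_trace = []
    attempted = accepted = 0
    dof = integrators.degrees_of_freedom(state)
    U, f = forcefield.energy_and_forces(state)
    for step in range(1, nsteps + 1):
        f = integrators._baoab_step(state, thermo, f, rng, step)
        if step % npt_params.move_interval == 0:
            U = forcefield.total_energy(state)
            attempted += 1
            cand_box = propose_box(state.box, rng, npt_params, cls)
            if cand_box is not None and state.lj.epsilon != 0:
                # reject boxes the explicit image window could not cover
                if not lattice.images_cover_cutoff(
                    cand_box, state.images.radius, state.lj.cutoff
                ):
                    cand_box = None
            if cand_box is not None:
                V_old = lattice.volume(state.box)
                V_new = lattice.volume(cand_box)
                s = state.frac_pos()
                old_box, old_pos = state.box, state.asym_pos
                state.box = cand_box
                state.asym_pos = s @ cand_box
                try:
                    U_new = forcefield.total_energy(state)
                except forcefield.OverlapError:
                    U_new = np.inf
                if np.isfinite(U_new) and accept_move(
                    U_new - U, V_old, V_new, N, npt_params, rng
                ):
                    accepted += 1
                    U = U_new
                else:
                    state.box, state.asym_pos = old_box, old_pos
                _, f = forcefield.energy_and_forces(state)
            density_trace.append(N / lattice.volume(state.box))
        if record_every and (step % record_every == 0 or step == nsteps):
            ke, pe, e = integrators.total_energy_report(state)
            records.append(
                (
                    step,
                    ke,
                    pe,
                    e,
                    integrators.temperature(state, dof),
                    N / lattice.volume(state.box),
                    lattice.volume(state.box),
                )
            )
    return {
        "records": records,
        "density_trace": np.asarray(density_trace),
        "acceptance_rate": accepted / max(attempted, 1),
    }
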