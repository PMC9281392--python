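"""Lennard-Jones energy and forces over the asymmetric unit with explicit ghosts.

Only the n asymmetric-unit particles are dynamical. Their symmetry mates
(orbit members) and all periodic images are *ghost particles*: positions
derived from the asymmetric unit by applying the group elements in
fractional coordinates, wrapping, offsetting by the image lattice vectors,
and mapping back to Cartesian. Ghosts are recomputed from scratch before
every force evaluation and are never integrated.

Energy accounting: the per-unit-cell potential is

    U = 1/2 * sum_i m_i * sum_{j != self(i)} u(|x_j - x_i|)

where i runs over the asymmetric unit, m_i is the orbit multiplicity of
particle i (|G| for a general position, the Wyckoff multiplicity for a
constrained one), and j runs over every explicit ghost. By symmetry every
orbit member sees the same environment, so this equals the brute-force sum
over all unordered unit-cell pairs plus half of the cell-image interactions
(each cross-cell pair is half-owned by the root cell). The force on an
asymmetric-unit particle is the plain physical force exerted by all explicit
neighbors, which makes ``m q'' = F`` the asymmetric-unit equation of motion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import lattice
from .groups import SymmetryGroup, wrap_frac

__all__ = ["LJParams", "SystemState", "lj_pair", "ghost_positions",
           "total_energy", "forces_asym", "energy_and_forces"]


class OverlapError(ValueError):
    """Two explicit particles coincide; the LJ potential diverges."""


class InsufficientImagesError(ValueError):
    """The explicit image window cannot cover the interaction cutoff, so
    orbit members would see differently truncated environments and the
    symmetric-dynamics equivalence would break. Increase the image radius
    or the cell size."""


@dataclass(frozen=True)
class LJParams:
    """Reduced-unit 12-6 Lennard-Jones parameters with a sharp cutoff."""

    epsilon: float = 1.0
    sigma: float = 1.0
    cutoff: float = 3.5

    def __post_init__(self):
        if self.epsilon < 0 or self.sigma <= 0 or self.cutoff <= self.sigma:
            raise ValueError("require epsilon >= 0, sigma > 0, cutoff > sigma")


def lj_pair(r: float, params: LJParams = LJParams()):
    """Pair energy and scalar force magnitude (-du/dr) at separation r.

    Zero at and beyond the cutoff (sharp truncation, no shift or tail).
    """
    if r == 0:
        raise OverlapError("zero pair separation")
    if r >= params.cutoff:
        return 0.0, 0.0
    sr6 = (params.sigma / r) ** 6
    e = 4.0 * params.epsilon * (sr6 * sr6 - sr6)
    f = 24.0 * params.epsilon * (2.0 * sr6 * sr6 - sr6) / r
    return e, f


@dataclass
class _OrbitPlan:
    """Per-particle orbit bookkeeping: which group elements generate ghosts."""

    rep_indices: list[np.ndarray]  # element indices per particle, identity first
    multiplicities: np.ndarray  # (n,)
    starts: np.ndarray  # ghost-block start per particle (in units of images)


@dataclass
class SystemState:
    """Generalized coordinates of the constrained dynamics.

    Holds the asymmetric-unit positions/velocities in Cartesian reduced
    units, the group handle, the box matrix and the explicit image offsets.
    Ghost positions are always a pure function of this state.
    """

    group: SymmetryGroup
    box: np.ndarray
    asym_pos: np.ndarray  # (n, D) Cartesian
    asym_vel: np.ndarray  # (n, D) Cartesian
    mass: np.ndarray  # (n,)
    lj: LJParams = field(default_factory=LJParams)
    images: lattice.ImageOffsets = None
    wyckoff_assignments: dict[int, str] = field(default_factory=dict)
    _plan: _OrbitPlan = field(default=None, repr=False)

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        self.asym_pos = np.atleast_2d(np.asarray(self.asym_pos, dtype=float))
        self.asym_vel = np.atleast_2d(np.asarray(self.asym_vel, dtype=float))
        self.mass = np.broadcast_to(
            np.asarray(self.mass, dtype=float), (self.n,)
        ).copy()
        if self.images is None:
            self.images = lattice.generate_images(2, self.group.dimension)
        if self._plan is None:
            self._plan = self._build_plan()

    @property
    def n(self) -> int:
        return self.asym_pos.shape[0]

    @property
    def dimension(self) -> int:
        return self.group.dimension

    @property
    def cell_particle_count(self) -> int:
        """N = number of particles in one unit cell (sum of multiplicities)."""
        return int(np.sum(self._plan.multiplicities))

    def _build_plan(self) -> _OrbitPlan:
        reps, mults, starts = [], [], []
        pos = 0
        for i in range(self.n):
            if i in self.wyckoff_assignments:
                site = self.group.site(self.wyckoff_assignments[i])
                idx = np.asarray(site.coset_reps, dtype=int)
            else:
                idx = np.arange(len(self.group.elements))
            reps.append(idx)
            mults.append(len(idx))
            starts.append(pos)
            pos += len(idx)
        return _OrbitPlan(
            rep_indices=reps,
            multiplicities=np.asarray(mults, dtype=int),
            starts=np.asarray(starts, dtype=int),
        )

    def copy(self) -> "SystemState":
        return replace(
            self,
            box=self.box.copy(),
            asym_pos=self.asym_pos.copy(),
            asym_vel=self.asym_vel.copy(),
            mass=self.mass.copy(),
            wyckoff_assignments=dict(self.wyckoff_assignments),
        )

    def frac_pos(self) -> np.ndarray:
        return lattice.cart_to_frac(self.asym_pos, self.box)

    def self_ghost_indices(self) -> np.ndarray:
        """Index into the ghost array of each particle's own root-cell copy."""
        n_img = self.images.count
        return self._plan.starts * n_img + self.images.zero_index


def _tiled_ghosts(state: SystemState, offsets: np.ndarray) -> np.ndarray:
    D = state.dimension
    s = state.frac_pos()
    blocks = []
    for i in range(state.n):
        ops = [state.group.elements[j] for j in state._plan.rep_indices[i]]
        M = np.stack([op.linear for op in ops])  # (m, D, D)
        t = np.stack([op.translation for op in ops])
        frac = wrap_frac(np.einsum("mij,j->mi", M, s[i]) + t)  # (m, D)
        tiled = (frac[:, None, :] + offsets[None, :, :]).reshape(-1, D)
        blocks.append(tiled)
    return np.concatenate(blocks, axis=0) @ state.box


def ghost_positions(state: SystemState) -> np.ndarray:
    """All explicit particle positions (Cartesian), including the asymmetric
    unit's own root copies; ordering is particle-major, then group element
    (identity first), then image offset."""
    return _tiled_ghosts(state, state.images.offsets)


def _active_offsets(state: SystemState):
    """Image offsets whose cells can possibly reach the root cell within the
    cutoff (exact geometric bound); pruned cells contribute exactly zero."""
    key = (state.box.tobytes(), state.lj.cutoff, id(state.images))
    cached = getattr(state, "_offset_cache", None)
    if cached is not None and cached[0] == key:
        return cached[1], cached[2]
    if state.lj.epsilon != 0 and not lattice.images_cover_cutoff(
        state.box, state.images.radius, state.lj.cutoff
    ):
        raise InsufficientImagesError(
            f"image radius {state.images.radius} does not cover cutoff "
            f"{state.lj.cutoff} for this box; increase the radius"
        )
    dmin = lattice.min_cell_distances(state.box, state.images.offsets)
    keep = dmin <= state.lj.cutoff + 1e-9
    offsets = state.images.offsets[keep]
    zero_idx = int(np.flatnonzero(np.all(offsets == 0.0, axis=1))[0])
    state._offset_cache = (key, offsets, zero_idx)
    return offsets, zero_idx


def _pair_table(state: SystemState):
    """Distances and displacement vectors from each asym particle to every
    explicit ghost within reach, with each particle's own root copy masked.

    Distances are evaluated at the *wrapped* asymmetric-unit positions so a
    particle that has drifted out of the root cell still sees its complete
    (and correctly centered) explicit environment; by lattice translation
    invariance the forces are those of the unwrapped particle.
    """
    offsets, zero_idx = _active_offsets(state)
    ghosts = _tiled_ghosts(state, offsets)
    wrapped = wrap_frac(state.frac_pos()) @ state.box
    diff = wrapped[:, None, :] - ghosts[None, :, :]  # (n, N, D)
    r = np.linalg.norm(diff, axis=-1)
    self_idx = state._plan.starts * len(offsets) + zero_idx
    r[np.arange(state.n), self_idx] = np.inf
    if np.min(r) < 1e-10:
        raise OverlapError("explicit particle overlap (r < 1e-10)")
    return diff, r


def energy_and_forces(state: SystemState):
    """Unit-cell potential energy and physical forces on the asymmetric unit."""
    p = state.lj
    diff, r = _pair_table(state)
    within = r < p.cutoff
    rw = np.where(within, r, p.cutoff)
    sr6 = np.where(within, (p.sigma / rw) ** 6, 0.0)
    e = 4.0 * p.epsilon * (sr6 * sr6 - sr6)
    fmag = 24.0 * p.epsilon * (2.0 * sr6 * sr6 - sr6) / rw
    mult = state._plan.multiplicities
    energy = 0.5 * float(mult @ e.sum(axis=1))
    forces = ((fmag / rw)[:, :, None] * diff).sum(axis=1)
    return energy, forces


def total_energy(state: SystemState) -> float:
    return energy_and_forces(state)[0]


def forces_asym(state: SystemState) -> np.ndarray:
    return energy_and_forces(state)[1]
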