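"""Crystallographic symmetry groups for constrained molecular dynamics.

A planar (wallpaper) or space group is represented as the finite set of
affine operators that act on fractional coordinates, i.e. the quotient of
the full crystallographic group by its translation lattice (centering
translations are kept as explicit elements, so ``len(group)`` equals the
general-position multiplicity of the conventional cell).

Group tables are bundled as plain-text fixture files storing generators in
Jones-faithful triplet notation (``"-y,x"``, ``"x+1/2,-y+1/2,z"``); closure
is computed at load time and validated against the tabulated multiplicity.
Wyckoff positions (special positions fixed by a nontrivial subgroup) are
derived from the fixed-point subspaces of the group elements rather than
transcribed, and are validated against known multiplicities in the tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import gemmi
import numpy as np
import yaml
from scipy.linalg import null_space

from .lattice import wrap_frac

__all__ = [
    "AffineOp",
    "WyckoffSite",
    "SymmetryGroup",
    "GroupNotBundledError",
    "SpecialPositionError",
    "available_groups",
    "load_group",
    "orbit",
    "expand_unit_cell",
    "sample_asymmetric_unit",
    "project_to_wyckoff",
]

_DATA_DIR = Path(__file__).parent / "data" / "groups"
_TOL = 1e-9


class GroupNotBundledError(KeyError):
    """Requested group identifier is not in the bundled tables."""


class SpecialPositionError(ValueError):
    """A general-position operation was given a point on a special position."""


def _frac_dist_mod1(a, b):
    """Max-norm distance between fractional points modulo the lattice."""
    d = np.asarray(a) - np.asarray(b)
    d -= np.round(d)
    return np.max(np.abs(d))


@dataclass(frozen=True)
class AffineOp:
    """One group element g: s -> linear @ s + translation, on fractional coords.

    Group elements carry their translation wrapped into [0, 1); Wyckoff
    projectors must keep the exact translation (I - M) s0 (wrapping it by a
    lattice vector would destroy idempotence), hence ``wrap_translation``.
    """

    linear: np.ndarray
    translation: np.ndarray
    wrap_translation: bool = True

    def __post_init__(self):
        object.__setattr__(self, "linear", np.asarray(self.linear, dtype=float))
        t = np.asarray(self.translation, dtype=float)
        if self.wrap_translation:
            t = wrap_frac(t)
        object.__setattr__(self, "translation", t)

    @property
    def dimension(self) -> int:
        return self.linear.shape[0]

    def apply(self, s):
        """Apply to one fractional point or an (n, D) stack, without wrapping."""
        return np.asarray(s) @ self.linear.T + self.translation

    def __call__(self, s):
        return self.apply(s)

    def compose(self, other: "AffineOp") -> "AffineOp":
        """self ∘ other, with the translation wrapped back into [0, 1)."""
        return AffineOp(
            self.linear @ other.linear,
            self.linear @ other.translation + self.translation,
        )

    def is_identity(self, tol: float = _TOL) -> bool:
        d = self.dimension
        return (
            np.allclose(self.linear, np.eye(d), atol=tol)
            and _frac_dist_mod1(self.translation, np.zeros(d)) < tol
        )

    def _key(self):
        # entries of crystallographic ops are multiples of 1/24 at most
        return (
            tuple(np.round(self.linear.ravel() * 24).astype(int)),
            tuple(np.round(wrap_frac(self.translation) * 24).astype(int) % 24),
        )


@dataclass(frozen=True)
class WyckoffSite:
    """A special-position locus: points fixed by a nontrivial subgroup of G.

    ``projector`` is the idempotent affine map onto the locus (the subgroup's
    "identity" in the sense that it sends a general position onto the site).
    ``coset_reps`` are indices into the parent group's element list giving one
    element per distinct image of a site point (the orbit of a site point has
    ``multiplicity`` members, not |G|).
    """

    label: str
    projector: AffineOp
    anchor: np.ndarray  # one point on the locus, in [0,1)^D
    directions: np.ndarray  # (D, site_dof) orthonormal basis of the free subspace
    site_dof: int
    multiplicity: int
    stabilizer: tuple[int, ...]  # element indices fixing a generic site point
    coset_reps: tuple[int, ...]

    @property
    def removed_dof(self) -> int:
        return self.anchor.shape[0] - self.site_dof


@dataclass(frozen=True)
class SymmetryGroup:
    """A closed set of affine operators plus its Bravais class and Wyckoff sites."""

    identifier: str
    dimension: int
    elements: tuple[AffineOp, ...]
    bravais_class: str
    wyckoff_sites: tuple[WyckoffSite, ...] = field(default_factory=tuple)
    number: int | None = None

    @property
    def order(self) -> int:
        return len(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def site(self, label: str) -> WyckoffSite:
        for s in self.wyckoff_sites:
            if s.label == label:
                return s
        raise KeyError(
            f"group {self.identifier} has no Wyckoff site {label!r}; "
            f"available: {[s.label for s in self.wyckoff_sites]}"
        )

    def stabilizer_of(self, s, tol: float = 1e-8) -> list[int]:
        """Indices of elements fixing fractional point s (mod lattice)."""
        s = np.asarray(s, dtype=float)
        return [
            j
            for j, op in enumerate(self.elements)
            if _frac_dist_mod1(op(s), s) < tol
        ]

    def asym_unit(self, s, tol: float = 1e-9) -> bool:
        """True if s is the canonical (lexicographically minimal) orbit member.

        The set of canonical representatives is an exact fundamental domain of
        measure 1/|G|, used as the asymmetric unit for sampling starts.
        """
        s = wrap_frac(np.asarray(s, dtype=float))
        return _frac_dist_mod1(s, self.canonical_representative(s)) < tol

    def canonical_representative(self, s):
        pts = [wrap_frac(op(s)) for op in self.elements]
        order = sorted(range(len(pts)), key=lambda j: tuple(pts[j]))
        return pts[order[0]]


# ---------------------------------------------------------------------------
# triplet parsing and closure

def _parse_triplet(triplet: str, dimension: int) -> AffineOp:
    """Parse Jones-faithful notation via gemmi (2D ops are padded with z)."""
    padded = triplet if dimension == 3 else triplet + ",z"
    op = gemmi.Op(padded)
    linear = np.array(op.rot, dtype=float) / gemmi.Op.DEN
    trans = np.array(op.tran, dtype=float) / gemmi.Op.DEN
    return AffineOp(linear[:dimension, :dimension], trans[:dimension])


def _closure(generators: list[AffineOp], dimension: int, cap: int = 200):
    identity = AffineOp(np.eye(dimension), np.zeros(dimension))
    elements = {identity._key(): identity}
    frontier = [identity]
    while frontier:
        new = []
        for a in frontier:
            for g in generators:
                c = g.compose(a)
                k = c._key()
                if k not in elements:
                    elements[k] = c
                    new.append(c)
        frontier = new
        if len(elements) > cap:
            raise ValueError("group closure did not terminate; bad generators")
    ops = list(elements.values())
    # identity first, remainder in deterministic key order
    ops.sort(key=lambda op: (not op.is_identity(), op._key()))
    return tuple(ops)


# ---------------------------------------------------------------------------
# Wyckoff-site derivation from fixed-point subspaces

@dataclass
class _Subspace:
    anchor: np.ndarray
    basis: np.ndarray  # (D, k), orthonormal columns; k may be 0

    @property
    def dim(self):
        return self.basis.shape[1]

    def projector_matrix(self):
        return self.basis @ self.basis.T

    def canonical_anchor(self):
        # anchor minus its component along the basis, wrapped
        a = self.anchor - self.basis @ (self.basis.T @ self.anchor)
        return wrap_frac(np.round(a, 12))


def _subspace_equal(s1: _Subspace, s2: _Subspace, tol: float = 1e-8) -> bool:
    if s1.dim != s2.dim:
        return False
    if np.max(np.abs(s1.projector_matrix() - s2.projector_matrix())) > tol:
        return False
    d = s2.anchor - s1.anchor
    P = s1.projector_matrix()
    D = len(d)
    for k in itertools.product((-1, 0, 1), repeat=D):
        r = d + np.array(k, dtype=float)
        if np.max(np.abs(r - P @ r)) < tol:
            return True
    return False


def _fixed_subspaces_of_op(op: AffineOp) -> list[_Subspace]:
    """All solutions of op(s) = s (mod lattice) as affine subspaces in the cell."""
    D = op.dimension
    A = op.linear - np.eye(D)
    ns = null_space(A, rcond=1e-10)
    out: list[_Subspace] = []
    bound = int(np.ceil(np.max(np.sum(np.abs(A), axis=1)))) + 1
    for k in itertools.product(range(-bound, bound + 1), repeat=D):
        b = -op.translation + np.array(k, dtype=float)
        s0, *_ = np.linalg.lstsq(A, b, rcond=None)
        if np.max(np.abs(A @ s0 - b)) > 1e-8:
            continue
        sub = _Subspace(anchor=s0, basis=ns)
        sub.anchor = sub.canonical_anchor()
        if not any(_subspace_equal(sub, o) for o in out):
            out.append(sub)
    return out


def _intersect(s1: _Subspace, s2: _Subspace) -> list[_Subspace]:
    """Intersections (mod lattice) of two affine subspaces, possibly several."""
    D = len(s1.anchor)
    W = np.hstack([s1.basis, -s2.basis]) if (s1.dim + s2.dim) else np.zeros((D, 0))
    P1, P2 = s1.projector_matrix(), s2.projector_matrix()
    common = null_space(np.vstack([np.eye(D) - P1, np.eye(D) - P2]), rcond=1e-10)
    out = []
    for k in itertools.product((-1, 0, 1), repeat=D):
        d = s2.anchor + np.array(k, dtype=float) - s1.anchor
        if W.shape[1]:
            ab, *_ = np.linalg.lstsq(W, d, rcond=None)
            if np.max(np.abs(W @ ab - d)) > 1e-8:
                continue
            p = s1.anchor + s1.basis @ ab[: s1.dim]
        else:
            if np.max(np.abs(d)) > 1e-8:
                continue
            p = s1.anchor
        sub = _Subspace(anchor=p, basis=common)
        sub.anchor = sub.canonical_anchor()
        if not any(_subspace_equal(sub, o) for o in out):
            out.append(sub)
    return out


def _transform_subspace(op: AffineOp, sub: _Subspace) -> _Subspace:
    basis = op.linear @ sub.basis
    if basis.shape[1]:
        q, _ = np.linalg.qr(basis)
        basis = q
    new = _Subspace(anchor=wrap_frac(op(sub.anchor)), basis=basis)
    new.anchor = new.canonical_anchor()
    return new


def _site_point(sub: _Subspace, scale: float = 0.382574) -> np.ndarray:
    """A generic (irrational-offset) point on the locus, to probe stabilizers."""
    if sub.dim == 0:
        return wrap_frac(sub.anchor)
    coeff = scale * (1.0 + np.arange(sub.dim) * 0.173205)
    return wrap_frac(sub.anchor + sub.basis @ coeff)


def _derive_wyckoff_sites(elements: tuple[AffineOp, ...]) -> tuple[WyckoffSite, ...]:
    D = elements[0].dimension
    loci: list[_Subspace] = []

    def _add(sub: _Subspace):
        if not any(_subspace_equal(sub, o) for o in loci):
            loci.append(sub)

    for op in elements:
        if op.is_identity():
            continue
        for sub in _fixed_subspaces_of_op(op):
            _add(sub)
    # close under pairwise intersection so sites whose stabilizer has no
    # single element with that exact fixed locus (e.g. point group 222) appear
    changed = True
    while changed:
        changed = False
        snapshot = list(loci)
        for s1, s2 in itertools.combinations(snapshot, 2):
            if s1.dim == 0 and s2.dim == 0:
                continue
            for sub in _intersect(s1, s2):
                if not any(_subspace_equal(sub, o) for o in loci):
                    loci.append(sub)
                    changed = True

    # group loci into orbits under G
    orbits: list[list[_Subspace]] = []
    for sub in loci:
        placed = False
        for orb in orbits:
            if any(
                _subspace_equal(_transform_subspace(op, sub), member)
                for op in elements
                for member in orb[:1]
            ):
                orb.append(sub)
                placed = True
                break
        if not placed:
            orbits.append([sub])

    sites = []
    for orb in orbits:
        rep = min(orb, key=lambda s: tuple(np.round(s.anchor, 9)))
        p = _site_point(rep)
        stab = [
            j for j, op in enumerate(elements) if _frac_dist_mod1(op(p), p) < 1e-8
        ]
        if len(stab) <= 1:
            continue  # not special for generic points of this locus
        images: list[np.ndarray] = []
        reps: list[int] = []
        for j, op in enumerate(elements):
            q = wrap_frac(op(p))
            if not any(_frac_dist_mod1(q, r) < 1e-8 for r in images):
                images.append(q)
                reps.append(j)
        mult = len(images)
        M = rep.projector_matrix()
        proj = AffineOp(M, (np.eye(D) - M) @ rep.anchor, wrap_translation=False)
        sites.append(
            WyckoffSite(
                label="",
                projector=proj,
                anchor=wrap_frac(rep.anchor),
                directions=rep.basis,
                site_dof=rep.dim,
                multiplicity=mult,
                stabilizer=tuple(stab),
                coset_reps=tuple(reps),
            )
        )

    sites.sort(key=lambda s: (s.multiplicity, s.site_dof, tuple(np.round(s.anchor, 9))))
    letters = "abcdefghijklmnopqrstuvwxyz"
    return tuple(
        WyckoffSite(
            label=f"{s.multiplicity}{letters[i]}",
            projector=s.projector,
            anchor=s.anchor,
            directions=s.directions,
            site_dof=s.site_dof,
            multiplicity=s.multiplicity,
            stabilizer=s.stabilizer,
            coset_reps=s.coset_reps,
        )
        for i, s in enumerate(sites)
    )


# ---------------------------------------------------------------------------
# loading

def _catalog() -> dict[tuple[str, int], Path]:
    cat = {}
    for path in sorted(_DATA_DIR.glob("*.yaml")):
        with open(path) as fh:
            meta = yaml.safe_load(fh)
        dim = int(meta["dimension"])
        keys = {str(meta["name"]).lower()}
        if "hermann_mauguin" in meta:
            keys.add(str(meta["hermann_mauguin"]).lower())
        if "number" in meta:
            keys.add(str(meta["number"]))
        for k in keys:
            cat[(k, dim)] = path
    return cat


def available_groups() -> list[tuple[str, int]]:
    """(name, dimension) of all bundled groups (primary names only)."""
    out = []
    for path in sorted(_DATA_DIR.glob("*.yaml")):
        with open(path) as fh:
            meta = yaml.safe_load(fh)
        out.append((str(meta["name"]), int(meta["dimension"])))
    return out


@lru_cache(maxsize=None)
def _load_group_cached(key: str, dimension: int | None) -> SymmetryGroup:
    cat = _catalog()
    matches = sorted(
        {path for (k, dim), path in cat.items()
         if k == key and dimension in (None, dim)}
    )
    if not matches:
        raise GroupNotBundledError(
            f"group {key!r} (D={dimension}) is not bundled; "
            f"available groups: {available_groups()}"
        )
    if len(matches) > 1:
        raise ValueError(
            f"identifier {key!r} is ambiguous across dimensions; pass dimension"
        )
    with open(matches[0]) as fh:
        meta = yaml.safe_load(fh)
    dim = int(meta["dimension"])
    gens = [_parse_triplet(t, dim) for t in meta.get("generators", [])]
    elements = _closure(gens, dim)
    if len(elements) != int(meta["multiplicity"]):
        raise ValueError(
            f"closure of {meta['name']} has {len(elements)} elements, "
            f"expected multiplicity {meta['multiplicity']}"
        )
    for op in elements:
        if abs(abs(np.linalg.det(op.linear)) - 1.0) > 1e-10:
            raise ValueError(f"element of {meta['name']} has |det| != 1")
    return SymmetryGroup(
        identifier=str(meta["name"]),
        dimension=dim,
        elements=elements,
        bravais_class=str(meta["bravais_class"]),
        wyckoff_sites=_derive_wyckoff_sites(elements),
        number=meta.get("number"),
    )


def load_group(identifier, dimension: int | None = None) -> SymmetryGroup:
    """Load a bundled group by planar name (e.g. ``"p6m"``) or space-group number.

    Raises :class:`GroupNotBundledError` listing what is available when the
    identifier is unknown; raises ``ValueError`` on a dimension mismatch.
    """
    return _load_group_cached(str(identifier).lower(), dimension)


# ---------------------------------------------------------------------------
# orbit algebra

def orbit(q, group: SymmetryGroup) -> np.ndarray:
    """The group orbit of fractional point q: entry j is wrap(elements[j](q)).

    Always has length |G|; entries coincide when q sits on a special position.
    """
    q = wrap_frac(np.asarray(q, dtype=float))
    return np.stack([wrap_frac(op(q)) for op in group.elements])


def expand_unit_cell(asym_positions, group: SymmetryGroup) -> np.ndarray:
    """Expand n general asymmetric-unit positions into the n*|G| cell positions.

    Orbits are concatenated in asymmetric-unit order with the generating
    particle first in each orbit. Positions on a special (Wyckoff) position
    are rejected: their orbit is degenerate and must be declared explicitly
    via a Wyckoff-site assignment instead.
    """
    asym_positions = np.atleast_2d(np.asarray(asym_positions, dtype=float))
    out = []
    for i, q in enumerate(asym_positions):
        stab = group.stabilizer_of(q)
        if len(stab) > 1:
            raise SpecialPositionError(
                f"particle {i} at {wrap_frac(q)} is fixed by non-identity group "
                f"elements {stab[1:]}; declare a Wyckoff site for it instead"
            )
        out.append(orbit(q, group))
    return np.concatenate(out, axis=0) if out else np.zeros((0, group.dimension))


def project_to_wyckoff(q, site: WyckoffSite) -> np.ndarray:
    """Project a fractional point onto a Wyckoff locus (idempotent)."""
    return wrap_frac(site.projector(np.asarray(q, dtype=float)))


def sample_asymmetric_unit(
    group: SymmetryGroup,
    n: int,
    rng_seed,
    *,
    box: np.ndarray | None = None,
    min_sep: float = 0.9,
    image_radius: int = 1,
    max_attempts: int = 5000,
) -> np.ndarray:
    """Rejection-sample n fractional points inside the asymmetric unit.

    Points are drawn uniformly in the cell and mapped to their canonical
    orbit representative (an exact fundamental domain of measure 1/|G|).
    When ``box`` is given, a minimum Cartesian pair separation ``min_sep``
    (in units of the LJ sigma) is enforced over the fully expanded cell,
    including neighbor images, by resampling the offending point.
    """
    from . import lattice  # local import to avoid a cycle

    rng = np.random.default_rng(rng_seed)
    D = group.dimension
    if n < 1:
        raise ValueError("n must be >= 1")
    offsets = (
        lattice.generate_images(image_radius, D).offsets
        if box is not None
        else None
    )

    def _ok(points):
        if box is None:
            return True
        cell = expand_unit_cell(points, group)
        cart = np.concatenate(
            [(cell[None, :, :] + offsets[:, None, :]).reshape(-1, D) @ box]
        )
        root = cell @ box
        d = np.linalg.norm(root[:, None, :] - cart[None, :, :], axis=-1)
        d[d < 1e-12] = np.inf  # self pairs
        return np.min(d) >= min_sep

    points: list[np.ndarray] = []
    attempts = 0
    stuck = 0
    while len(points) < n:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} particles with separation {min_sep} after "
                f"{max_attempts} attempts; lower n or the density"
            )
        cand = group.canonical_representative(rng.random(D))
        if len(group.stabilizer_of(cand)) > 1:
            continue  # vanishing-probability special position; resample
        if _ok(points + [cand]):
            points.append(cand)
            stuck = 0
        else:
            stuck += 1
            if stuck >= 100:  # earlier placements may block the rest
                points.clear()
                stuck = 0
    return np.stack(points)
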