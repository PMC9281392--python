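"""Box-matrix algebra: fractional/Cartesian transforms, Bravais projection, images.

Conventions: lattice vectors are the *rows* of the box matrix B, and a
fractional row-vector s maps to Cartesian via ``x = s @ B``. All boxes are
right-handed (det B > 0). The Bravais projector maps an arbitrary (triclinic
in 3D, oblique in 2D) box matrix onto the canonical box of a Bravais class;
free parameters are extracted by averaging the quantities the class forces
to be equal (e.g. the cubic edge is the mean of the three vector lengths),
which makes the projection continuous and idempotent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BRAVAIS_CLASSES_2D",
    "BRAVAIS_CLASSES_3D",
    "ImageOffsets",
    "BravaisProjector",
    "make_projector",
    "apply_projector",
    "generate_images",
    "frac_to_cart",
    "cart_to_frac",
    "wrap_frac",
    "volume",
    "canonical_box",
    "box_from_density",
]

BRAVAIS_CLASSES_2D = (
    "oblique",
    "rectangular",
    "centered-rectangular",
    "square",
    "hexagonal",
)
BRAVAIS_CLASSES_3D = (
    "triclinic",
    "monoclinic",
    "orthorhombic",
    "tetragonal",
    "trigonal",
    "hexagonal",
    "cubic",
)


def wrap_frac(s):
    """Wrap fractional coordinates into [0, 1) (floor-based, so -0.25 -> 0.75).

    Tiny negative values would round to exactly 1.0 under ``s - floor(s)``;
    those are mapped back to 0.0 so the half-open contract holds.
    """
    s = np.asarray(s, dtype=float)
    w = s - np.floor(s)
    return np.where(w >= 1.0, w - 1.0, w)


def volume(box) -> float:
    return float(np.linalg.det(box))


def _check_box(box):
    box = np.asarray(box, dtype=float)
    det = np.linalg.det(box)
    if abs(det) < 1e-300:
        raise ValueError("singular box matrix")
    return box


def frac_to_cart(s, box):
    """x = s @ B for one fractional vector or an (n, D) stack."""
    return np.asarray(s, dtype=float) @ _check_box(box)


def cart_to_frac(x, box):
    return np.asarray(x, dtype=float) @ np.linalg.inv(_check_box(box))


@dataclass(frozen=True)
class ImageOffsets:
    """Integer lattice offsets of the explicitly simulated periodic images.

    Radius a gives 3^a cells per dimension (offsets -(3^a-1)/2 .. +(3^a-1)/2),
    3^(aD) cells in total, so cells may shrink to 1/a of the interaction
    cutoff while every neighbor within the cutoff remains explicit.
    """

    offsets: np.ndarray  # (3^(aD), D) integer array
    radius: int

    @property
    def count(self) -> int:
        return self.offsets.shape[0]

    @property
    def zero_index(self) -> int:
        return (self.count - 1) // 2


def generate_images(radius: int, dimension: int) -> ImageOffsets:
    if radius < 1:
        raise ValueError("image radius must be >= 1")
    half = (3**radius - 1) // 2
    rng = range(-half, half + 1)
    offsets = np.array(list(itertools.product(rng, repeat=dimension)), dtype=float)
    return ImageOffsets(offsets=offsets, radius=radius)


# ---------------------------------------------------------------------------
# Bravais projection

def _lengths(B):
    return np.linalg.norm(B, axis=1)


_HEX2 = np.array([[1.0, 0.0], [-0.5, np.sqrt(3.0) / 2.0]])


def _project(bravais_class: str, B: np.ndarray) -> np.ndarray:
    ln = _lengths(B)
    if bravais_class in ("oblique", "triclinic"):
        return B.copy()
    if bravais_class in ("rectangular", "centered-rectangular"):
        return np.diag(ln)
    if bravais_class == "square":
        return np.mean(ln) * np.eye(2)
    if bravais_class == "hexagonal" and B.shape[0] == 2:
        return np.mean(ln[:2]) * _HEX2
    if bravais_class == "orthorhombic":
        return np.diag(ln)
    if bravais_class == "tetragonal":
        return np.diag([np.mean(ln[:2]), np.mean(ln[:2]), ln[2]])
    if bravais_class in ("trigonal", "hexagonal"):
        a = np.mean(ln[:2])
        out = np.zeros((3, 3))
        out[:2, :2] = a * _HEX2
        out[2, 2] = ln[2]
        return out
    if bravais_class == "cubic":
        return np.mean(ln) * np.eye(3)
    if bravais_class == "monoclinic":
        # b-unique setting: alpha = gamma = 90, beta free
        cosb = np.dot(B[0], B[2]) / (ln[0] * ln[2])
        cosb = np.clip(cosb, -0.999999, 0.999999)
        sinb = np.sqrt(1.0 - cosb**2)
        out = np.diag([ln[0], ln[1], 0.0])
        out[2] = [ln[2] * cosb, 0.0, ln[2] * sinb]
        return out
    raise ValueError(f"unknown Bravais class {bravais_class!r}")


@dataclass(frozen=True)
class BravaisProjector:
    """Idempotent map from an arbitrary box matrix onto a Bravais class.

    For the classes where the map is linear in B (identity classes and the
    axis-aligned diagonal classes applied to already-diagonal input) the
    equivalent rank-4 tensor is available via :meth:`tensor`; the
    length-averaging parameter extraction used for the other classes is
    smooth but not linear, so the projector is exposed as a callable.
    """

    bravais_class: str
    dimension: int

    def __call__(self, B) -> np.ndarray:
        B = _check_box(B)
        if B.shape != (self.dimension, self.dimension):
            raise ValueError("box dimension mismatch")
        out = _project(self.bravais_class, B)
        if np.linalg.det(out) <= 0:
            raise ValueError("projected box is not right-handed")
        return out

    def tensor(self) -> np.ndarray:
        """Rank-4 tensor T with (T B)_ij = sum_kl T[i,j,k,l] B[k,l], exact for
        the identity classes; raises for length-averaged classes."""
        D = self.dimension
        if self.bravais_class in ("oblique", "triclinic"):
            T = np.zeros((D, D, D, D))
            for i in range(D):
                for j in range(D):
                    T[i, j, i, j] = 1.0
            return T
        raise NotImplementedError(
            f"projection onto {self.bravais_class!r} extracts parameters from "
            "vector lengths and is not a linear map"
        )


def make_projector(bravais_class: str, dimension: int) -> BravaisProjector:
    valid = BRAVAIS_CLASSES_2D if dimension == 2 else BRAVAIS_CLASSES_3D
    if bravais_class not in valid:
        raise ValueError(
            f"unknown Bravais class {bravais_class!r} for D={dimension}; "
            f"valid: {valid}"
        )
    return BravaisProjector(bravais_class=bravais_class, dimension=dimension)


def apply_projector(projector: BravaisProjector, B) -> np.ndarray:
    return projector(B)


def canonical_box(bravais_class: str, dimension: int) -> np.ndarray:
    """Unit-volume canonical box of a class (used to seed initial boxes)."""
    seed = np.eye(dimension)
    B = make_projector(bravais_class, dimension)(seed)
    return B / volume(B) ** (1.0 / dimension)


def min_cell_distances(box, offsets) -> np.ndarray:
    """Exact minimum Cartesian distance between the root cell and cell k,
    for each integer offset k: min |u B| over u in k + [-1, 1]^D.

    Solved exactly by enumerating active sets of the bound-constrained
    quadratic (each coordinate free or pinned at k_i -+ 1), vectorized over
    offsets. Used to skip image cells that provably cannot contain any
    particle within the interaction cutoff.
    """
    B = np.asarray(box, dtype=float)
    ks = np.atleast_2d(np.asarray(offsets, dtype=float))
    D = B.shape[0]
    best = np.full(len(ks), np.inf)
    for pattern in itertools.product((None, -1.0, 1.0), repeat=D):
        fixed = [i for i, p in enumerate(pattern) if p is not None]
        free = [i for i, p in enumerate(pattern) if p is None]
        shift = np.array([pattern[i] for i in fixed], dtype=float)
        uC = ks[:, fixed] + shift  # (m, |C|)
        c = uC @ B[fixed] if fixed else np.zeros((len(ks), D))
        if free:
            BF = B[free]  # (|F|, D)
            G = BF @ BF.T
            x = -np.linalg.solve(G, BF @ c.T).T  # (m, |F|)
            w = x - ks[:, free]
            feasible = np.all(np.abs(w) <= 1.0 + 1e-12, axis=1)
            cand = np.linalg.norm(x @ BF + c, axis=1)
        else:
            feasible = np.ones(len(ks), dtype=bool)
            cand = np.linalg.norm(c, axis=1)
        best = np.where(feasible & (cand < best), cand, best)
    return best


def images_cover_cutoff(box, radius: int, cutoff: float) -> bool:
    """True if the explicit 3^(a D) image window represents every particle
    within ``cutoff`` of the root cell.

    Exact criterion: every cell in the first shell *outside* the window is
    farther from the root cell than the cutoff (distances via
    :func:`min_cell_distances`).
    """
    B = np.asarray(box, dtype=float)
    D = B.shape[0]
    h = (3**radius - 1) // 2
    shell = [
        k
        for k in itertools.product(range(-h - 1, h + 2), repeat=D)
        if np.max(np.abs(k)) == h + 1
    ]
    return bool(np.all(min_cell_distances(B, np.array(shell)) >= cutoff))


def box_from_density(
    bravais_class: str, dimension: int, n_particles: int, density: float
) -> np.ndarray:
    """Canonical Bravais box whose volume gives the requested number density."""
    if density <= 0:
        raise ValueError("density must be positive")
    V = n_particles / density
    return canonical_box(bravais_class, dimension) * V ** (1.0 / dimension)
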