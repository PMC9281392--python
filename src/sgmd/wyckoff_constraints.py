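"""Holonomic constraints that hold particles on Wyckoff positions.

The constraint residual for a particle with fractional coordinates s on a
site with idempotent projector P (linear part M_P, translation t_P) is

    sigma_frac(s) = (I - M_P) s - c,

an affine map that vanishes exactly on the site. Sites are defined in
fractional coordinates, so sigma is evaluated through the current box
(s = x B^-1) and the constant Jacobian is recomputed whenever the box
changes; constraints therefore stay exact under NPT box moves. Because
sigma is affine, the Lagrange multiplier solve is a single linear system
(no SHAKE iteration) and the post-step residual is zero to machine
precision.

A Wyckoff locus appears as several parallel affine branches that are
identical modulo lattice translations; at assignment time the anchor is
snapped to the branch nearest the particle so sigma is smooth thereafter.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .groups import WyckoffSite
from .lattice import cart_to_frac

__all__ = [
    "WyckoffConstraint",
    "make_constraint",
    "sigma",
    "constraint_force",
    "solve_lambda",
    "removed_dof_total",
    "project_position",
    "project_velocity",
]


@dataclass
class WyckoffConstraint:
    particle_index: int
    site: WyckoffSite
    anchor: np.ndarray  # site anchor on the particle's branch (fractional)
    normal_rows: np.ndarray  # (k, D) orthonormal rows spanning range(I - M_P)

    @property
    def removed_dof(self) -> int:
        return self.normal_rows.shape[0]

    # -- fractional-space residual -------------------------------------
    def sigma_frac(self, s) -> np.ndarray:
        D = self.anchor.shape[0]
        res = (np.eye(D) - self.site.projector.linear) @ (
            np.asarray(s, dtype=float) - self.anchor
        )
        return self.normal_rows @ res

    # -- Cartesian maps through the current box ------------------------
    def jacobian(self, box: np.ndarray) -> np.ndarray:
        """Constant Jacobian d sigma / d x for the current box (k x D)."""
        D = self.anchor.shape[0]
        Binv = np.linalg.inv(box)
        return self.normal_rows @ (np.eye(D) - self.site.projector.linear) @ Binv.T

    def tangent_rows(self, box: np.ndarray) -> np.ndarray:
        """Orthonormal Cartesian basis of the site's free directions (t x D)."""
        if self.site.site_dof == 0:
            return np.zeros((0, box.shape[0]))
        cart = self.site.directions.T @ box  # fractional dirs -> Cartesian rows
        q, _ = np.linalg.qr(cart.T)
        return q.T


def make_constraint(
    particle_index: int, site: WyckoffSite, s_init, tol: float = 1e-6
) -> WyckoffConstraint:
    """Bind a particle to a site, snapping the anchor to the nearest branch.

    ``s_init`` (fractional) must already lie on the site modulo lattice
    translations (use :func:`sgmd.groups.project_to_wyckoff` to place it).
    """
    s_init = np.asarray(s_init, dtype=float)
    D = s_init.shape[0]
    Q = np.eye(D) - site.projector.linear
    best, best_res = None, np.inf
    for k in itertools.product((-1, 0, 1), repeat=D):
        anchor = site.anchor + np.array(k, dtype=float)
        res = np.linalg.norm(Q @ (s_init - anchor))
        if res < best_res:
            best, best_res = anchor, res
    if best_res > tol:
        raise ValueError(
            f"particle {particle_index} at {s_init} is not on Wyckoff site "
            f"{site.label} (residual {best_res:.2e})"
        )
    # orthonormal rows spanning the normal space of the (possibly oblique) Q
    u, sv, vt = np.linalg.svd(Q)
    rank = int(np.sum(sv > 1e-10))
    rows = u[:, :rank].T @ Q
    rows = np.linalg.qr(rows.T)[0].T if rank else np.zeros((0, D))
    return WyckoffConstraint(
        particle_index=particle_index, site=site, anchor=best, normal_rows=rows
    )


def sigma(x_cart, constraint: WyckoffConstraint, box: np.ndarray) -> np.ndarray:
    """Constraint residual of a Cartesian position; zero iff on the site."""
    return constraint.sigma_frac(cart_to_frac(x_cart, box))


def constraint_force(lam, constraint: WyckoffConstraint, box: np.ndarray):
    """Cartesian force -J^T lambda exerted by the constraint."""
    return -constraint.jacobian(box).T @ np.atleast_1d(lam)


def solve_lambda(
    x_unconstrained, constraint: WyckoffConstraint, box, dt: float, m: float
):
    """Multiplier making the corrected position satisfy sigma = 0 exactly.

    The correction x -> x + (dt^2/m) * (-J^T lambda) is applied by the
    integrator; for affine sigma the solve is exact in one step.
    """
    if dt <= 0 or m <= 0:
        raise ValueError("dt and m must be positive")
    J = constraint.jacobian(box)
    JJt = J @ J.T
    if JJt.shape[0] and np.linalg.cond(JJt) > 1e12:
        raise np.linalg.LinAlgError(
            f"singular constraint Jacobian for site {constraint.site.label}"
        )
    res = sigma(x_unconstrained, constraint, box)
    return (m / dt**2) * np.linalg.solve(JJt, res)


def project_position(x_cart, constraint: WyckoffConstraint, box) -> np.ndarray:
    """Exact position correction (equivalent to the Lagrange solve)."""
    J = constraint.jacobian(box)
    res = sigma(x_cart, constraint, box)
    return x_cart - J.T @ np.linalg.solve(J @ J.T, res)


def project_velocity(v_cart, constraint: WyckoffConstraint, box) -> np.ndarray:
    """Remove the velocity component normal to the site (in Cartesian space)."""
    T = constraint.tangent_rows(box)
    return T.T @ (T @ v_cart)


def removed_dof_total(constraints) -> int:
    return int(sum(c.removed_dof for c in constraints))


def degrees_of_freedom(n: int, dimension: int, constraints=()) -> int:
    """D*n minus the degrees removed by Wyckoff constraints."""
    return dimension * n - removed_dof_total(constraints)
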