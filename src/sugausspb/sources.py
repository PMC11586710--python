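"""Analytic Coulomb potential, boundary conditions, and regularized sources.

The regularization splits the potential into a singular Coulomb part
phi_C = G (the Green's function of the homogeneous eps_ref Poisson problem)
and a bounded reaction field phi_RF.  The reaction field then satisfies a
variable-coefficient equation whose right-hand side is the smooth field

    f = grad(eps) . grad(G) - [1 - S] kappa^2 G        (water phase)
    f = grad(eps_v) . grad(G)                          (vacuum phase)

which is finite everywhere, including at atom centers, because grad(eps)
vanishes there faster than grad(G) diverges (m >= 2) and [1-S] is zero
inside the solute.  Dirichlet values for phi_RF on the box faces are the
screened far-field potential minus G.

The Green's function denominator uses eps_ref -- the dielectric of the
homogeneous problem that defines phi_C -- so the decomposition stays
self-consistent when eps_ref != 1 (for the default eps_ref = 1 the choice
is invisible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import PhysicalConstants
from .dielectric import DielectricFields
from .grid import Grid, ScalarField
from .structio import Solute

__all__ = [
    "ChargeSummary",
    "charge_summary",
    "greens_potential",
    "greens_gradient",
    "greens_on_grid",
    "boundary_potential",
    "rpb_source_water",
    "rpb_source_vacuum",
]

_SINGULARITY_A = 1e-9  # distances below this are treated as "at the charge"


@dataclass(frozen=True)
class ChargeSummary:
    """Net positive/negative partial charges and their charge-weighted
    centers; the two centers form the dipole used by the dipolar boundary
    condition.  A center is None when its sign class is empty."""

    q_tot_plus: float
    q_tot_minus: float
    center_plus: tuple[float, float, float] | None
    center_minus: tuple[float, float, float] | None

    @property
    def dipole_length(self) -> float | None:
        if self.center_plus is None or self.center_minus is None:
            return None
        return float(np.linalg.norm(np.subtract(self.center_plus, self.center_minus)))


def charge_summary(solute: Solute) -> ChargeSummary:
    q = solute.charges
    pos = solute.positions
    plus = q > 0.0
    minus = q < 0.0
    q_plus = float(q[plus].sum())
    q_minus = float(q[minus].sum())
    c_plus = tuple((pos[plus] * q[plus, None]).sum(axis=0) / q_plus) if q_plus > 0 else None
    c_minus = tuple((pos[minus] * q[minus, None]).sum(axis=0) / q_minus) if q_minus < 0 else None
    return ChargeSummary(q_plus, q_minus, c_plus, c_minus)


def greens_potential(solute: Solute, point, constants: PhysicalConstants, eps_ref: float):
    """G(r) = (e^2/kBT) sum_j q_j / (eps_ref |r - r_j|), in kT/e.

    Raises if any evaluation point sits on a charge (use
    :func:`greens_on_grid` for fields that must tolerate coincidences).
    """
    pts = np.asarray(point, dtype=float)
    G = np.zeros(pts.shape[:-1])
    for atom in solute.atoms:
        d = np.linalg.norm(pts - np.asarray(atom.position), axis=-1)
        if np.any(d < _SINGULARITY_A):
            raise ValueError(f"evaluation point within {_SINGULARITY_A} A of atom {atom.name!r}")
        G += atom.charge / d
    G *= constants.coulomb_prefactor / eps_ref
    return G if np.ndim(G) else float(G)


def greens_gradient(solute: Solute, point, constants: PhysicalConstants, eps_ref: float) -> np.ndarray:
    """grad G = -(e^2/kBT) sum_j q_j (r - r_j)/(eps_ref |r - r_j|^3)."""
    pts = np.asarray(point, dtype=float)
    out = np.zeros(pts.shape[:-1] + (3,))
    for atom in solute.atoms:
        dr = pts - np.asarray(atom.position)
        d = np.linalg.norm(dr, axis=-1)
        if np.any(d < _SINGULARITY_A):
            raise ValueError(f"evaluation point within {_SINGULARITY_A} A of atom {atom.name!r}")
        out += -atom.charge * dr / d[..., None] ** 3
    out *= constants.coulomb_prefactor / eps_ref
    return out


def greens_on_grid(
    solute: Solute, grid: Grid, constants: PhysicalConstants, eps_ref: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """G and grad G at every node, plus a boolean mask of nodes that
    coincide with an atom center (where both are set to 0 and the caller
    zeroes the source -- the regularized limit)."""
    pts = grid.node_coords()
    G = np.zeros(grid.dims)
    gradG = np.zeros(grid.dims + (3,))
    coincident = np.zeros(grid.dims, dtype=bool)
    for atom in solute.atoms:
        dr = pts - np.asarray(atom.position)
        d = np.linalg.norm(dr, axis=-1)
        near = d < _SINGULARITY_A
        coincident |= near
        d_safe = np.where(near, 1.0, d)
        G += np.where(near, 0.0, atom.charge / d_safe)
        gradG += np.where(near[..., None], 0.0, -atom.charge * dr / d_safe[..., None] ** 3)
    pref = constants.coulomb_prefactor / eps_ref
    G *= pref
    gradG *= pref
    G[coincident] = 0.0
    gradG[coincident] = 0.0
    return G, gradG, coincident


def boundary_potential(
    solute: Solute,
    point,
    phase: str,
    bc_type: str,
    constants: PhysicalConstants,
    eps_out: float,
    kappa2: float,
):
    """Dirichlet boundary value of the full potential, kT/e.

    coulombic: screened per-charge sum  sum_j q_j e^{-d_j kappa_eff} /
    (eps_out d_j) with kappa_eff = sqrt(kappa2/eps_out); dipolar: the same
    two-term expression over the net positive and negative charges at their
    weighted centers.  The vacuum phase uses eps_out = 1 and no screening.
    """
    pts = np.asarray(point, dtype=float)
    if phase == "vacuum":
        kappa2 = 0.0
    kappa_eff = np.sqrt(kappa2 / eps_out) if kappa2 > 0 else 0.0
    pref = constants.coulomb_prefactor / eps_out

    def _screened(q: float, center) -> np.ndarray:
        d = np.linalg.norm(pts - np.asarray(center, dtype=float), axis=-1)
        d = np.maximum(d, _SINGULARITY_A)
        return pref * q * np.exp(-d * kappa_eff) / d

    if bc_type == "coulombic":
        phi = np.zeros(pts.shape[:-1])
        for atom in solute.atoms:
            phi = phi + _screened(atom.charge, atom.position)
    elif bc_type == "dipolar":
        cs = charge_summary(solute)
        if cs.center_plus is None or cs.center_minus is None:
            raise ValueError(
                "dipolar boundary condition needs both positive and negative charges; "
                "use bc_type='coulombic' for single-sign solutes"
            )
        phi = _screened(cs.q_tot_plus, cs.center_plus) + _screened(cs.q_tot_minus, cs.center_minus)
    else:
        raise ValueError(f"unknown bc_type {bc_type!r}")
    return phi if np.ndim(phi) else float(phi)


def rpb_source_water(
    solute: Solute,
    grid: Grid,
    fields: DielectricFields,
    constants: PhysicalConstants,
    eps_ref: float,
) -> ScalarField:
    """Water-phase regularized source f = grad(eps).grad(G) - (1-S) kappa^2 G.

    Finite at every node: nodes that coincide with an atom center get
    exactly 0 (both factors vanish there in the limit).
    """
    G, gradG, coincident = greens_on_grid(solute, grid, constants, eps_ref)
    f = np.einsum("...i,...i->...", fields.grad_eps.values, gradG)
    if constants.kappa2 > 0:
        f -= (1.0 - fields.S.values) * constants.kappa2 * G
    f[coincident] = 0.0
    return ScalarField(grid, f)


def rpb_source_vacuum(
    solute: Solute,
    grid: Grid,
    fields: DielectricFields,
    constants: PhysicalConstants,
    eps_ref: float,
) -> ScalarField:
    """Vacuum-phase regularized source f = grad(eps_v).grad(G) (no salt)."""
    _, gradG, coincident = greens_on_grid(solute, grid, constants, eps_ref)
    f = np.einsum("...i,...i->...", fields.grad_eps.values, gradG)
    f[coincident] = 0.0
    return ScalarField(grid, f)
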