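"""Solute structures, model parameters, and PQR input/output.

The solute is an ordered list of atoms, each carrying a position (A), a
partial charge (e) and a radius (A) -- exactly the payload of a PQR file.
Parsing is whitespace-tokenized rather than fixed-column because PQR files
in the wild disagree about column layout; the last five numeric tokens of
an ATOM/HETATM record are taken as x y z q r, which is robust to optional
chain identifiers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Solute",
    "PBParams",
    "read_pqr",
    "write_pqr",
    "make_born_ion",
    "make_two_atom",
    "default_params",
    "load_params",
    "save_params",
]


@dataclass(frozen=True)
class Atom:
    """A single solute atom: label, center (A), partial charge (e), radius (A)."""

    name: str
    position: tuple[float, float, float]
    charge: float
    radius: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name!r}: non-finite position {self.position}")
        if not self.radius > 0:
            raise ValueError(f"atom {self.name!r}: radius must be positive, got {self.radius}")


@dataclass(frozen=True)
class Solute:
    """Ordered collection of atoms with a free-text identifier."""

    atoms: tuple[Atom, ...]
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a solute needs at least one atom")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(N, 3) array of atom centers, A."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)


@dataclass(frozen=True)
class PBParams:
    """All tunable parameters of the dielectric model and the solver.

    sigma, m : variance and exponent of the (super-)Gaussian atom density.
        m=1 is a plain Gaussian, m>=2 a flat-topped super-Gaussian; m -> inf
        approaches a hard sphere.
    eps_ref : minimum (reference) dielectric at atom centers.
    eps_gap : limiting dielectric of loosely packed solute interior.
    eps_out : solvent dielectric (80 for water; the vacuum phase uses 1).
    eta : steepness of the density-dependent surface sigmoid.
    salt_molar : 1:1 ionic strength, mol/L.
    scale : grid nodes per A (spacing h = 1/scale).
    padding_A : minimum distance from any atom center to the box faces.
    bc_type : Dirichlet boundary flavor, "coulombic" (per-charge screened
        sum) or "dipolar" (two net-charge centers).
    sor_omega, sor_tol, sor_maxiter : successive over-relaxation controls;
        the residual tolerance is on the diagonally scaled residual in kT/e.
    """

    sigma: float = 1.0
    m: int = 2
    eps_ref: float = 1.0
    eps_gap: float = 22.0
    eps_out: float = 80.0
    eta: float = 2.0
    salt_molar: float = 0.0
    temperature: float = 300.0
    scale: float = 2.5
    padding_A: float = 15.0
    bc_type: str = "coulombic"
    sor_omega: float = 1.9
    sor_tol: float = 1e-6
    sor_maxiter: int = 20000

    def __post_init__(self) -> None:
        if self.eps_ref < 1:
            raise ValueError("eps_ref must be >= 1")
        if self.eps_gap < self.eps_ref:
            raise ValueError("eps_gap must be >= eps_ref")
        if self.eps_out < 1:
            raise ValueError("eps_out must be >= 1")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if self.m < 1:
            raise ValueError("m must be an integer >= 1")
        if not self.eta > 0:
            raise ValueError("eta must be > 0")
        if not self.scale > 0:
            raise ValueError("scale must be > 0")
        if self.salt_molar < 0:
            raise ValueError("salt concentration must be >= 0")
        if self.bc_type not in ("coulombic", "dipolar"):
            raise ValueError(f"bc_type must be 'coulombic' or 'dipolar', got {self.bc_type!r}")

    def replace(self, **kw) -> "PBParams":
        return dataclasses.replace(self, **kw)


def default_params() -> PBParams:
    """The recommended parameter set: sigma=1.0, m=2, eps_ref=1, eps_gap=22,
    eps_out=80, eta=4/m=2, no salt, scale=2.5 grids/A, 15 A box padding."""
    return PBParams()


class PQRParseError(ValueError):
    pass


def read_pqr(path: str | Path) -> Solute:
    """Read a PQR file (whitespace-tokenized ATOM/HETATM records).

    The trailing five numeric fields of each record are x, y, z, charge,
    radius; leading fields (serial, atom/residue names, optional chain id,
    residue number) are tolerated in any of the common layouts.
    """
    path = Path(path)
    atoms: list[Atom] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            if len(rec) < 7:
                raise PQRParseError(f"{path}:{lineno}: too few fields in record: {line.rstrip()!r}")
            try:
                x, y, z, q, r = (float(t) for t in rec[-5:])
            except ValueError as exc:
                raise PQRParseError(f"{path}:{lineno}: non-numeric trailing fields: {line.rstrip()!r}") from exc
            name = rec[2] if len(rec) > 2 else rec[1]
            try:
                atoms.append(Atom(name=name, position=(x, y, z), charge=q, radius=r))
            except ValueError as exc:
                raise PQRParseError(f"{path}:{lineno}: {exc}") from exc
    if not atoms:
        raise PQRParseError(f"{path}: no ATOM/HETATM records found")
    return Solute(atoms=tuple(atoms), id=path.stem)


def write_pqr(solute: Solute, path: str | Path) -> None:
    """Write a Solute as a minimal single-residue PQR file; round-trips
    through :func:`read_pqr` to 1e-3 A/e."""
    path = Path(path)
    with path.open("w") as fh:
        for i, a in enumerate(solute.atoms, start=1):
            x, y, z = a.position
            fh.write(
                f"ATOM  {i:5d} {a.name:<4.4s} MOL     1    "
                f"{x:10.4f}{y:10.4f}{z:10.4f} {a.charge:9.4f} {a.radius:8.4f}\n"
            )
        fh.write("END\n")


def make_born_ion(q: float = 1.0, R: float = 2.0) -> Solute:
    """Single ion of charge q (e) and radius R (A) at the origin -- the
    closed-form Born-model anchor fixture."""
    if R <= 0:
        raise ValueError("radius must be positive")
    return Solute(atoms=(Atom("ION", (0.0, 0.0, 0.0), q, R),), id="born_ion")


def make_two_atom(q1: float = 0.5, q2: float = -0.5) -> Solute:
    """Two-atom fixture: radii 1.5 and 1.7 A at (-1.5, 0, 0) and (1.7, 0, 0).

    The geometry probes overlapping density tails and the interface between
    two unequal atoms; charges default to +/-0.5 e so the pair is a neutral
    dipole usable for boundary-condition tests.
    """
    return Solute(
        atoms=(
            Atom("A1", (-1.5, 0.0, 0.0), q1, 1.5),
            Atom("A2", (1.7, 0.0, 0.0), q2, 1.7),
        ),
        id="two_atom",
    )


_PARAM_TYPES = {f.name: f.type for f in dataclasses.fields(PBParams)}


def load_params(path: str | Path) -> PBParams:
    """Read a flat ``key = value`` config file mapping 1:1 onto PBParams."""
    kw = {}
    for lineno, line in enumerate(Path(path).open(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, val = (t.strip() for t in line.split("=", 1))
        if key not in _PARAM_TYPES:
            raise ValueError(f"{path}:{lineno}: unknown parameter {key!r}")
        if key == "bc_type":
            kw[key] = val
        elif key in ("m", "sor_maxiter"):
            kw[key] = int(val)
        else:
            kw[key] = float(val)
    return PBParams(**kw)


def save_params(params: PBParams, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for f in dataclasses.fields(PBParams):
            fh.write(f"{f.name} = {getattr(params, f.name)}\n")
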