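"""TIP3P water geometry, parameters and the water-water pair potential.

The rigid three-site TIP3P model places a Lennard-Jones site on the oxygen
and fixed partial charges on all three atoms.  The interaction energy
between two waters ``a`` and ``b`` is

    v(a, b) = sum_{i on a} sum_{j on b} k_e * q_i * q_j / r_ij
              + A / r_oo^12  -  C / r_oo^6

i.e. nine Coulomb terms over the 3 x 3 charge-site pairs plus a single
oxygen-oxygen Lennard-Jones term.  A pair is counted as hydrogen bonded
when v(a, b) falls at or below an energy criterion (default
-2.25 kcal/mol, the minimum of the pair-energy distribution of liquid
TIP3P water).  Intramolecular terms are never computed: the monomer is
rigid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "TIP3PParameters",
    "WaterMolecule",
    "pair_interaction_energy",
    "is_hydrogen_bonded",
    "O_MASS",
    "H_MASS",
    "OH_BOND_LENGTH",
    "HOH_ANGLE_DEG",
]

#: Atomic masses used for water-ring centers of mass, in Da.
O_MASS = 15.999
H_MASS = 1.008

#: Ideal rigid TIP3P monomer geometry.
OH_BOND_LENGTH = 0.9572  # Angstrom
HOH_ANGLE_DEG = 104.52

# warn-only tolerances on the monomer geometry checks
_OH_TOL = 0.05  # Angstrom
_ANGLE_TOL = 2.0  # degrees


@dataclass(frozen=True)
class TIP3PParameters:
    """TIP3P pair-potential parameters.

    Attributes
    ----------
    A : float
        Repulsive Lennard-Jones coefficient, kcal A^12 / mol.
    C : float
        Attractive Lennard-Jones coefficient, kcal A^6 / mol.
    q_O, q_H : float
        Partial charges on oxygen and hydrogen, in units of e.
    k_e : float
        Coulomb conversion constant, kcal A / (mol e^2).  The CHARMM
        convention (332.0636) is the default so that charge products in
        e^2 / Angstrom come out in kcal/mol.
    e_hbond : float
        Hydrogen-bond energy criterion, kcal/mol.  A pair with
        ``v(a, b) <= e_hbond`` is hydrogen bonded (the boundary counts).
    """

    A: float = 582000.0
    C: float = 595.0
    q_O: float = -0.834
    q_H: float = 0.417
    k_e: float = 332.0636
    e_hbond: float = -2.25

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError(f"A must be positive, got {self.A}")
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if abs(self.q_O + 2.0 * self.q_H) > 1e-9:
            raise ValueError(
                f"water must be charge neutral: q_O + 2 q_H = {self.q_O + 2 * self.q_H}"
            )
        if not self.e_hbond < 0:
            raise ValueError(f"e_hbond must be negative, got {self.e_hbond}")

    @property
    def lj_r_min(self) -> float:
        """O-O distance of the pure Lennard-Jones minimum, (2A/C)^(1/6)."""
        return (2.0 * self.A / self.C) ** (1.0 / 6.0)

    @property
    def lj_depth(self) -> float:
        """Depth of the pure Lennard-Jones well, -C^2/(4A) (kcal/mol)."""
        return -self.C * self.C / (4.0 * self.A)


class WaterMolecule:
    """One rigid TIP3P water: an oxygen and two hydrogens.

    Parameters
    ----------
    water_id : int
        Label unique within a frame.
    o_pos, h1_pos, h2_pos : array-like, shape (3,)
        Cartesian atom positions in Angstrom.
    check_geometry : bool
        Warn (never raise) if O-H bond lengths or the H-O-H angle deviate
        from the ideal rigid monomer beyond tolerance.
    """

    __slots__ = ("water_id", "o_pos", "h1_pos", "h2_pos")

    def __init__(self, water_id, o_pos, h1_pos, h2_pos, *, check_geometry=True):
        self.water_id = int(water_id)
        self.o_pos = np.asarray(o_pos, dtype=float)
        self.h1_pos = np.asarray(h1_pos, dtype=float)
        self.h2_pos = np.asarray(h2_pos, dtype=float)
        for name, pos in (("O", self.o_pos), ("H1", self.h1_pos), ("H2", self.h2_pos)):
            if pos.shape != (3,):
                raise ValueError(f"{name} position must have shape (3,), got {pos.shape}")
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"{name} position of water {water_id} is not finite")
        if check_geometry:
            self._warn_if_distorted()

    def _warn_if_distorted(self) -> None:
        d1 = float(np.linalg.norm(self.h1_pos - self.o_pos))
        d2 = float(np.linalg.norm(self.h2_pos - self.o_pos))
        for tag, d in (("O-H1", d1), ("O-H2", d2)):
            if abs(d - OH_BOND_LENGTH) > _OH_TOL:
                warnings.warn(
                    f"water {self.water_id}: {tag} bond {d:.3f} A deviates from "
                    f"ideal {OH_BOND_LENGTH} A",
                    stacklevel=3,
                )
        if d1 > 0 and d2 > 0:
            u = (self.h1_pos - self.o_pos) / d1
            v = (self.h2_pos - self.o_pos) / d2
            ang = math.degrees(math.acos(float(np.clip(np.dot(u, v), -1.0, 1.0))))
            if abs(ang - HOH_ANGLE_DEG) > _ANGLE_TOL:
                warnings.warn(
                    f"water {self.water_id}: H-O-H angle {ang:.2f} deg deviates "
                    f"from ideal {HOH_ANGLE_DEG} deg",
                    stacklevel=3,
                )

    @property
    def sites(self) -> np.ndarray:
        """(3, 3) array of charge-site positions in the order O, H1, H2."""
        return np.stack([self.o_pos, self.h1_pos, self.h2_pos])

    def translated(self, shift) -> "WaterMolecule":
        shift = np.asarray(shift, dtype=float)
        return WaterMolecule(
            self.water_id,
            self.o_pos + shift,
            self.h1_pos + shift,
            self.h2_pos + shift,
            check_geometry=False,
        )

    def transformed(self, rotation, translation=(0.0, 0.0, 0.0)) -> "WaterMolecule":
        """Apply ``x -> R x + t`` to every atom."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return WaterMolecule(
            self.water_id,
            R @ self.o_pos + t,
            R @ self.h1_pos + t,
            R @ self.h2_pos + t,
            check_geometry=False,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"WaterMolecule(id={self.water_id}, O={np.round(self.o_pos, 3)})"


def _site_charges(p: TIP3PParameters) -> np.ndarray:
    return np.array([p.q_O, p.q_H, p.q_H])


def pair_energies(sites_a: np.ndarray, sites_b: np.ndarray, p: TIP3PParameters) -> np.ndarray:
    """Vectorized pair potential for batches of water site coordinates.

    ``sites_a``/``sites_b`` have shape (m, 3, 3): m pairs, 3 sites (O, H1,
    H2), xyz.  Returns the m pair energies in kcal/mol.  Raises
    :class:`DegenerateGeometryError` if any intermolecular site distance
    is zero.
    """
    sites_a = np.asarray(sites_a, dtype=float)
    sites_b = np.asarray(sites_b, dtype=float)
    # (m, 3, 3) pairwise site distances: i on a (axis 1), j on b (axis 2)
    diff = sites_a[:, :, None, :] - sites_b[:, None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    if np.any(r == 0.0):
        raise DegenerateGeometryError("coincident interaction sites between two waters")
    q = _site_charges(p)
    coulomb = p.k_e * np.sum(q[None, :, None] * q[None, None, :] / r, axis=(1, 2))
    r_oo = r[:, 0, 0]
    r6 = r_oo**6
    lj = p.A / (r6 * r6) - p.C / r6
    return coulomb + lj


def pair_interaction_energy(
    a: WaterMolecule, b: WaterMolecule, p: TIP3PParameters | None = None
) -> float:
    """Interaction energy v(a, b) between two waters, kcal/mol.

    Nine Coulomb site-site terms plus the O-O Lennard-Jones term; symmetric
    in its arguments.  Raises on equal ids (a water does not interact with
    itself under the rigid model) and on coincident sites.
    """
    if p is None:
        p = TIP3PParameters()
    if a.water_id == b.water_id:
        raise ValueError(f"pair energy requested for water {a.water_id} with itself")
    return float(pair_energies(a.sites[None], b.sites[None], p)[0])


def is_hydrogen_bonded(
    a: WaterMolecule, b: WaterMolecule, p: TIP3PParameters | None = None
) -> bool:
    """True iff ``v(a, b) <= e_hbond`` (the boundary counts as bonded)."""
    if p is None:
        p = TIP3PParameters()
    return pair_interaction_energy(a, b, p) <= p.e_hbond
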