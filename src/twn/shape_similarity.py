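"""Ligand vs water-network shape similarity.

A docked ligand is compared with the centres of mass (COMs) of the water
rings detected in the apo binding site.  Networks are first selected by
proximity (COM within a cutoff, default 2 Angstrom, of any ligand heavy
atom); the similarity score is then the percentage of ligand heavy atoms
that have at least one network COM within the match radius -- a
heavy-atom coverage fraction.  A region-restricted variant uses only the
heavy atoms and COMs assigned to a named binding-site region, which is how
the solvent-front (D-site) contribution to selectivity is isolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .ring_graph import WaterRing
from .site_regions import RegionDefinition, assign_region

__all__ = [
    "LigandStructure",
    "ShapeSimilarityResult",
    "select_networks_near_ligand",
    "shape_similarity_score",
    "read_ligand",
]


@dataclass(frozen=True)
class LigandStructure:
    """A ligand as (element, position) atoms; hydrogens are ignored."""

    atoms: tuple[tuple[str, tuple[float, float, float]], ...]

    def __post_init__(self) -> None:
        if not any(el.upper() != "H" for el, _ in self.atoms):
            raise ValueError("ligand has no heavy atoms")
        for el, pos in self.atoms:
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"non-finite position on ligand atom {el}")

    @property
    def heavy_atoms(self) -> np.ndarray:
        """(n, 3) heavy-atom coordinates in Angstrom."""
        return np.asarray(
            [pos for el, pos in self.atoms if el.upper() != "H"], dtype=float
        )


def read_ligand(path) -> LigandStructure:
    """Read a ligand from PDB, SDF or MOL2 (by extension) via RDKit."""
    from rdkit import Chem

    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
        mol = next((m for m in supplier if m is not None), None)
    elif ext == ".mol2":
        mol = Chem.MolFromMol2File(str(path), removeHs=False, sanitize=False)
    elif ext == ".pdb":
        mol = Chem.MolFromPDBFile(str(path), removeHs=False, sanitize=False)
    else:
        raise ValueError(f"unsupported ligand format {ext!r} (use .pdb/.sdf/.mol2)")
    if mol is None:
        raise ValueError(f"could not parse ligand file {path}")
    conf = mol.GetConformer()
    atoms = tuple(
        (
            atom.GetSymbol(),
            tuple(float(x) for x in conf.GetAtomPosition(atom.GetIdx())),
        )
        for atom in mol.GetAtoms()
    )
    return LigandStructure(atoms)


@dataclass
class ShapeSimilarityResult:
    overall_percent: float
    per_region_percent: dict[str, float] = field(default_factory=dict)
    n_networks_used: int = 0
    n_heavy_atoms: int = 0
    match_radius: float = 2.0

    def to_dict(self) -> dict:
        return {
            "overall_percent": self.overall_percent,
            "per_region_percent": self.per_region_percent,
            "n_networks_used": self.n_networks_used,
            "n_heavy_atoms": self.n_heavy_atoms,
            "match_radius": self.match_radius,
        }


def _ring_coms(networks) -> np.ndarray:
    coms = []
    for r in networks:
        if r.com is None:
            raise ValueError(f"ring {r.members} has no centre of mass")
        coms.append(r.com)
    return np.asarray(coms, dtype=float).reshape(-1, 3)


def select_networks_near_ligand(
    rings, ligand: LigandStructure, cutoff: float = 2.0
) -> list[WaterRing]:
    """Rings whose COM is within ``cutoff`` (inclusive) of any heavy atom."""
    if not cutoff > 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    heavy = ligand.heavy_atoms
    rings = list(rings)
    if not rings:
        return []
    coms = _ring_coms(rings)
    d = np.linalg.norm(coms[:, None, :] - heavy[None, :, :], axis=-1)
    keep = d.min(axis=1) <= cutoff
    return [r for r, k in zip(rings, keep) if k]


def _coverage_percent(heavy: np.ndarray, coms: np.ndarray, radius: float) -> float:
    if heavy.shape[0] == 0:
        return 0.0
    if coms.shape[0] == 0:
        return 0.0
    d = np.linalg.norm(heavy[:, None, :] - coms[None, :, :], axis=-1)
    covered = (d.min(axis=1) <= radius).sum()
    return 100.0 * covered / heavy.shape[0]


def shape_similarity_score(
    ligand: LigandStructure,
    networks,
    match_radius: float = 2.0,
    regions: list[RegionDefinition] | None = None,
    region_names=None,
) -> ShapeSimilarityResult:
    """Heavy-atom coverage score between a ligand and network COMs.

    Overall: percentage of ligand heavy atoms with at least one network
    COM within ``match_radius``.  For each requested region name, the
    score is recomputed using only heavy atoms assigned to that region and
    only COMs assigned to it.
    """
    networks = list(networks)
    heavy = ligand.heavy_atoms
    coms = _ring_coms(networks) if networks else np.empty((0, 3))
    result = ShapeSimilarityResult(
        overall_percent=_coverage_percent(heavy, coms, match_radius),
        n_networks_used=len(networks),
        n_heavy_atoms=heavy.shape[0],
        match_radius=match_radius,
    )
    if region_names:
        if regions is None:
            raise ConfigurationError("region names given but no region definitions")
        defined = {r.name for r in regions}
        for name in region_names:
            if name not in defined:
                raise ConfigurationError(f"region {name!r} is not defined")
            atom_mask = np.array(
                [assign_region(x, regions) == name for x in heavy], dtype=bool
            )
            com_mask = np.array(
                [assign_region(x, regions) == name for x in coms], dtype=bool
            )
            result.per_region_percent[name] = _coverage_percent(
                heavy[atom_mask], coms[com_mask], match_radius
            )
    return result
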