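"""Binding-site regions, ring-propensity tables and residue-string similarity.

A kinase ATP site is partitioned into named regions (conventionally A-E:
adenine/hinge pocket, back pocket, ribose groove, solvent-exposed front,
catalytic/DFG area).  Each region is a union of spheres whose centres are
literal points or atom selectors resolved per frame.  A ring belongs to
the region whose sphere contains its centre of mass; overlaps are broken
by the closest containing-sphere centre, then by declaration order.

The propensity table reports, per region, the count and percentage of
rings assigned to it, normalised over assigned rings only; unassigned
rings are counted separately.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .ring_graph import WaterRing, ring_center_of_mass
from .trajectory_io import AtomRecord, Frame, select_atoms

__all__ = [
    "Sphere",
    "RegionDefinition",
    "RegionPropensityTable",
    "assign_region",
    "compute_region_propensity",
    "residue_similarity",
    "DEFAULT_SIMILARITY_GROUPS",
    "regions_from_config",
]

logger = logging.getLogger(__name__)

#: Default residue similarity grouping: aliphatic, aromatic, basic, acidic,
#: amide, hydroxyl, and the three singletons.
DEFAULT_SIMILARITY_GROUPS = (
    "AVILM",
    "FYW",
    "KRH",
    "DE",
    "NQ",
    "ST",
    "C",
    "G",
    "P",
)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class Sphere:
    """One region sphere: a literal centre point or an atom selector.

    Exactly one of ``point`` (Angstrom triple) or ``selector`` (mapping for
    :func:`twn.trajectory_io.select_atoms`; the centre is the centroid of
    the matched atoms) must be given.
    """

    radius: float
    point: tuple[float, float, float] | None = None
    selector: dict | None = None

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"sphere radius must be positive, got {self.radius}")
        if (self.point is None) == (self.selector is None):
            raise ValueError("exactly one of point or selector must be set")

    def center(self, protein_atoms: list[AtomRecord] | None = None) -> np.ndarray:
        if self.point is not None:
            return np.asarray(self.point, dtype=float)
        matched = select_atoms(protein_atoms or [], self.selector)
        if not matched:
            raise ConfigurationError(
                f"region sphere selector {self.selector!r} matched no atoms"
            )
        return np.mean([a.position for a in matched], axis=0)


@dataclass(frozen=True)
class RegionDefinition:
    name: str
    spheres: tuple[Sphere, ...]

    def __post_init__(self) -> None:
        if not self.spheres:
            raise ValueError(f"region {self.name!r} has no spheres")


def assign_region(
    point,
    regions: list[RegionDefinition],
    protein_atoms: list[AtomRecord] | None = None,
) -> str | None:
    """Name of the region owning ``point``, or None if no sphere contains it.

    Boundary is inclusive.  When spheres of several regions contain the
    point, the region whose nearest containing-sphere centre is closest
    wins; remaining ties go to the earlier-declared region.
    """
    point = np.asarray(point, dtype=float)
    best: tuple[float, int] | None = None
    best_name: str | None = None
    for order, region in enumerate(regions):
        containing = [
            d
            for s in region.spheres
            if (d := float(np.linalg.norm(point - s.center(protein_atoms)))) <= s.radius
        ]
        if not containing:
            continue
        key = (min(containing), order)
        if best is None or key < best:
            best, best_name = key, region.name
    return best_name


@dataclass
class RegionPropensityTable:
    """Per-region ring counts and percentages over a set of frames."""

    counts: dict[str, int]
    percents: dict[str, float]
    total_assigned: int
    total_rings: int
    unassigned: int
    frames_used: int

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "region": list(self.counts),
                "rings": [self.counts[r] for r in self.counts],
                "percent": [self.percents[r] for r in self.counts],
            }
        )


def compute_region_propensity(
    rings,
    regions: list[RegionDefinition],
    waters_by_frame: dict[int, dict] | None = None,
    protein_atoms_by_frame: dict[int, list[AtomRecord]] | None = None,
) -> RegionPropensityTable:
    """Assign every ring (by its centre of mass) to a region and tabulate.

    Percentages are normalised over assigned rings only; rings outside all
    spheres are reported in ``unassigned``.  Rings lacking a precomputed
    centre of mass are resolved through ``waters_by_frame`` (frame index ->
    water lookup).
    """
    counts = {r.name: 0 for r in regions}
    unassigned = 0
    frames = set()
    rings = list(rings)
    for ring in rings:
        if ring.frame_index is not None:
            frames.add(ring.frame_index)
        com = ring.com
        if com is None:
            if waters_by_frame is None or ring.frame_index not in waters_by_frame:
                raise ValueError(
                    f"ring {ring.members} has no centre of mass and no water lookup"
                )
            com = ring_center_of_mass(ring, waters_by_frame[ring.frame_index])
        atoms = None
        if protein_atoms_by_frame is not None and ring.frame_index is not None:
            atoms = protein_atoms_by_frame.get(ring.frame_index)
        name = assign_region(com, regions, atoms)
        if name is None:
            unassigned += 1
        else:
            counts[name] += 1

    total_assigned = sum(counts.values())
    if total_assigned == 0:
        if rings:
            logger.warning("no rings fell inside any region; percentages undefined")
        percents = {r.name: math.nan for r in regions}
    else:
        percents = {name: 100.0 * c / total_assigned for name, c in counts.items()}
    return RegionPropensityTable(
        counts=counts,
        percents=percents,
        total_assigned=total_assigned,
        total_rings=len(rings),
        unassigned=unassigned,
        frames_used=len(frames),
    )


def residue_similarity(
    seq_a: str,
    seq_b: str,
    grouping=DEFAULT_SIMILARITY_GROUPS,
) -> float:
    """Positionwise percent similarity of two equal-length residue strings.

    A position counts when the residues are identical or fall in the same
    similarity group.  No alignment is performed; a length mismatch is an
    error.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequence lengths differ ({len(seq_a)} vs {len(seq_b)}); "
            "residue_similarity does not align"
        )
    if not seq_a:
        raise ValueError("empty sequences")
    for ch in seq_a + seq_b:
        if ch not in _AA_ALPHABET:
            raise ValueError(f"non-amino-acid character {ch!r}")
    group_of: dict[str, int] = {}
    for gi, group in enumerate(grouping):
        for ch in group:
            group_of[ch.upper()] = gi
    matches = sum(
        1
        for a, b in zip(seq_a, seq_b)
        if a == b or (a in group_of and b in group_of and group_of[a] == group_of[b])
    )
    return 100.0 * matches / len(seq_a)


def regions_from_config(cfg: list | dict) -> list[RegionDefinition]:
    """Build region definitions from parsed YAML/JSON.

    Expected shape::

        regions:
          - name: D
            spheres:
              - point: [x, y, z]
                radius: 5.0
              - selector: {resname: MET, resid: 265, name: CA}
                radius: 6.0
    """
    if isinstance(cfg, dict):
        cfg = cfg.get("regions", cfg)
    regions = []
    names = set()
    for entry in cfg:
        name = entry.get("name")
        if not name:
            raise ConfigurationError("region entry missing 'name'")
        if name in names:
            raise ConfigurationError(f"duplicate region name {name!r}")
        names.add(name)
        spheres = []
        for s in entry.get("spheres", []):
            extra = set(s) - {"point", "selector", "radius"}
            if extra:
                raise ConfigurationError(
                    f"region {name!r}: unknown sphere keys {sorted(extra)}"
                )
            if "radius" not in s:
                raise ConfigurationError(f"region {name!r}: sphere missing 'radius'")
            spheres.append(
                Sphere(
                    radius=float(s["radius"]),
                    point=tuple(s["point"]) if "point" in s else None,
                    selector=s.get("selector"),
                )
            )
        regions.append(RegionDefinition(name=name, spheres=tuple(spheres)))
    return regions
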