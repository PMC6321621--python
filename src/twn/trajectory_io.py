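"""Reading and writing hydration snapshots, and binding-site water extraction.

Snapshots come in as multi-model PDB or GRO files (one :class:`Frame` per
model / snapshot) via MDAnalysis, so coordinates are in Angstrom regardless
of the on-disk unit.  Waters are recognised by residue name and must carry
exactly three atoms (O, H1, H2); incomplete waters are skipped and counted
unless ``strict`` is set.

Site extraction keeps every water whose oxygen lies within a cutoff
(default 20 Angstrom, inclusive) of the centroid of a set of anchor atoms
-- typically the Asp-Phe-Gly (DFG) motif at the start of a kinase
activation loop.  Frames are assumed solute-centred and wrapped, so
distances are plain Euclidean by default; an orthorhombic minimum-image
option exists for raw boxes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, TWNError
from .water_model import WaterMolecule

__all__ = [
    "AtomRecord",
    "Frame",
    "SiteSelection",
    "DEFAULT_WATER_RESNAMES",
    "read_frames",
    "write_frames",
    "extract_site_waters",
]

logger = logging.getLogger(__name__)

#: Residue names treated as water on input.
DEFAULT_WATER_RESNAMES = frozenset({"HOH", "SOL", "WAT", "TIP3"})


@dataclass(frozen=True)
class AtomRecord:
    """One labelled non-water atom (protein, ligand, ion) in a frame."""

    resname: str
    resid: int
    name: str
    position: tuple[float, float, float]


@dataclass
class Frame:
    """One snapshot: waters plus labelled non-water atoms.

    ``box`` holds orthorhombic box lengths in Angstrom when known.
    ``n_skipped_waters`` counts water residues dropped on read because they
    did not have exactly one O and two H atoms.
    """

    frame_index: int
    waters: list[WaterMolecule]
    protein_atoms: list[AtomRecord] = field(default_factory=list)
    time: float | None = None
    box: tuple[float, float, float] | None = None
    n_skipped_waters: int = 0

    def __post_init__(self) -> None:
        ids = [w.water_id for w in self.waters]
        if len(ids) != len(set(ids)):
            raise ValueError(f"frame {self.frame_index}: duplicate water ids")

    def water_lookup(self) -> dict[int, WaterMolecule]:
        return {w.water_id: w for w in self.waters}


@dataclass(frozen=True)
class SiteSelection:
    """Binding-site definition: anchor atom selector plus a cutoff radius.

    ``anchor_spec`` is a mapping with any of the keys ``resname``,
    ``resid``, ``name``; each value is a single label or a list.  An atom
    matches when it satisfies every given key.  ``ca_only`` restricts the
    anchor to CA atoms regardless of ``name``.
    """

    anchor_spec: dict
    cutoff: float = 20.0
    ca_only: bool = False

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")


def _as_set(value) -> set | None:
    if value is None:
        return None
    if isinstance(value, (str, int)):
        return {value}
    return set(value)


def select_atoms(atoms: list[AtomRecord], spec: dict) -> list[AtomRecord]:
    """Filter atom records by a {resname, resid, name} selector mapping."""
    unknown = set(spec) - {"resname", "resid", "name"}
    if unknown:
        raise ConfigurationError(f"unknown selector keys: {sorted(unknown)}")
    resnames = _as_set(spec.get("resname"))
    resids = _as_set(spec.get("resid"))
    names = _as_set(spec.get("name"))
    out = []
    for a in atoms:
        if resnames is not None and a.resname not in resnames:
            continue
        if resids is not None and a.resid not in resids:
            continue
        if names is not None and a.name not in names:
            continue
        out.append(a)
    return out


def _classify_water_atoms(names: list[str], positions: np.ndarray):
    """Split a water residue's atoms into (O, [H...]) by atom-name element hint."""
    o, hs = None, []
    for name, pos in zip(names, positions):
        elem = name.strip().lstrip("0123456789")[:1].upper()
        if elem == "O":
            if o is not None:
                return None  # two oxygens: malformed
            o = pos
        elif elem == "H":
            hs.append(pos)
        else:
            return None
    if o is None or len(hs) != 2:
        return None
    return o, hs


def read_frames(
    path,
    water_resnames=DEFAULT_WATER_RESNAMES,
    strict: bool = False,
) -> list[Frame]:
    """Read a multi-model PDB or GRO file into a list of frames.

    One frame per MODEL record (a PDB without MODEL records yields a single
    frame).  Water residues with anything other than one O and two H atoms
    are skipped with a warning and counted on ``Frame.n_skipped_waters``
    (``strict=True`` raises instead).
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    water_resnames = set(water_resnames)
    with warnings.catch_warnings():
        # PDB fixtures routinely lack element/charge columns; the guessed
        # attributes are not used below.
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))

    # residue split computed once; coordinates vary per trajectory frame
    water_residues, other_atoms_ix = [], []
    for res in u.residues:
        if res.resname.strip() in water_resnames:
            water_residues.append(res)
        else:
            other_atoms_ix.extend(res.atoms.indices)

    frames: list[Frame] = []
    for ts in u.trajectory:
        waters, skipped = [], 0
        for wid, res in enumerate(water_residues):
            names = [a.name for a in res.atoms]
            parsed = _classify_water_atoms(names, res.atoms.positions)
            if parsed is None:
                msg = (
                    f"frame {ts.frame}: water residue {res.resname} {res.resid} "
                    f"has atoms {names}, expected one O and two H; skipped"
                )
                if strict:
                    raise TWNError(msg)
                logger.warning(msg)
                skipped += 1
                continue
            o, (h1, h2) = parsed
            waters.append(WaterMolecule(wid, o, h1, h2, check_geometry=False))
        protein_atoms = [
            AtomRecord(
                u.atoms[i].resname,
                int(u.atoms[i].resid),
                u.atoms[i].name,
                tuple(map(float, u.atoms[i].position)),
            )
            for i in other_atoms_ix
        ]
        box = None
        if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            box = tuple(float(x) for x in ts.dimensions[:3])
        with warnings.catch_warnings():
            # readers without dt information warn when asked for a time
            warnings.simplefilter("ignore")
            time = float(ts.time) if ts.time is not None else None
        frames.append(
            Frame(
                frame_index=int(ts.frame),
                waters=waters,
                protein_atoms=protein_atoms,
                time=time,
                box=box,
                n_skipped_waters=skipped,
            )
        )
    return frames


def write_frames(frames: list[Frame], path) -> None:
    """Write frames as a multi-model PDB (waters as HOH, O/H1/H2 atoms)."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    if not frames:
        raise ValueError("no frames to write")
    first = frames[0]
    n_waters = len(first.waters)
    n_prot = len(first.protein_atoms)
    for f in frames:
        if len(f.waters) != n_waters or len(f.protein_atoms) != n_prot:
            raise ValueError("all frames must share one topology to be written")

    n_atoms = n_prot + 3 * n_waters

    # build one flat topology: protein atoms first (one residue per distinct
    # (resname, resid)), then waters as HOH residues with atoms O, H1, H2
    names, resnames, resids, resindex = [], [], [], []
    res_seen: dict[tuple, int] = {}
    for a in first.protein_atoms:
        key = (a.resname, a.resid)
        if key not in res_seen:
            res_seen[key] = len(res_seen)
            resnames.append(a.resname)
            resids.append(a.resid)
        names.append(a.name)
        resindex.append(res_seen[key])
    next_resid = (max(resids) + 1) if resids else 1
    for w in first.waters:
        ri = len(resnames)
        resnames.append("HOH")
        resids.append(next_resid)
        next_resid += 1
        for nm in ("O", "H1", "H2"):
            names.append(nm)
            resindex.append(ri)

    coords = np.empty((len(frames), n_atoms, 3), dtype=np.float32)
    for k, f in enumerate(frames):
        rows = [a.position for a in f.protein_atoms]
        for w in f.waters:
            rows.extend([w.o_pos, w.h1_pos, w.h2_pos])
        coords[k] = np.asarray(rows, dtype=np.float32)

    u = mda.Universe.empty(
        n_atoms,
        n_residues=len(resnames),
        atom_resindex=np.asarray(resindex),
        residue_segindex=np.zeros(len(resnames), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    u.load_new(coords, format=MemoryReader)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms, multiframe=True) as pdb:
            for ts in u.trajectory:
                pdb.write(u.atoms)


def anchor_centroid(frame: Frame, site: SiteSelection) -> np.ndarray:
    """Centroid of the anchor atoms of ``site`` in ``frame`` (Angstrom)."""
    spec = dict(site.anchor_spec)
    if site.ca_only:
        spec["name"] = "CA"
    matched = select_atoms(frame.protein_atoms, spec)
    if not matched:
        raise ConfigurationError(
            f"site anchor selector {site.anchor_spec!r} matched no atoms "
            f"in frame {frame.frame_index}"
        )
    return np.mean([a.position for a in matched], axis=0)


def extract_site_waters(
    frame: Frame,
    site: SiteSelection,
    minimum_image: bool = False,
) -> list[WaterMolecule]:
    """Waters whose oxygen lies within ``site.cutoff`` (inclusive) of the
    anchor centroid.  Water ids are preserved.
    """
    center = anchor_centroid(frame, site)
    if not frame.waters:
        return []
    o_pos = np.stack([w.o_pos for w in frame.waters])
    delta = o_pos - center
    if minimum_image:
        if frame.box is None:
            raise ConfigurationError("minimum_image requested but frame has no box")
        box = np.asarray(frame.box)
        delta -= box * np.round(delta / box)
    dist = np.linalg.norm(delta, axis=1)
    return [w for w, d in zip(frame.waters, dist) if d <= site.cutoff]
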