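"""Hydrogen-bond graph construction and cyclic water-ring enumeration.

Waters linked by hydrogen bonds form cyclic ring networks; the topological
water network (TWN) analysis counts the three- to six-membered simple
cycles of the hydrogen-bond graph.  Rings are reported in a canonical
orientation (smallest member id first, proceeding toward its smaller-id
neighbour) so that rotations and reflections of the same cycle collapse to
one record.

By default all simple cycles count, whether or not the cycle carries a
chord (an extra hydrogen bond across the ring); ``chordless=True``
restricts enumeration to chordless cycles for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .water_model import (
    H_MASS,
    O_MASS,
    TIP3PParameters,
    WaterMolecule,
    pair_energies,
)

__all__ = [
    "WaterRing",
    "build_hbond_graph",
    "enumerate_rings",
    "ring_center_of_mass",
    "detect_rings",
    "DEFAULT_OO_PRESCREEN",
]

#: O-O distance (Angstrom) beyond which no water pair can reach the
#: hydrogen-bond energy criterion; used as a neighbour-list pre-screen.
#: Result-identity with the all-pairs scan is covered by the test suite.
DEFAULT_OO_PRESCREEN = 6.0


@dataclass(frozen=True)
class WaterRing:
    """A canonical cyclic water ring.

    ``members`` is the cyclic member sequence starting at the smallest
    water id and proceeding toward its smaller-id neighbour.  ``com`` is
    the mass-weighted centre of the 3 * size atoms, when computed.
    """

    members: tuple[int, ...]
    com: tuple[float, float, float] | None = None
    frame_index: int | None = None

    def __post_init__(self) -> None:
        if not 3 <= len(self.members):
            raise ValueError(f"a ring needs at least 3 members, got {self.members}")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"repeated member in ring {self.members}")

    @property
    def size(self) -> int:
        return len(self.members)

    def with_com(self, com) -> "WaterRing":
        return WaterRing(self.members, tuple(float(x) for x in com), self.frame_index)


def canonical_cycle(members) -> tuple[int, ...]:
    """Canonical orientation of a cyclic id sequence.

    Rotate so the smallest id comes first, then run toward the smaller of
    its two cycle neighbours, making the tuple unique under rotation and
    reflection.
    """
    members = list(members)
    n = len(members)
    k = members.index(min(members))
    rot = members[k:] + members[:k]
    if rot[1] > rot[-1]:
        rot = [rot[0]] + rot[:0:-1]
    return tuple(rot)


def build_hbond_graph(
    waters: list[WaterMolecule],
    p: TIP3PParameters | None = None,
    prescreen: float | None = DEFAULT_OO_PRESCREEN,
) -> nx.Graph:
    """Build the water hydrogen-bond graph.

    Nodes are water ids; an edge joins two waters whose pair energy is at
    or below ``p.e_hbond``, annotated with that energy (``energy`` edge
    attribute, kcal/mol).  ``prescreen`` limits the pair evaluation to
    oxygens within that distance; pass ``None`` for the exhaustive
    all-pairs scan (identical result, slower).
    """
    if p is None:
        p = TIP3PParameters()
    ids = [w.water_id for w in waters]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate water ids in hydrogen-bond graph input")

    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(waters)
    if n < 2:
        return g

    if prescreen is not None:
        tree = cKDTree(np.stack([w.o_pos for w in waters]))
        pairs = np.asarray(sorted(tree.query_pairs(prescreen)), dtype=int)
        if pairs.size == 0:
            return g
    else:
        iu = np.triu_indices(n, k=1)
        pairs = np.stack(iu, axis=1)

    sites = np.stack([w.sites for w in waters])
    energies = pair_energies(sites[pairs[:, 0]], sites[pairs[:, 1]], p)
    for (i, j), e in zip(pairs, energies):
        if e <= p.e_hbond:
            g.add_edge(ids[i], ids[j], energy=float(e))
    return g


def enumerate_rings(
    g: nx.Graph,
    min_size: int = 3,
    max_size: int = 6,
    chordless: bool = False,
    frame_index: int | None = None,
) -> set[WaterRing]:
    """Enumerate every simple cycle of length ``min_size``..``max_size``.

    Each cycle appears exactly once, in canonical form, regardless of
    rotation or reflection.  The bounded depth-first search roots each
    cycle at its smallest node and fixes the traversal direction by
    requiring the second node to be smaller than the last, so no cycle is
    emitted twice.
    """
    if not 3 <= min_size <= max_size:
        raise ValueError(f"need 3 <= min_size <= max_size, got {min_size}, {max_size}")

    adj = {u: sorted(g.neighbors(u)) for u in g.nodes}
    rings: set[WaterRing] = set()

    def extend(root: int, path: list[int], on_path: set[int]) -> None:
        last = path[-1]
        for nxt in adj[last]:
            if nxt == root:
                if len(path) >= min_size and path[1] < path[-1]:
                    rings.add(WaterRing(tuple(path), frame_index=frame_index))
            elif nxt > root and nxt not in on_path and len(path) < max_size:
                path.append(nxt)
                on_path.add(nxt)
                extend(root, path, on_path)
                on_path.discard(path.pop())

    for root in sorted(adj):
        extend(root, [root], {root})

    if chordless:
        rings = {
            r for r in rings if g.subgraph(r.members).number_of_edges() == r.size
        }
    return rings


def ring_center_of_mass(
    ring: WaterRing, waters: dict[int, WaterMolecule]
) -> np.ndarray:
    """Mass-weighted centre of all 3*size atoms of the ring's waters."""
    masses, positions = [], []
    for wid in ring.members:
        if wid not in waters:
            raise ValueError(f"ring member {wid} not present in water lookup")
        w = waters[wid]
        positions.extend([w.o_pos, w.h1_pos, w.h2_pos])
        masses.extend([O_MASS, H_MASS, H_MASS])
    masses = np.asarray(masses)
    positions = np.stack(positions)
    return (masses[:, None] * positions).sum(axis=0) / masses.sum()


def detect_rings(
    waters: list[WaterMolecule],
    p: TIP3PParameters | None = None,
    min_size: int = 3,
    max_size: int = 6,
    chordless: bool = False,
    frame_index: int | None = None,
    prescreen: float | None = DEFAULT_OO_PRESCREEN,
) -> set[WaterRing]:
    """Full per-frame pipeline: H-bond graph, cycles, centres of mass."""
    g = build_hbond_graph(waters, p, prescreen=prescreen)
    lookup = {w.water_id: w for w in waters}
    return {
        r.with_com(ring_center_of_mass(r, lookup))
        for r in enumerate_rings(
            g, min_size, max_size, chordless=chordless, frame_index=frame_index
        )
    }
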