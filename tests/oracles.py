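"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the library's own code paths: scalar arithmetic
with ``math``, exhaustive double loops, and subset enumeration.
"""

import itertools
import math


def pair_energy_oracle(a, b, A, C, q_O, q_H, k_e):
    """Ten-term scalar evaluation of the water-water pair potential."""
    sites_a = [(tuple(a.o_pos), q_O), (tuple(a.h1_pos), q_H), (tuple(a.h2_pos), q_H)]
    sites_b = [(tuple(b.o_pos), q_O), (tuple(b.h1_pos), q_H), (tuple(b.h2_pos), q_H)]
    total = 0.0
    for (pa, qa) in sites_a:
        for (pb, qb) in sites_b:
            r = math.dist(pa, pb)
            total += k_e * qa * qb / r
    r_oo = math.dist(tuple(a.o_pos), tuple(b.o_pos))
    total += A / r_oo**12 - C / r_oo**6
    return total


def hbond_edges_oracle(waters, p):
    """All-pairs double loop: edges where the scalar oracle energy <= cutoff."""
    edges = set()
    for a, b in itertools.combinations(waters, 2):
        e = pair_energy_oracle(a, b, p.A, p.C, p.q_O, p.q_H, p.k_e)
        if e <= p.e_hbond:
            edges.add(frozenset((a.water_id, b.water_id)))
    return edges


def _canonical(members):
    members = list(members)
    k = members.index(min(members))
    rot = members[k:] + members[:k]
    if rot[1] > rot[-1]:
        rot = [rot[0]] + rot[:0:-1]
    return tuple(rot)


def rings_oracle(nodes, edges, min_size=3, max_size=6):
    """Every node subset of size min..max whose induced subgraph has a
    Hamiltonian cycle, reported as the canonical cycle tuples."""
    edges = {frozenset(e) for e in edges}
    found = set()
    nodes = sorted(nodes)
    for size in range(min_size, max_size + 1):
        for subset in itertools.combinations(nodes, size):
            first, rest = subset[0], subset[1:]
            for perm in itertools.permutations(rest):
                cyc = (first,) + perm
                if all(
                    frozenset((cyc[i], cyc[(i + 1) % size])) in edges
                    for i in range(size)
                ):
                    found.add(_canonical(cyc))
    return found


def com_oracle(waters, m_O=15.999, m_H=1.008):
    """Flat weighted mean over the 3N atoms of the given waters."""
    sx = sy = sz = sm = 0.0
    for w in waters:
        for pos, m in ((w.o_pos, m_O), (w.h1_pos, m_H), (w.h2_pos, m_H)):
            sx += m * pos[0]
            sy += m * pos[1]
            sz += m * pos[2]
            sm += m
    return (sx / sm, sy / sm, sz / sm)
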