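# Methods

## The model

`twn` analyses the *topology* of binding-site hydration. Water molecules
in an explicit-solvent snapshot are treated as rigid three-site TIP3P
monomers, and a pair of waters is called hydrogen bonded when their
interaction energy

    v(a, b) = Σ_i Σ_j k_e q_i q_j / r_ij  +  A / r_oo^12  −  C / r_oo^6

falls at or below an energy criterion. The double sum runs over the nine
intermolecular charge-site pairs (O, H1, H2 on each water); the
Lennard-Jones term acts between the oxygens only. Intramolecular terms
are never computed: the monomer is rigid. Waters linked by hydrogen
bonds form a graph, and the cyclic networks of interest are the simple
cycles of length 3–6 of that graph ("water rings"). Each ring is
summarised by the mass-weighted centre of its 3 × size atoms
(m_O = 15.999, m_H = 1.008 Da).

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `A` | 582 000 | kcal Å¹² mol⁻¹ | LJ repulsion (O–O) |
| `C` | 595 | kcal Å⁶ mol⁻¹ | LJ attraction (O–O) |
| `q_O`, `q_H` | −0.834, +0.417 | e | TIP3P partial charges (neutral monomer enforced) |
| `k_e` | 332.0636 | kcal Å mol⁻¹ e⁻² | Coulomb conversion constant, CHARMM convention |
| `e_hbond` | −2.25 | kcal mol⁻¹ | hydrogen-bond energy criterion; the boundary counts as bonded (≤) |
| site cutoff | 20.0 | Å | water-extraction radius around the anchor centroid |
| selection / match radius | 2.0 | Å | network-selection and shape-matching radius |

The criterion value −2.25 kcal/mol corresponds to the minimum of the
pair-energy distribution of liquid TIP3P water; with the defaults, a
canonical linear dimer at r_OO = 2.75 Å scores about −6.2 kcal/mol, and
the charge-free limit reduces to a pure LJ potential with minimum at
r* = (2A/C)^(1/6) ≈ 3.55 Å and depth −C²/(4A) ≈ −0.152 kcal/mol — both
used as closed-form checks in the test suite.

## Numerical and algorithmic choices

**Pair energies** are evaluated in batch (vectorised over candidate
pairs). Coincident interaction sites raise a degenerate-geometry error;
there is no distance cutoff on the energy itself. A neighbour-list
pre-screen at 6 Å O–O accelerates graph construction; at that separation
no orientation of two TIP3P waters comes near −2.25 kcal/mol, and
result-identity with the all-pairs scan is asserted in the test suite.

**Cycle enumeration** uses a bounded depth-first search that roots each
cycle at its smallest node and only emits the traversal direction whose
second node is smaller than its last, so every cycle of length 3–6
appears exactly once. The canonical form (smallest id first, running
toward the smaller neighbour) makes ring sets well defined under
rotation and reflection. Correctness is checked against an exhaustive
subset oracle (every node subset of size 3–6 tested for a Hamiltonian
cycle) on hundreds of random graphs, and against networkx's bounded
`simple_cycles` as an independent library cross-check. Cycles with
chords count by default — the definition is "cyclic network", not
"induced cycle" — and a `chordless` flag restricts enumeration for
sensitivity analysis.

**Region assignment** is sphere-union membership with an inclusive
boundary; overlaps resolve to the region with the closest containing
sphere centre, then declaration order. Propensity percentages are
normalised over assigned rings only (unassigned rings are reported
separately), so the per-region values always sum to 100 when anything is
assigned, and are NaN with a warning otherwise.

**Shape similarity** is a heavy-atom coverage fraction: the percentage
of ligand heavy atoms with at least one ring centre of mass within the
match radius (2 Å, the same radius used to select networks near the
ligand). This is the simplest geometric overlap consistent with a 2 Å
proximity criterion; the published analyses of this kind used
unpublished in-house code, so the scorer is deliberately pluggable —
the result object records the radius and counts needed to compare
variants. Centres of mass are pooled across all frames before scoring.

**Site extraction** measures plain Euclidean distance from the anchor
centroid (all atoms of the anchor residues, or CA-only), recomputed per
frame by default, on the assumption that frames are solute-centred and
wrapped — standard trajectory post-processing. An orthorhombic
minimum-image option exists for raw boxes. Periodic images never
contribute to pair energies: the 20 Å site sphere is small relative to a
solvated simulation box.

**Residue similarity** is a positionwise percentage over equal-length
strings with no alignment; two residues match when identical or in the
same similarity group. The default grouping —
{AVILM}, {FYW}, {KRH}, {DE}, {NQ}, {ST}, {C}, {G}, {P} — is a standard
physicochemical partition and is configurable, since published values of
this kind rarely state their grouping.

**Drug-likeness** uses the original rule-of-five definitions: donors =
O–H plus N–H count, acceptors = N plus O count, all four rules strict
(`MW < 500`, `HBD < 5`, `HBA < 10`, `logP < 5`). logP is an input field,
never recomputed: published screens used proprietary AlogP/ClogP
predictors and silently substituting a different estimator would change
results. Molecular weights come from an embedded IUPAC 2021 abridged
standard-atomic-weight table.

## The synthetic-data generator

`twn.synthetic_data` emulates the one thing the pipeline needs from an
MD trajectory: frames containing hydrogen-bonded cyclic rings of known
size and position among uncorrelated waters. Ring oxygens sit on a
circle with adjacent O–O spacing 2.75 Å (a typical hydrogen-bond
distance); each water donates one hydrogen along the O–O vector to the
next member. The free hydrogen's azimuth about the donor axis is set per
ring size (size 3: all in-plane; 4 and 6: alternating above/below the
ring plane; 5: one in-plane member breaking the frustrated alternation)
— patterns chosen so that every ring edge clears the −2.25 kcal/mol
criterion by at least ~1.1 kcal/mol while every non-edge pair stays
above it. Noise waters are rejection-sampled uniformly in a cubic box
(default 40 Å) with a 6 Å minimum O–O separation from everything, which
makes accidental hydrogen bonds geometrically impossible.

Generation is self-verifying: after building a frame (and after any
jitter), all pairs are re-evaluated and the frame is rejected with an
error unless hydrogen bonds exist exactly on planted ring edges. The
same integer seed reproduces a frame bit-identically. Trajectory
jitter is a per-water rigid translation; 0.02 Å comfortably preserves
the planted topology given the ~1 kcal/mol energy margins, and larger
values fail validation loudly rather than producing bad fixtures.

What the generator does **not** emulate: liquid-water density and
structure (noise waters are far sparser than bulk water), thermal
orientation disorder, protein atoms beyond optional anchor pseudo-atoms,
ring–ring contacts, and rings transiently forming and breaking. Passing
tests therefore demonstrate that detection, counting, assignment and
scoring are correct on known ground truth — not that any particular
protein will show a given ring propensity.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic
inputs at small scale: 100 random graphs of ≤ 12 nodes for cycle
enumeration, 50 generated frames (four rings, sizes 3–6, plus 30 noise
waters each) for recovery, and 10-frame planted trajectories for
propensity arithmetic. These sizes fully exercise every code path while
keeping the whole suite under a minute of compute.

## Known limitations

- Published per-region propensities for real kinases (and the
  D-site ≈ 36%-style numbers) depend on nanosecond-scale MD sampling,
  specific structures, and pictorially-defined region geometry; they are
  not reproducible from this package alone. Given user-supplied
  trajectories and region definitions, `twn analyze` computes the same
  tables, and the expectation is agreement within MD sampling error.
- The shape-similarity formula is this package's own (documented above);
  published values produced with in-house code and commercial docking
  poses are not comparable number-for-number.
- Only orthorhombic boxes are supported for minimum-image distances;
  binary trajectory formats (XTC/DCD) are out of scope for the core
  reader contract.
- Rings larger than six members, polyhedral water cages, and the
  persistence of a ring across frames are not modelled.
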