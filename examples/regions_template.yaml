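# Template region set for a generic kinase ATP site.
#
# This is a RECONSTRUCTION to be adapted per structure, not a published
# definition: sphere centres are anchored on the usual ATP-site landmarks
# (replace the resid values with the ones from your own numbering, e.g.
# for IRAK4 the gatekeeper is Tyr262, the hinge is Met265 and the
# catalytic lysine is Lys213).  Radii of 5-6 A give largely disjoint
# regions for a typical pocket; check overlaps visually before use.
regions:
  - name: A            # adenine / hinge pocket
    spheres:
      - selector: {resname: MET, resid: 265, name: CA}
        radius: 6.0
  - name: B            # back pocket behind the gatekeeper
    spheres:
      - selector: {resname: TYR, resid: 262, name: CA}
        radius: 5.0
  - name: C            # ribose groove
    spheres:
      - selector: {resname: ASP, resid: 272, name: CA}
        radius: 5.0
  - name: D            # solvent-exposed front at the hinge exit
    spheres:
      - selector: {resname: MET, resid: 265, name: O}
        radius: 6.0
  - name: E            # catalytic / DFG area
    spheres:
      - selector: {resname: LYS, resid: 213, name: CA}
        radius: 5.0
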