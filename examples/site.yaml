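# Binding-site water extraction: waters within 20 A of the DFG motif
# centroid.  Replace the resid values with your structure's numbering.
site:
  anchor:
    resname: [ASP, PHE, GLY]
    resid: [329, 330, 331]
  cutoff: 20.0
  ca_only: false
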