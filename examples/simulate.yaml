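# Synthetic frame spec for `twn simulate`: two planted rings plus noise
# waters, with a pseudo DFG anchor at the origin for site extraction.
rings:
  - size: 4
    center: [0.0, 0.0, 0.0]
  - size: 6
    center: [14.0, 0.0, 0.0]
noise:
  n_waters: 10
  box: 36.0
  min_separation: 6.0
dfg_anchor: [0.0, 0.0, 0.0]
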