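# Receptor-ligation scenarios over the four input ligands.
#   A: CAR ligation only (tumor antigen)
#   B: CAR ligation + IL2
#   C: CAR + IL2 + both inhibitory ligands (PDL1/PDL2 and CD80/CD86)
#   D: as C with PDL1/PDL2 blocked
#   E: as C with CD80/CD86 blocked
defaults:
  replicates: 10000
  horizon: 100
  steady_window: 20
scenarios:
  A:
    active_inputs: [TAex]
  B:
    active_inputs: [TAex, IL2ex]
  C:
    active_inputs: [TAex, IL2ex, PDL1L2ex, CD8086ex]
  D:
    active_inputs: [TAex, IL2ex, CD8086ex]
  E:
    active_inputs: [TAex, IL2ex, PDL1L2ex]
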