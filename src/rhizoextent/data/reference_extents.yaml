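# Reference ranges of simulated rhizosphere extents (μm from the root
# surface) across the 12 core scenarios, used only by the `report` command
# for side-by-side comparison with a fresh run.
simulated_extent_ranges_um:
  Ca: {min: 700,  max: 9800}
  S:  {min: 110,  max: 5200}
  P:  {min: 40,   max: 2090}
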