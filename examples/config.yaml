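# Example run configuration for `ashcarbon run-all --config examples/config.yaml`.
# Omit `inputs` to run on a synthetic dataset instead (as here); set it to
# analyse real tables:
#
# inputs:
#   titrations: data/titrations.tsv
#   pools: data/pools.tsv
#   deltas: data/deltas.tsv

seed: 1
alpha: 0.05

end_members:
  delta_soc_b: -19.5     # permil, baseline C4 soil
  delta_straw: -27.5     # permil, wheat straw
  delta_ash: -26.4       # permil, wood ash
  straw_c_content: 456.1 # g C per kg straw
  ash_organic_c: 3.2     # g C per kg ash
  ash_sic: 432.0         # mg carbonate C per kg soil at the 12 g/kg dose

simulation:
  n_replicates: 3
  soil_mass: 0.25        # kg dry soil per jar
  true_fraction_new:
    Control: 0.0
    W: 0.0
    S: 0.25
    SW: 0.267
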