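# Small abstract-arbor gain sweep: two contrasting morphologies
# (multipolar moderately branched vs multipolar unbranched) at two
# irradiance levels.  Runs in a few minutes on one CPU.
name: abstract-gain-small
morphology:
  - [4, 2, 5]
  - [4, 1, 31]
irradiances: [0.0, 0.02]
seed: 1
n_seeds: 2
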