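# Synthetic demonstration run: two species x two limbs at the default scale
# (~3,000 cells, 5,000 genes, 200 TADs).  All stage parameters are the
# analysis defaults; override any block to experiment.
seed: 1
output_dir: patagium_demo
simulation: {}
parameters: {}
programme:
  distal_cluster: FbDist
  proximal_clusters: [FbProx]
  other_proximal_clusters: [FbProx]
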