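# Southern fulmar (Ile des Petrels) finite-mixture model configuration.
# Mixing distribution over latent heterogeneity groups at fledging.
groups: [UH-1, UH-2, UH-3]
pi: [0.14, 0.67, 0.19]
horizon: 100
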