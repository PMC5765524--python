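vital_rate,stage,UH-1,UH-2,UH-3
survival,PB,1.00,0.92,1.00
survival,S,0.93,0.99,0.89
survival,F,0.94,0.93,0.93
survival,NB,0.88,0.88,0.88
breeding,PB,0.10,0.01,0.16
breeding,S,0.96,0.80,0.97
breeding,F,0.81,0.80,0.80
breeding,NB,0.42,0.55,0.55
success,PB,0.81,0.69,1.00
success,S,0.80,0.85,0.99
success,F,0.65,0.64,0.66
success,NB,0.66,0.66,0.66
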