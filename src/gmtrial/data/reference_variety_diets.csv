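diet_id,substitution_pct,dry_matter,carbohydrates,proteins,lipids,is_commercial_control
MV1,15,94.0,38.1,34.5,5.9,False
MV2,15,93.9,32.2,43.8,2.9,False
MV3,15,93.9,37.2,24.4,4.2,False
MV4,15,93.8,30.6,30.6,4.7,False
MV5,15,93.9,36.9,37.0,4.8,False
MV6,15,93.9,35.9,32.6,5.8,False
MV7,15,93.9,38.1,21.8,6.1,False
MV8,15,93.8,28.0,26.9,5.1,False
MV9,15,93.8,61.6,28.5,6.6,False
MV10,15,93.9,33.2,29.6,4.2,False
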