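diet_id,substitution_pct,dry_matter,carbohydrates,proteins,lipids,is_commercial_control
CCD,0,93.0,46.4,33.4,3.7,True
sub0,0,90.0,32.1,30.4,5.0,False
sub5,5,90.4,34.7,34.8,5.5,False
sub10,10,90.4,31.3,34.4,4.0,False
sub15,15,90.8,31.5,36.8,5.8,False
sub20,20,90.8,29.5,34.9,5.0,False
sub25,25,90.6,27.5,33.9,6.1,False
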