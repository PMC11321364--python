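skin,wavelength_nm,sao2,acdc
light,660,70,0.4398
light,660,75,0.3845
light,660,80,0.3232
light,660,85,0.2785
light,660,90,0.2631
light,660,95,0.1610
light,660,100,0.1192
light,940,70,0.2748
light,940,75,0.2973
light,940,80,0.2949
light,940,85,0.3227
light,940,90,0.3220
light,940,95,0.3007
light,940,100,0.2967
moderate,660,70,0.3012
moderate,660,75,0.2328
moderate,660,80,0.1759
moderate,660,85,0.1524
moderate,660,90,0.2495
moderate,660,95,0.1383
moderate,660,100,0.0831
moderate,940,70,0.2340
moderate,940,75,0.2219
moderate,940,80,0.2240
moderate,940,85,0.2247
moderate,940,90,0.3618
moderate,940,95,0.2937
moderate,940,100,0.2543
dark,660,70,0.2114
dark,660,75,0.1758
dark,660,80,0.1607
dark,660,85,0.1316
dark,660,90,0.1085
dark,660,95,0.0811
dark,660,100,0.0586
dark,940,70,0.3051
dark,940,75,0.2305
dark,940,80,0.2258
dark,940,85,0.3015
dark,940,90,0.2425
dark,940,95,0.2296
dark,940,100,0.2585
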