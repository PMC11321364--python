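cohort,spo2,sao2_mean,sao2_low,sao2_high,bias_mean,bias_high,bias_low
white,89,88.5,78,99,0.5,11,-3
white,90,89,80,97.5,1,3,-7.5
white,91,91,83,98,0,8,-7
white,92,92,83.5,98.5,0,8.5,-6.5
white,93,93,85,98,0,8,-5
white,94,93.5,86,98,0.5,8,-4
white,95,94,87,98.5,1,8,-3.5
white,96,94.5,89,99,1.5,7,-3
black,89,86,83,92,3,6,-3
black,90,87,83,97,3,7,-7
black,91,87.5,80,97.5,3.5,11,-6.5
black,92,89,82.5,96,4,9.5,-4
black,93,90,84,97.5,3,7,-7
black,94,91.5,85,97,2.5,9,-3
black,95,92,85.5,97,3,9.5,-2
black,96,92,84,98,4,12,-2
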