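protocol,mode_or_ratio,strain_or_stretch_f,stretch_n,channel,stress_kPa
shear-fs,fs,0.0,1.0,sigma_fs,0.0
shear-fs,fs,0.125,1.0,sigma_fs,0.11611025328873104
shear-fs,fs,0.25,1.0,sigma_fs,0.5657713612478064
shear-fs,fs,0.375,1.0,sigma_fs,1.8324764186732603
shear-fs,fs,0.5,1.0,sigma_fs,6.0397324940251575
biaxial-1:1,1:1,1.0,1.0,sigma_ff,0.0
biaxial-1:1,1:1,1.0,1.0,sigma_nn,0.0
biaxial-1:1,1:1,1.025,1.025,sigma_ff,0.4064043996625822
biaxial-1:1,1:1,1.025,1.025,sigma_nn,0.3253871834102953
biaxial-1:1,1:1,1.05,1.05,sigma_ff,1.1501487141749194
biaxial-1:1,1:1,1.05,1.05,sigma_nn,0.851201455816424
biaxial-1:1,1:1,1.0750000000000002,1.0750000000000002,sigma_ff,2.684849311084566
biaxial-1:1,1:1,1.0750000000000002,1.0750000000000002,sigma_nn,1.7578815602876108
biaxial-1:1,1:1,1.1,1.1,sigma_ff,5.92739082127647
biaxial-1:1,1:1,1.1,1.1,sigma_nn,3.251002584412043
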