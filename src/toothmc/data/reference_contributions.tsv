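wavelength_nm	geometry	sds_mm	wdp_wsr	wdp_wosr	contrib_wsr_pct	contrib_wosr_pct
633	reflectance	0.25	2.67e3	1.10e3	0.196	0.0579
633	reflectance	0.75	1.09e4	2.19e3	0.273	0.0859
633	reflectance	1.5	3.07e4	6.63e3	0.515	0.188
633	transmittance	7.0	5.75e5	2.55e5	3.20	2.04
1310	reflectance	0.25	8.15e3	6.57e3	0.823	0.329
1310	reflectance	0.75	5.35e4	1.34e4	1.081	0.495
1310	reflectance	1.5	1.46e5	5.50e4	2.241	1.525
1310	transmittance	7.0	2.74e5	1.37e5	2.45	2.02
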