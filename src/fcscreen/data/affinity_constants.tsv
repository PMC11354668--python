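table	ligand_id	group	k_on_per_M_s	k_dis_per_s	k_d_reported_M	r_squared
1	5XRZ	dnafl	3.76e3	3.17e-3	8.43e-7	0.9402
1	6GN7	dnafl	9.52e3	2.29e-3	2.41e-7	0.9294
1	4GNX	dnafl	1.81e3	3.80e-3	2.10e-6	0.9622
1	7JSG	dnafl	3.11e3	3.48e-3	1.12e-6	0.9692
1	2C62	dnafl	1.85e3	6.00e-3	3.24e-6	0.9251
1	7XHD	dnafl	6.29e3	3.28e-3	5.21e-7	0.9229
1	6SKO	dnafl	4.26e3	4.54e-3	1.07e-6	0.9636
1	1RDE	dnafl	2.91e3	3.18e-3	1.09e-6	0.9661
1	2CCZ	dnafl	4.42e3	4.02e-3	9.09e-7	0.9614
1	6CRM	dnafl	5.14e3	5.70e-3	1.11e-6	0.9257
1	1PH1-D	dnafl	6.97e3	6.14e-3	8.81e-7	0.8856
1	1OTC	dnafl	8.24e3	3.41e-3	4.14e-7	0.9031
1	4JS5	dnafl	3.34e3	5.78e-3	1.73e-6	0.9447
1	3UGO	dnafl	5.38e3	4.27e-3	7.93e-7	0.8999
1	2A0I	dnafl	6.39e3	5.57e-3	8.72e-7	0.9134
1	2KN7	dnafl	5.06e3	6.08e-3	1.20e-6	0.94
1	4OU6	dnafl	5.06e3	4.79e-3	9.47e-7	0.9497
1	7JSI	dnafl	2.58e3	4.73e-3	1.83e-6	0.9672
1	5FGP	dnafl	2.74e3	4.13e-3	1.51e-6	0.9522
1	6S3M	dnafl	6.93e3	8.06e-3	1.16e-6	0.9262
1	SPA-IgG	control	4.80e4	7.16e-4	1.49e-8	0.959
2	poly-A10	polybase
2	poly-A15	polybase
2	poly-A20	polybase
2	poly-A25	polybase
2	poly-A30	polybase
2	poly-C10	polybase
2	poly-C15	polybase	4.27e3	5.81e-3	1.36e-6	0.9117
2	poly-C20	polybase	7.42e3	5.65e-3	7.61e-7	0.8997
2	poly-C25	polybase
2	poly-C30	polybase
2	poly-G10	polybase	6.87e3	2.02e-3	2.95e-7	0.9301
2	poly-G15	polybase	8.42e3	2.30e-3	2.73e-7	0.9676
2	poly-G20	polybase	7.85e3	2.45e-3	3.12e-7	0.9583
2	poly-G25	polybase	7.24e3	5.01e-3	6.92e-7	0.8785
2	poly-G30	polybase	4.39e3	2.45e-3	5.57e-7	0.8844
2	poly-T10	polybase	3.79e3	5.66e-3	1.49e-6	0.9438
2	poly-T15	polybase	4.42e3	4.02e-3	9.09e-7	0.9614
2	poly-T20	polybase	4.50e3	3.74e-3	8.30e-7	0.9628
2	poly-T25	polybase	4.18e3	4.20e-3	1.01e-6	0.9661
2	poly-T30	polybase	2.50e3	3.57e-3	1.43e-6	0.9448
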