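# Printed characterization of the genotyped introgression-line library in the
# Dianjingyou 1 background: per-donor IL counts, segment counts, mean
# segments per chromosome, segment length range/mean (Mb), and mean
# background recovery rate (%).
donor	n_ils	n_segments	segments_per_chromosome	length_min_mb	length_max_mb	length_mean_mb	background_recovery_pct
O_barthii	29	349	29.08	2.66	28.98	6.99	88.92
O_glumaepatula	30	210	17.50	0.66	25.60	5.35	91.94
O_meridionalis	76	434	36.17	0.27	23.77	5.83	93.21
O_nivara	380	3332	277.67	0.30	27.43	5.84	92.74
O_rufipogon	74	625	52.08	0.28	23.46	6.37	89.92
O_glaberrima	81	1138	94.83	0.27	24.17	5.80	85.14
upland_rice	731	9198	766.50	0.19	43.27	6.67	84.03
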