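# Printed per-chromosome marker description of the 168-SSR genotyping panel:
# marker counts, mean inter-marker interval (Mb), and per-donor marker
# polymorphism rates (%) against the recurrent parent Dianjingyou 1.
chromosome	n_markers	density_mb	O_barthii	O_glumaepatula	O_meridionalis	O_nivara	O_rufipogon	O_glaberrima	upland_rice
1	17	2.55	94.12	94.12	100.00	100.00	100.00	100.00	100.00
2	18	2.00	77.78	77.78	88.89	83.33	88.89	94.44	77.78
3	16	2.28	100.00	100.00	100.00	100.00	100.00	100.00	100.00
4	15	2.37	80.00	100.00	93.33	100.00	100.00	100.00	93.33
5	15	2.00	93.33	60.00	86.67	93.33	93.33	86.67	80.00
6	13	2.40	92.31	84.62	100.00	100.00	100.00	100.00	100.00
7	14	2.12	92.86	78.57	92.86	92.86	92.86	100.00	85.72
8	14	2.03	100.00	57.14	100.00	100.00	100.00	100.00	78.58
9	10	2.30	100.00	90.00	100.00	100.00	100.00	100.00	83.34
10	12	1.93	91.67	100.00	100.00	100.00	91.67	100.00	100.00
11	12	2.42	66.67	66.67	83.33	100.00	83.33	100.00	100.00
12	12	2.29	83.33	83.33	100.00	100.00	100.00	100.00	100.00
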