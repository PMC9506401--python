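host	fungal_rhizosphere	fungal_root	fungal_shoot	bacterial_rhizosphere	bacterial_root	bacterial_shoot
arabidopsis	0.05	0.18	0.08	0.17	0.36	0.50
barley	0.11	0.18	0.30	0.04	0.11	0.30
brachiaria	0.08	0.15	0.11	0.21	0.07	0.07
brachypodium	0.05	0.11	0.00	0.18	0.32	0.47
cassava	0.06	0.13	0.16	0.14	0.30	0.41
coffee	0.07	0.17	0.26	0.13	0.31	0.41
maize	0.09	0.40	0.32	0.12	0.08	0.05
panicum	0.06	0.07	0.19	0.28	0.33	0.11
pea	0.03	0.15	0.31	0.06	0.17	0.49
phaseolus	0.02	0.24	0.24	0.25	0.17	0.21
rice	0.34	0.50	0.12	0.10	0.25	0.17
sorghum	0.10	0.22	0.10	0.13	0.23	0.14
soy	0.01	0.51	0.48	0.10	0.16	0.11
sugarcane	0.18	0.33	0.31	0.23	0.39	0.17
sunflower	0.01	0.13	0.06	0.11	0.30	0.25
tomato	0.09	0.17	0.38	0.27	0.36	0.46
wheat	0.02	0.09	0.14	0.10	0.11	0.15
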