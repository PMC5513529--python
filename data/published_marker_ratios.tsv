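cell_type	gene	AD	MS	PD
microglia	ALOX5AP	0.79	0.70	1.15
microglia	C1QA	0.66	0.79	1.47
microglia	C1QB	0.75	0.81	1.20
microglia	C1QC	0.58	0.79	1.17
microglia	CD74	0.66	0.59	0.85
microglia	FCER1G	0.65	0.84	0.92
microglia	HSPA1A	0.63	1.19	1.04
microglia	ITGB2	0.64	0.69	0.87
microglia	SPP1	0.73	1.06	1.62
astrocyte	DTNA	0.13	0.92	0.56
astrocyte	GJA1	0.24	0.68	0.73
astrocyte	ID4	0.20	0.56	0.60
astrocyte	KCNN3	-0.02	0.57	0.70
astrocyte	MGST1	-0.02	0.88	0.51
astrocyte	MUC1	0.01	1.13	0.51
astrocyte	PALLD	0.14	0.59	0.95
astrocyte	PAX6	0.14	0.54	0.59
astrocyte	PDK4	0.30	0.83	1.13
astrocyte	SLC1A3	0.00	0.52	0.83
astrocyte	SLC7A2	0.33	0.81	0.54
astrocyte	SOX9	0.19	0.69	0.82
endothelia	AHNAK	0.24	0.59	0.85
endothelia	ANKRD37	0.10	0.50	0.82
endothelia	C10orf10	0.21	0.81	0.71
endothelia	HSPB1	0.44	0.86	1.11
endothelia	IFITM2	0.08	0.89	0.91
endothelia	IFITM3	0.11	0.90	1.14
endothelia	LRRC32	0.11	0.73	0.50
endothelia	PECAM1	0.16	0.57	0.98
endothelia	S100A11	0.32	0.59	0.90
endothelia	TGFBR3	0.23	0.55	0.69
endothelia	TIMP1	-0.09	0.90	0.77
endothelia	TM4SF1	0.14	0.78	1.12
endothelia	TPD52L1	0.29	0.63	1.14
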