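rule	CTBA	BrJAP	KIV	KRC	GND	GKW	ACHE	GRC
Bw4A-3DL1	0.09	0.17	0.02	0.01	0.05	0.01	0.02	0.00
Bw4B-3DL1	0.16	0.16	0.13	0.10	0.04	0.05	0.01	0.04
A3-3DL2	0.06	0.01	0.00	0.01	0.00	0.00	0.00	0.00
A11-3DL2	0.03	0.07	0.00	0.02	0.01	0.00	0.00	0.00
A11-2DS4	0.02	0.05	0.00	0.01	0.01	0.00	0.00	0.00
C2-2DL1	0.15	0.04	0.16	0.14	0.21	0.19	0.26	0.06
C1C2-2DL2	0.15	0.04	0.19	0.23	0.12	0.10	0.01	0.36
C1-2DL3	0.18	0.36	0.19	0.22	0.32	0.41	0.30	0.41
C2-2DS1	0.06	0.01	0.11	0.13	0.14	0.16	0.17	0.09
C16-2DS2	0.01	0.00	0.00	0.00	0.00	0.00	0.00	0.00
C2-2DS5	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00
Csub-2DS4	0.10	0.09	0.20	0.13	0.09	0.06	0.22	0.05
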