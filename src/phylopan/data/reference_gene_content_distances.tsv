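	MpV1	MpV-12T	MpV-PL1	MpV-SP1	BpV1	BpV2	OtV1	OtV2	OtV5	OtV6	OlV1	PBCV1	AR158
MpV1	0.00	0.98	0.64	0.66	1.11	1.08	0.63	0.72	0.69	0.57	0.68	4.99	5.40
MpV-12T	0.98	0.00	1.02	0.99	1.18	1.16	1.06	1.05	1.11	1.00	1.06	5.41	5.01
MpV-PL1	0.64	1.02	0.00	0.30	1.12	1.10	0.71	0.75	0.75	0.67	0.73	5.04	5.45
MpV-SP1	0.66	0.99	0.30	0.00	1.09	1.10	0.70	0.75	0.77	0.69	0.71	4.99	5.40
BpV1	1.11	1.18	1.12	1.09	0.00	0.24	1.07	1.16	1.17	1.15	1.13	4.89	4.90
BpV2	1.08	1.16	1.10	1.10	0.24	0.00	1.05	1.17	1.13	1.11	1.13	4.91	4.92
OtV1	0.63	1.06	0.71	0.70	1.07	1.05	0.00	0.29	0.25	0.42	0.24	5.36	5.37
OtV2	0.72	1.05	0.75	0.75	1.16	1.17	0.29	0.00	0.33	0.48	0.22	6.07	6.08
OtV5	0.69	1.11	0.75	0.77	1.17	1.13	0.25	0.33	0.00	0.46	0.28	5.42	5.43
OtV6	0.57	1.00	0.67	0.69	1.15	1.11	0.42	0.48	0.46	0.00	0.45	5.40	5.41
OlV1	0.68	1.06	0.73	0.71	1.13	1.13	0.24	0.22	0.28	0.45	0.00	6.09	6.10
PBCV1	4.99	5.41	5.04	4.99	4.89	4.91	5.36	6.07	5.42	5.40	6.09	0.00	0.81
AR158	5.40	5.01	5.45	5.40	4.90	4.92	5.37	6.08	5.43	5.41	6.10	0.81	0.00
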