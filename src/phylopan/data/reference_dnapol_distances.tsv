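	MpV1	MpV-12T	MpV-PL1	MpV-SP1	BpV1	BpV2	OtV1	OtV2	OtV5	OtV6	OlV1	PBCV1	AR158
MpV1	0.00	0.36	0.26	0.23	0.38	0.39	0.27	0.26	0.27	0.26	0.28	2.09	2.15
MpV-12T	0.36	0.00	0.36	0.36	0.42	0.42	0.33	0.33	0.33	0.35	0.35	2.15	2.18
MpV-PL1	0.26	0.36	0.00	0.18	0.38	0.38	0.24	0.23	0.25	0.25	0.25	2.19	2.23
MpV-SP1	0.23	0.36	0.18	0.00	0.39	0.39	0.25	0.24	0.25	0.24	0.24	2.05	2.10
BpV1	0.38	0.42	0.38	0.39	0.00	0.05	0.37	0.41	0.37	0.38	0.39	2.03	2.07
BpV2	0.39	0.42	0.38	0.39	0.05	0.00	0.38	0.41	0.38	0.38	0.40	2.05	2.08
OtV1	0.27	0.33	0.24	0.25	0.37	0.38	0.00	0.05	0.01	0.09	0.08	2.21	2.27
OtV2	0.26	0.33	0.23	0.24	0.41	0.41	0.05	0.00	0.06	0.10	0.08	2.21	2.27
OtV5	0.27	0.33	0.25	0.25	0.37	0.38	0.01	0.06	0.00	0.09	0.08	2.22	2.30
OtV6	0.26	0.35	0.25	0.24	0.38	0.38	0.09	0.10	0.09	0.00	0.09	2.13	2.22
OlV1	0.28	0.35	0.25	0.24	0.39	0.40	0.08	0.08	0.08	0.09	0.00	2.16	2.25
PBCV1	2.09	2.15	2.19	2.05	2.03	2.05	2.21	2.21	2.22	2.13	2.16	0.00	0.12
AR158	2.15	2.18	2.23	2.10	2.07	2.08	2.27	2.27	2.30	2.22	2.25	0.12	0.00
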