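genome	n_cds
MpV1	244
MpV-12T	252
MpV-PL1	271
MpV-SP1	244
BpV1	202
BpV2	209
OtV1	230
OtV2	235
OtV5	260
OtV6	249
OlV1	246
PBCV1	789
AR158	806
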