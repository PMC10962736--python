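# synthetic three-study human fold-change table (linear scale; NA = gene not profiled)
human_gene	study1	study2	study3
PHGDH	4.22	2.63	3.42
PSAT1	2.62	2.41	2.47
PYCR1	2.72	3.26	3.55
ASNS	3.03	3.36	4.2
PCK2	4.16	2.65	3.6
MTHFD2	2.74	3.63	3.48
CHAC1	2.77	2.3	4.21
TRIB3	4.22	4.02	2.31
ATF5	3.24	3.1	2.45
FGF21	2.6	2.4	NA
CTH	2.0	2.0	2.0
ORTH12	3.0	2.0	0.9
ORTH13	1.8	1.6	NA
ORTH14	1.27	0.81	1.68
ORTH15	0.82	1.16	1.14
ORTH16	1.32	1.25	0.87
ORTH17	1.41	1.07	0.7
ORTH18	1.54	0.66	1.17
ORTH19	1.21	1.16	1.53
ORTH20	0.74	1.49	1.57
ORTH21	1.16	1.37	1.29
ORTH22	0.86	1.61	1.1
ORTH23	0.94	1.21	1.69
ORTH24	1.74	1.6	1.57
ORTH25	1.01	1.11	1.21
ORTH26	1.49	0.94	1.1
ORTH27	1.12	1.8	1.12
ORTH28	0.77	1.32	1.14
ORTH29	1.13	0.85	1.15
ORTH30	1.3	1.58	1.15
ORTH31	0.96	1.2	1.8
ORTH32	1.39	1.43	1.84
ORTH33	0.74	1.58	1.34
ORTH34	1.77	1.9	1.36
ORTH35	1.46	0.76	1.51
ORTH36	1.78	1.82	1.47
ORTH37	1.74	0.73	1.0
ORTH38	1.28	1.09	0.61
ORTH39	1.44	0.64	1.49
ORTH40	1.37	0.77	1.41
ORTH41	1.54	1.29	1.61
ORTH42	0.64	1.75	0.95
ORTH43	1.54	0.71	1.67
ORTH44	1.19	0.89	1.27
ORTH45	0.76	0.71	0.85
ORTH46	1.48	1.85	1.7
ORTH47	1.74	0.96	0.9
ORTH48	1.63	1.44	0.84
ORTH49	1.39	1.78	0.65
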