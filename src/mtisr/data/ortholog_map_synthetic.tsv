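# synthetic ortholog map: heart core-signature mouse gene ids -> human symbols
# g0050/g0051 intentionally unmapped
mouse_gene	human_gene
g0001	PHGDH
g0002	PSAT1
g0003	PYCR1
g0004	ASNS
g0005	PCK2
g0006	MTHFD2
g0007	CHAC1
g0008	TRIB3
g0009	ATF5
g0010	FGF21
g0011	CTH
g0012	ORTH12
g0013	ORTH13
g0014	ORTH14
g0015	ORTH15
g0016	ORTH16
g0017	ORTH17
g0018	ORTH18
g0019	ORTH19
g0020	ORTH20
g0021	ORTH21
g0022	ORTH22
g0023	ORTH23
g0024	ORTH24
g0025	ORTH25
g0026	ORTH26
g0027	ORTH27
g0028	ORTH28
g0029	ORTH29
g0030	ORTH30
g0031	ORTH31
g0032	ORTH32
g0033	ORTH33
g0034	ORTH34
g0035	ORTH35
g0036	ORTH36
g0037	ORTH37
g0038	ORTH38
g0039	ORTH39
g0040	ORTH40
g0041	ORTH41
g0042	ORTH42
g0043	ORTH43
g0044	ORTH44
g0045	ORTH45
g0046	ORTH46
g0047	ORTH47
g0048	ORTH48
g0049	ORTH49
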