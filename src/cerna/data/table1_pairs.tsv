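mRNA	lncRNA	correlation
OAS1	KTN1-AS1	0.789029469
JAK2	KTN1-AS1	0.752564718
BPIFB1	KTN1-AS1	0.858522985
RHOA	TMEM72-AS1	0.758943191
NGF	TMEM72-AS1	0.773519315
IL33	TMEM72-AS1	0.783806615
COLEC12	TMEM72-AS1	0.761881119
PPP4C	LINC00092	0.75444876
TG	C4B-AS1	0.835504137
GZMB	C4B-AS1	0.791438674
NGF	C4B-AS1	0.763980651
IL33	C4B-AS1	0.786158581
COLEC12	C4B-AS1	0.792932936
UBR1	C4B-AS1	0.798578035
XCR1	C4B-AS1	0.767467957
BRAF	HHATL-AS1	0.855393248
JAK2	ZNF503-AS2	0.899336755
NPR3	ZNF503-AS2	0.831443126
BRAF	ZNF503-AS2	0.871300503
NGF	PLCXD2-AS1	0.77646062
COLEC12	PLCXD2-AS1	0.799703687
CD8B	PLCXD2-AS1	0.761688487
BPIFC	MIR210HG	0.799484632
FYN	AC091078.1	0.780037819
TG	AC091078.1	0.833008855
XCR1	AC091078.1	0.766529515
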