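name	pattern	rank	hc_group	phospho
m1	GEDKFSQ	1		False
hc1	DYSERNDEFVE	2	HC1	False
rptA	TPRXS[SN]	3		True
rptB	KFDEGA	4		False
rptC	SMELYP	5		False
hc2	SNAWDKLGREQM	6	HC2	False
m7	PKNSDAG	7		False
hc3	WFSPASSENRLY	8	HC3	False
m9	QNFAGED	9		False
hc4	YTPANPDEFSSV	10	HC4	False
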