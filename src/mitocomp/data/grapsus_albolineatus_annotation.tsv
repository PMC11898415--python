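# taxon=Grapsus albolineatus
# accession=MF198247
# molecule_length=15580
Gene	Direction	Location	Size	IntergenicNt	StartCodon	StopCodon
cox1	F	1–1534	1534		ATG	T
trnL2	F	1535–1599	65
cox2	F	1610–2297	688		ATG	T
trnK	F	2298–2366	69
trnD	F	2367–2430	64
atp8	F	2431–2589	159		GTG	TAA
atp6	F	2583–3257	675	−7	ATT	TAA
cox3	F	3257–4048	792	−1	ATG	TAA
trnG	F	4048–4110	63	−1
nad3	F	4111–4461	351		ATC	TAA
trnA	F	4460–4523	64	−2
trnR	F	4530–4593	64
trnN	F	4595–4659	65
trnS1	F	4664–4730	67
trnE	F	4733–4800	68
trnH	R	4804–4868	65
trnF	R	4873–4937	65
nad5	R	4990–6720	1731		ATG	TAA
nad4	R	6765–8102	1338		ATG	TAG
nad4L	R	8096–8398	303	−7	ATG	TAA
trnT	F	8413–8478	66
trnP	R	8479–8545	67
nad6	F	8548–9051	504		ATT	TAA
cytb	F	9051–10,185	1135	−1	ATG	T
trnS2	F	10,186–10,253	68
nad1	R	10,281–11,246	966		ATT	TAA
trnL1	R	11,252–11,318	67
rrnL	R	11,319–12,646	1328
trnV	R	12,647–12,719	73
rrnS	R	12,720–13,546	827
CR	-	13,547–14,762	616
trnI	F	14,164–14,229	67
trnQ	R	14,227–14,297	71
trnM	F	14,305–14,375	71
nad2	F	14,376–15,386	1011		ATG	TAG
trnW	F	15,385–15,453	69	−2
trnC	R	15,453–15,516	64	−1
trnY	R	15,517–15,680	64
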