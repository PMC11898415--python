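Species	Size(bp)	A	T	C	G	A+T	AT skew	GC skew
G. albolineatus	15580	33.4	34	20.5	12.1	67.4	−0.01	−0.26
C. jpacificus	15341	34.6	37	17.2	11.1	71.6	−0.033	−0.215
S. serrata	15721	33.4	35.8	19.5	11.3	69.2	−0.034	−0.266
S. paramamosain	15824	34.9	38.2	16.8	10.2	73.1	−0.045	−0.247
A. alayseae	15611	34.5	32.4	21.9	11.3	66.9	0.032	−0.321
U. orientalis	15466	33.1	34.9	20.2	11.8	68	−0.027	−0.262
E. sinensis	16350	35.3	36.4	17.6	10.7	71.7	−0.015	−0.245
G. puia	15548	35.1	34.8	19.8	10.3	69.9	0.006	−0.313
M. crispata	16592	33.6	36.7	18.6	11.1	70.3	−0.044	−0.25
M. squinado	16598	33.7	37.1	18.2	11	70.8	−0.047	−0.245
X. ngatama	16106	36.1	36.8	17.5	9.6	72.9	−0.01	−0.293
A. lunaris	15807	34.8	35.4	18.7	11.1	70.2	−0.009	−0.256
M. longicarpus	15548	32.4	36.6	19.2	11.8	69	−0.06	−0.236
M. longipes	16424	37.5	34.2	18	10.4	71.7	0.046	−0.266
C. bimaculata	15712	33.9	37.6	16.9	11.5	71.5	−0.052	−0.192
T. thungwa	16156	37.2	36	9.1	17.6	73.2	0.017	0.318
P. trituberculatus	16026	33.3	36.9	18.5	11.3	70.2	−0.051	−0.241
C. sapidus	16263	34.2	34.9	19.8	11.1	69.1	−0.011	−0.279
P. gigas	15515	35	35.5	18.7	10.8	70.5	−0.006	−0.268
S. serrata NC	15775	34.6	38	17.1	10.4	72.6	−0.047	−0.242
S. tranquebarica	15833	35	38.7	16.5	9.7	73.7	−0.05	−0.258
S. olivacea	15723	33.5	35.9	19.4	11.2	69.4	−0.035	−0.267
C. japonica	15738	33.8	35.4	18.9	11.9	69.2	−0.024	−0.228
X. testudinatus	15798	36.7	37.2	16.8	9.3	73.9	−0.007	−0.286
G. yunohana	15567	34.3	35.7	19.3	10.8	70	−0.019	−0.281
A. distinguendus	15700	32.3	27.9	25.5	14.4	60.2	0.073	−0.278
A. rodriguezensis	15611	35.3	33.5	20.9	10.3	68.8	0.025	−0.341
P. crassipes	15652	30.5	35.8	21	12.7	66.3	−0.08	−0.245
R. ranina	15557	30.3	36.3	21.1	12.2	66.6	−0.09	−0.266
T. crenata	15787	34.4	35.3	18.8	11.5	69.7	−0.013	−0.24
C. feriata	15660	34.1	36.1	18.6	11.3	70.2	−0.028	−0.246
H. malayensis	15793	37.3	34.4	18.3	10	71.7	0.04	−0.292
P. pelagicus	16157	33.7	35	19.1	12.2	68.7	−0.019	−0.219
M. gladiator	15878	33.3	35.7	19.2	11.8	69	−0.034	−0.242
N. minutum	15637	38	39.7	13.4	8.9	77.7	−0.022	−0.201
C. haematocheir	15899	37.3	38.3	15	9.4	75.6	−0.013	−0.226
E. anaglyptus	16435	33.2	34.8	21	11.1	68	−0.023	−0.309
A. lactea	15659	34.8	34.6	18.5	12	69.4	0.003	−0.214
P. subquadrata	16898	34.2	33.5	21.7	10.5	67.7	0.01	−0.347
O. punctatus	16084	32.6	35.5	19.4	12.5	68.1	−0.042	−0.218
L. depressum	16537	35.4	37.9	17.3	9.3	73.3	−0.034	−0.302
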