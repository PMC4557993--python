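accession	species	existing_symbol	proposed_symbol
P02784	Bos taurus	BSP1	BSP1
L8HVY1	Bos mutus	M91_09268	BSP3
L8HUS6	Bos mutus	M91_09267	BSP5
P04557	Bos taurus	BSP3	BSP3a
UPI00004F4791	Bos taurus		BSP3b
P81019	Bos taurus	BSP5	BSP5
I6VPN8	Bubalus bubalis	SPA3	BSP3
F7DHB2	Equus caballus	LOC100629397	BSP1
Q70GG6	Equus caballus	sp1/BSP1	BSP1
UPI000179695D	Equus caballus		BSP1
Q70GG5	Equus caballus	spneu	BSP2a
F6XU34	Equus caballus	BSP2	BSP2b
G1P9I0	Myotis lucifugus		BSP1
G1U8W1	Oryctolagus cuniculus		BSP1a
G1U2M8	Oryctolagus cuniculus	BSP1	BSP1b
B7VBV2	Ovis aries	RSVP14/BSP1	BSP1
UPI00029D7739	Ovis aries		BSP3
W5PFH1	Ovis aries	BSP5	BSP5a
A4GZY3	Ovis aries	RSVP20	BSP5b
B7VBV3	Ovis aries	RSVP22	BSP5c
P80964	Sus scrofa	BSP1	BSP1
G1M9H5	Ailuropoda melanoleuca	BSPH1	BSPH1a
UPI0001DEA849	Ailuropoda melanoleuca		BSPH1b
L8IJD4	Bos mutus	M91_16052	BSPH1
F7GBI3	Callithrix jacchus	BSPH1	BSPH1
UPI0003AD8E0C	Canis familiaris		BSPH1
F7BI87	Equus caballus	BSPH1	BSPH1
M3WP82	Felis catus	BSPH1	BSPH1
G3SG51	Gorilla gorilla	101138349	BSPH1a
G3QCV5	Gorilla gorilla	101138349	BSPH1b
Q075Z2	Homo sapiens	BSPH1	BSPH1
G3TLL8	Loxodonta africana	BSPH1	BSPH1
UPI0003ABC7FF	Macaca fascicularis		BSPH1
B7ZWD1	Mus musculus	BSPH1	BSPH1a
Q3UW26	Mus musculus	BSPH1	BSPH1b
L5LGP2	Myotis davidii	MDA_GLEAN10005915	BSPH1
G1QB61	Myotis lucifugus		BSPH1
G1Q9H4	Myotis lucifugus		BSPH1
G1QKU7	Nomascus leucogenys	BSPH1	BSPH1
G1U2S1	Oryctolagus cuniculus	BSPH1	BSPH1a
UPI0001CE17C1	Oryctolagus cuniculus		BSPH1b
UPI00029D6F22	Ovis aries		BSPH1
H2QGQ3	Pan troglodytes	BSPH1	BSPH1
gi_545831688	Sus scrofa	BSPH1	BSPH1
F1MJB9	Bos taurus	BSPH2	BSPH2
T0MF66	Camelus ferus	CB1_000516002	BSPH2
J9P5U4	Canis familiaris		BSPH2
G3IE86	Cricetulus griseus	I79_022030	BSPH2
F6SEG3	Equus caballus		BSPH2
G5B896	Heterocephalus glaber	GW7_05342	BSPH2
G3TTN3	Loxodonta africana		BSPH2
Q0Q236	Mus musculus	BSPH2	BSPH2
M3XZ70	Mustela putorius furo	BSPH1	BSPH2
S7NFA6	Myotis brandtii	D623_10017573	BSPH2
G1SP69	Oryctolagus cuniculus	LOC100341751	BSPH2
UPI00048D144F	Oryctolagus cuniculus		BSPH2
H0Y1M6	Otolemur garnettii	BSPH1	BSPH2
UPI00029D5E35	Ovis aries		BSPH2
M0RAM1	Rattus norvegicus	BSPH2	BSPH2
G3VIB3	Sarcophilus harrisii	BSPH1	BSPH2
I3N753	Spermophilus tridecemlineatus	BSPH1	BSPH2
gi_545831705	Sus scrofa	BSP-30 kDa like	BSPH2
UPI0003C8CD4E	Tupaia chinensis		BSPH2
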