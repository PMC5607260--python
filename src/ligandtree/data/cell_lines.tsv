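cell_line	kras_mutation	pik3ca_mutation	egfr_thousand_per_cell	her2_thousand_per_cell	erbb3_thousand_per_cell	met_thousand_per_cell
CCK-81	wt	C420R, C472Y	18.2	1325.4	28.1	19.9
GP2D	G12D	H1047L	4.2	2359.7	35.0	3.0
H508	wt	E545K	185.1	63.4	20.1	42.0
H747	G13D	wt	193.1	2281.8	21.6	57.0
HCT116	G13D	H1047R	118.2	121.0	21.2	58.1
HCT15	G13D	E545K, D549N	290.1	382.8	23.4	40.3
HT115	wt	p.R88Q, p.E321D	381.3	44.9	9.3	49.0
KM12	wt	wt	180.3	1852.1	29.2	15.5
LOVO	G13D	wt	23.9	105.7	33.8	3.8
LS123	G12S	wt	23.5	121.2	31.8	11.5
LS180	G12D	H1047R	5.3	2364.7	39.5	3.2
MDST8	wt	wt	47.7	69.7	32.9	34.1
OUMS23	wt	wt	149.2	117.2	32.1	34.3
RCM-1	G12V	wt	98.7	139.9	31.4	41.4
RKO	wt	H1047R	632.2	84.5	21.3	68.9
SW48	wt	G914R	174.5	46.4	16.5	67.7
SW620	G12V	wt	97.3	88.9	23.1	29.4
T84	G13D	E542K	117.8	99.7	32.5	36.6
OVCAR-8	wt	wt	61.0	47.8	28.7	34.1
MKN-45	wt	wt	121.6	66.3	30.3	51.1
SNU-5	wt	wt	213.2	55.9	22.6	57.1
H441	G12V	wt	96.8	93.5	28.6	43.4
HCC827	wt	wt	409.4	58.8	7.0	43.4
A549	G12S	wt	102.7	57.3	25.4	19.8
H322M	wt	wt	96.8	82.3	29.0	49.1
H358	G12C	wt	21.2	44.1	11.7	18.8
ZR-75-1	wt	wt	543.0	70.0	20.6	24.8
MDA-MB-231	G13D	wt	4.4	34.3	26.4	36.7
BT-474	wt	K111N	149.4	55.1	29.6	63.4
HCC1419	wt	wt	80.1	95.0	23.1	26.7
HCC1937	wt	wt	5.2	57.0	8.5	18.0
HCC1954	wt	H1047R	182.2	33.6	6.7	395.2
HCC38	wt	wt	188.3	78.6	20.2	76.1
JIMT-1	wt	wt	270.8	1287.4	21.3	56.1
SK-BR-3	wt	wt	167.7	65.6	26.4	302.2
T47D	wt	H1047R	228.5	2393.0	24.2	25.2
ZR-75-30	wt	wt	116.5	3263.7	32.1	35.5
AGS	G12D	E453K	287.6	479.3	23.1	246.8
HGC27	wt	wt	138.4	74.1	30.0	34.0
Hs746T	wt	wt	374.0	69.0	18.4	297.7
KATO III	wt	wt	366.9	42.1	11.1	73.2
KYSE-410	wt	wt	84.0	13.8	9.5	21.4
N87	wt	wt	20.7	2060.9	22.5	38.2
OE19	wt	wt	662.5	34.4	21.0	87.5
OE33	wt	wt	140.6	24.5	8.3	49.7
SNU-16	wt	wt	305.0	69.5	18.0	41.9
H1915	wt	wt	98.6	53.7	18.2	55.0
H2170	wt	wt	165.4	92.7	27.7	158.3
H226	wt	wt	71.3	36.5	7.3	30.6
H23	G12C	wt	5.8	11.4	9.9	16.2
H460	Q61H	E545K	634.6	28.6	10.6	53.8
H520	wt	wt	5501.4	55.1	19.3	82.3
H596	wt	E545K	276.8	40.7	21.0	58.5
CaOV3	wt	wt	171.1	93.0	12.9	62.3
IGROV-1	wt	wt	19.0	47.9	17.1	30.1
OV90	wt	wt	121.3	45.5	20.1	13.4
OVCAR-3	wt	wt	221.8	55.0	20.7	22.4
TOV-112D	wt	wt	12.9	64.9	9.8	3.2
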