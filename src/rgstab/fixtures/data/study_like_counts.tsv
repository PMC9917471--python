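gene	green_1	green_2	green_3	red_1	red_2	red_3
ADF2	441	788	629	607	550	631
CYB5	1629	965	1512	1828	1342	890
iPGAM	394	289	408	232	280	227
SCL13	280	266	243	238	168	164
TRXL3-3	286	596	463	571	388	485
VHA-H	601	676	701	831	512	382
ACT	6550	8376	7030	21139	23219	15268
GAPDH-2C	3513	3398	2390	1283	1065	1121
UPL6	155	240	164	1175	787	672
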