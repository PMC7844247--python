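protein_id	gene_model	rp_class	family	paralog	marker_role	paralog_specific
eIF6A	AT3G55620	biogenesis	TIF6	eIF6A	pre60S_marker	true
NMD3	AT2G03820	biogenesis	NMD3	NMD3	pre60S_marker	true
RPL24C	AT2G44860	biogenesis	eL24	RPL24C	none	true
RPP0D	AT1G25260	biogenesis	MRT4	RPP0D	none	true
R3H	AT1G03250	biogenesis	R3H	R3H	none	true
LEA	AT5G60530	biogenesis	LEA	LEA	none	true
RPL3A	AT1G43170	RP60S	uL3	RPL3A	none	true
RPL3B	AT1G61580	RP60S	uL3	RPL3B	none	true
RPL7aB	AT3G62870	RP60S	eL8	RPL7aB	none	true
RPL10A	AT1G14320	RP60S	uL16	RPL10A	none	true
RPL10C	AT3G11250	RP60S	uL16	RPL10C	none	true
RPL10aB	AT2G27530	RP60S	uL1	RPL10aB	none	true
RPL12C	AT5G60670	RP60S	uL11	RPL12C	none	true
RPL13aD	AT5G48760	RP60S	uL13	RPL13aD	none	true
RPL24B	AT3G53020	RP60S	eL24	RPL24B	none	true
RPL26A	AT3G49910	RP60S	uL24	RPL26A	none	true
RPL30C	AT3G18740	RP60S	eL30	RPL30C	none	true
RPL37aC	AT3G60245	RP60S	eL43	RPL37aC	none	true
RPP0B	AT3G09200	RP60S	uL10	RPP0B	none	true
RPP1A	AT1G01100	RP60S	P1/P2	RPP1A	none	false
RPP1B	AT4G00810	RP60S	P1/P2	RPP1B	none	false
RPP1C	AT5G47700	RP60S	P1/P2	RPP1C	none	false
RPP2D	AT3G44590	RP60S	P1/P2	RPP2D	none	false
eIF3A1	AT4G11420	eIF3	eIF3A	eIF3A1	preinit_marker	true
eIF3C1	AT3G56150	eIF3	eIF3C	eIF3C1	none	false
eIF3C2	AT3G22860	eIF3	eIF3C	eIF3C2	none	false
eIF3G2	AT5G06000	eIF3	eIF3G	eIF3G2	none	true
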