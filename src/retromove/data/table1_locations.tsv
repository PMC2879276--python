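# Muller-element locations of 21 retrogenes whose parental copy was lost,
# across the 12 sequenced Drosophila species.
# Dialect: tab-separated; '-' = missing; '***E***' = cell carries the
# intronless (retroposed) copy; '^†^' = degraded/partial copy; 'C/B' =
# ambiguous between elements; 'A (C)' = parental at A plus an independent
# secondary retrocopy at C; '^‡^' = footnote (second origin, parental kept).
gene	Dmel	Dsec	Dsim	Dyak	Dere	Dana	Dpse	Dper	Dwil	Dmoj	Dvir	Dgri
CG11164	A	A^†^	A	A	A	A	A	A	A	***C***	***C***	***C***
CG11790	E	E	E	E	E	E	E^†^	E	E	***B***	***B***	***B***
CG12375	***B***	***B***	***B***	***B***	***B***	***B***	A	A	A	A	A	A
CG1354	A	A	A	A	A	***D***	A	A	A	A	A	A
CG14286	***E***	***E***	***E***	***E***	***E***	-	A^†^	A	A	A	A	A
CG14618	A	A	A	A	A	A	A	A	A	***C***	***C***	***C***
CG14779	A	A	A	A	A	***E***	A	A	A	A	A	A
CG1639	A	A	A	A	A	A	***E***	***E***	A	A (C)^‡^	A (C)^‡^	A (C)^‡^
CG16771	***B***	***B***	***B***	***C/B***	***C/B***	***B***	-	-	A	A	A	A
CG2059	A	A	A^†^	A	A	***B***	A	A	A	A	A	A
CG2227	***A***	***A^†^***	***A***	***A***	***A***	***A***	***A***	***A***	***A***	E	E	E
CG32441	D	D	D	D	D	D	D	D	D	***E***	***E***	***E***
CG33250	A	A	A	A	A	***D***	X^†^	X^†^	A	A	X^†^	A
CG4918	***E***	***E***	***E***	***E***	***E***	A	A	A	A	A	A	A
CG5029	B	B	B^†^	B	B	B	B^†^	B	B	***A***	***A***	***A***
CG6284	***E***	***E***	***E***	***E***	***E***	***E***	B	B^†^	B	B	B	B
CG8239	A	A	A	A	A	A	A	A	A	***C***	***C***	***C***
CG8939	A	-	A	A	A	***D***	X	X	A	A	A	A
CG9126	A	A	A	A	A	***D***	X	X	A	A	A	A
CG9172	***A***	***A***	***A***	***A***	***A***	***A***	***A***	***A***	***A***	C	C	C
CG9742	A	A	A	A	A	A	***E***	***E***	A	A	A	A
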