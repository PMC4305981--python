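rank	tf1	tf2	method_citations	has_ppi	mips_categories
1	Reb1	YDR026C	B3
2	Fkh2	Fkh1	B1,B2,B3,B4,B7,B8,B38	Y	mitotic cell cycle and cell cycle control; budding, cell polarity and filament formation
3	Tye7	Cbf1	B3	Y	metabolism
4	Dig1	Ste12	B3,B7,B20	Y	protein folding; pheromone response, mating-type determination, sex-specific proteins; budding, cell polarity and filament formation
5	Pdr3	Pdr1		Y	DNA binding; chemical agent resistance; detoxification
6	Swi6	Mbp1	B2,B3,B4,B5,B7,B20,B38	Y	DNA synthesis and replication; mitotic cell cycle and cell cycle control; protein with binding function or co-factor requirement (structural or catalytic)
7	Swi6	Swi4	B2,B3,B4,B5,B7,B9,B20,B38	Y	G1/S transition of mitotic cell cycle
8	Dal80	Gln3		Y	regulation of nitrogen metabolism
9	Gln3	Gat1	B3	Y	regulation of nitrogen metabolism
10	Dal80	Gat1			regulation of nitrogen metabolism
11	Pho4	Cbf1		Y	metabolism; DNA binding
12	Pho4	Tye7			metabolism
13	Hap3	Hap2	B20	Y	regulation of C-compound and carbohydrate metabolism
14	Gal80	Gal4		Y	regulation of C-compound and carbohydrate metabolism
15	Met31	Met32	B3	Y	metabolism of methionine; metabolism of cysteine; regulation of amino acid metabolism; regulation of nitrogen, sulfur and selenium metabolism; DNA binding
16	Msn4	Msn2	B3	Y	DNA binding; stress response
17	Rap1	Fhl1	B3,B8,B20	Y
18	Tec1	Ste12	B3	Y	budding, cell polarity and filament formation
19	Swi6	Stb1	B3,B7	Y	G1/S transition of mitotic cell cycle
20	Hap2	Hap5	B8	Y	regulation of C-compound and carbohydrate metabolism
21	Nrg1	Nrg2		Y	protein with binding function or co-factor requirement (structural or catalytic); budding, cell polarity and filament formation
22	Hap3	Hap5	B8,B20	Y	regulation of C-compound and carbohydrate metabolism
23	Swi4	Stb1	B3,B4,B7	Y	G1/S transition of mitotic cell cycle
24	Swi5	Ace2	B2,B3,B4,B7,B9	Y	G1 phase of mitotic cell cycle
25	Sok2	Phd1	B3	Y	budding, cell polarity and filament formation
26	Hap5	Hap4		Y	regulation of C-compound and carbohydrate metabolism
27	Mbp1	Swi4	B1,B2,B3,B6,B7,B9	Y	mitotic cell cycle and cell cycle control
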