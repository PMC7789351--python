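cell_type	total	promoter	coding	introns	intergenic
master	84243	13171	5243	34137	31692
HSC	70731	27973	4166	18931	19661
MkP	47363	23998	2013	10036	11316
EP	38007	23243	2014	7040	5710
GM	30529	15559	1440	6697	6833
B	70358	24596	4461	21210	20091
T	51832	25103	2016	11929	12784
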