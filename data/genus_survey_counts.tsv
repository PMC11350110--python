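# Published genus-level survey counts for the 12 Pantoea antibiotic
# biosynthetic gene clusters: strains carrying each cluster vs. genome
# projects/assemblies available per genus in the public databases.
# Rows without an assembly total in the published table are omitted.
cluster	genus	strains_with_cluster	genomes_surveyed
Agglomerin	Dickeya	178	516
Agglomerin	Pantoea	1	2527
Agglomerin	Musicola	2	6
Andrimid	Serratia	27	6933
Andrimid	Pantoea	11	2527
Andrimid	Vibrio	2	56817
AGA	Xenorhabdus	11	354
AGA	Pantoea	10	2527
AGA	Pectobacterium	10	1182
Dapdiamide	Pantoea	8	2527
Dapdiamide	Serratia	1	6933
Herbicolin	Pantoea	3	2527
Herbicolin	Candidatus Fukatsuia symbiotica	1	2
Pantocin A	Pantoea	47	2527
Pantocin A	Dickeya	5	516
Pantocin A	Edwardsiella	3	241
Pantocin B	Pantoea	3	2527
PNP-1	Pantoea	8	2527
PNP-2	Enterobacter	38	23425
PNP-2	Pantoea	30	2527
PNP-2	Proteus	27	4919
PNP-2	Serratia	25	6933
PNP-2	Providencia	18	2273
PNP-2	Pectobacterium	10	1182
PNP-3	Pantoea	22	2527
PNP-4	Pantoea	14	2527
PNP-5	Yersinia	171	12230
PNP-5	Photobacterium	13	975
PNP-5	Serratia	11	6933
PNP-5	Pantoea	2	2527
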