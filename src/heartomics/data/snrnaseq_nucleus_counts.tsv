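# Per-cell-type nucleus counts of the three public human-heart snRNA-seq
# studies on the Broad Single Cell Portal (accessions SCP1303, SCP1852,
# SCP1849), as reported by the source studies.
# Note: the reported per-cell-type breakdown of SCP1852 sums to 100,000,
# not to its stated 157,273 total; consolidated totals therefore use the
# stated per-dataset totals (see reference.DATASET_TOTALS).
dataset	cell_type	n_nuclei
SCP1303	cardiomyocytes	158469
SCP1303	fibroblasts	142009
SCP1303	endothelial cells	101307
SCP1303	pericytes	69304
SCP1303	macrophages	54715
SCP1303	VSMCs	18137
SCP1303	lymphocytes	16246
SCP1303	endocardial cells	6489
SCP1303	adipocytes	5320
SCP1303	neuronal cells	4292
SCP1303	lymphatic endothelial cells	5181
SCP1303	activated fibroblasts	5210
SCP1303	mast cells	4465
SCP1303	proliferating macrophages	1276
SCP1303	epicardial cells	269
SCP1852	cardiomyocytes	25838
SCP1852	endothelial cells	25838
SCP1852	fibroblasts	21034
SCP1852	pericytes	12037
SCP1852	macrophages	7010
SCP1852	VSMCs	2405
SCP1852	neuronal cells	1985
SCP1852	endocardial cells	1436
SCP1852	lymphocytes	1121
SCP1852	lymphatic endothelial cells	658
SCP1852	adipocytes	454
SCP1852	mast cells	92
SCP1852	epithelial-like cells	51
SCP1852	epicardial cells	41
SCP1849	cardiomyocytes	31614
SCP1849	fibroblasts	22480
SCP1849	endothelial cells	19035
SCP1849	pericytes	10565
SCP1849	macrophages	9239
SCP1849	VSMCs	1939
SCP1849	lymphocytes	1925
SCP1849	lymphatic endothelial cells	1427
SCP1849	neuronal cells	668
SCP1849	adipocytes	572
SCP1849	mast cells	136
SCP1849	epicardial cells	84
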