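# positive_class: lymphoma
# negative_class: breast_cancer
# Published three-pair lymphoma vs breast-cancer panel. The direction column
# gives the REO pattern in the positive (lymphoma) class; in breast cancer
# MMP3 > RGS13, EPCAM > CD37 and EPCAM > STAP1. Rank differences were not
# published, so this fixture supports classification but not rank-difference
# filtering.
gene_i	gene_j	direction_positive	rank_diff_positive	rank_diff_negative	degree
MMP3	RGS13	j_higher	NA	NA	NA
CD37	EPCAM	i_higher	NA	NA	NA
EPCAM	STAP1	j_higher	NA	NA	NA
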