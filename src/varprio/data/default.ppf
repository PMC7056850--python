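# Default prioritization parameter file for rare-disease cohort screening
# (tuned for dominant/recessive monogenic disease, e.g. congenital heart
# disease exome/genome studies).
#
# Filters: drop common variants (population minor allele frequency > 0.1%
# in gnomAD/ExAC/1000 Genomes annotations; absence from a frequency
# database passes, as absence is evidence of rarity) and synonymous calls.
#
# Scoring: high-impact consequences (stop-gain, frameshift, splicing) carry
# the largest weights; in-silico predictors contribute at the pathogenicity
# thresholds their authors recommend (CADD phred >= 20 possibly pathogenic,
# GERP++ RS >= 4 constrained, damaging calls from PolyPhen-2/
# MutationTaster2/LRT/MetaSVM).

[filters]
gnomAD_AF	greater	0.001	true
ExAC_AF	greater	0.001	true
g1000_AF	greater	0.001	true
ExonicFunc.refGene	equals	synonymous_SNV	true

[scoring]
ExonicFunc.refGene	categorical	stopgain	5
ExonicFunc.refGene	categorical	stoploss	4
ExonicFunc.refGene	categorical	frameshift_insertion	5
ExonicFunc.refGene	categorical	frameshift_deletion	5
ExonicFunc.refGene	categorical	nonsynonymous_SNV	1
Func.refGene	categorical	splicing	5
CADD_phred	interval	20	inf	2
CADD_phred	interval	10	20	1
Polyphen2_HVAR_pred	categorical	D	2
Polyphen2_HVAR_pred	categorical	P	1
MutationTaster_pred	categorical	A	2
MutationTaster_pred	categorical	D	2
LRT_pred	categorical	D	1
MetaSVM_pred	categorical	D	2
GERPpp_RS	interval	4	inf	1

[qc]
min_depth	8
min_allele_balance	0.25

[output]
score_cutoff	0
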