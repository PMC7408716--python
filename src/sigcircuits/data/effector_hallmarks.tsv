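effector_gene	hallmarks
VEGFA	Inducing angiogenesis
FIGF	Inducing angiogenesis
KDR	Inducing angiogenesis
NOS3	Inducing angiogenesis
PTK2	Inducing angiogenesis;Activating invasion and metastasis
RAD51	Genome instability and mutation
RAD51C	Genome instability and mutation
BRCA1	Genome instability and mutation
PTCH1	Evading growth suppressors
E2F1	Sustaining proliferative signaling;Resisting cell death
RB1	Evading growth suppressors
CDKN1A	Evading growth suppressors
CCND1	Sustaining proliferative signaling
RPS6KB1	Sustaining proliferative signaling
ELK1	Sustaining proliferative signaling
STAT5A	Sustaining proliferative signaling
STAT1	Tumor-promoting inflammation
CBLC	Sustaining proliferative signaling
ERBB3	Sustaining proliferative signaling
IGFBP3	Resisting cell death
BBC3	Resisting cell death
ILK	Activating invasion and metastasis
MAPK8	Sustaining proliferative signaling
PIM1	Resisting cell death;Sustaining proliferative signaling
MITF	Sustaining proliferative signaling
TNF	Tumor-promoting inflammation
NFKB1	Tumor-promoting inflammation;Resisting cell death
MYC	Sustaining proliferative signaling;Enabling replicative immortality
BCL2	Resisting cell death
JUN	Sustaining proliferative signaling
FOXO3	Resisting cell death
MAPK1	Sustaining proliferative signaling
AKT3	Resisting cell death;Sustaining proliferative signaling
RAC1	Activating invasion and metastasis
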