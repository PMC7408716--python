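effector_gene	functions
VEGFA	Angiogenesis
FIGF	Angiogenesis
KDR	Angiogenesis
NOS3	Angiogenesis
PTK2	Angiogenesis
RAD51	DNA recombination
RAD51C	DNA recombination
BRCA1	DNA recombination
PTCH1	Tumor suppressor
E2F1	Apoptosis;Cell cycle
RB1	Cell cycle
CDKN1A	Cell cycle
CCND1	Cell division;DNA damage
RPS6KB1	Translation regulation
ELK1	Transcription;Transcription regulation
STAT5A	Transcription;Transcription regulation
STAT1	Transcription;Transcription regulation
CBLC	Ubl conjugation pathway
ERBB3	Cell differentiation
IGFBP3	Apoptosis
BBC3	Apoptosis
ILK	Cell growth;Metastasis
MAPK8	Biological rhythms
PIM1	Apoptosis;Cell cycle
MITF	Transcription regulation;Pigmentation
TNF	Inflammatory response
NFKB1	Transcription regulation;Inflammatory response
MYC	Cell proliferation;Transcription regulation
BCL2	Apoptosis regulation
JUN	Transcription regulation;Cell proliferation
FOXO3	Apoptosis;Cell cycle
MAPK1	Cell proliferation;Signal transduction
AKT3	Cell survival;Signal transduction
RAC1	Cell motility;Metastasis
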