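# Example stress-response-gene (SRG) family definitions (synthetic stand-in).
# One row per family: defining Pfam domain accessions (comma-separated) and
# stress category (chemical / pathogen / wounding).  File order sets the
# priority used when a gene matches more than one family.  Supply a curated
# table for real analyses.
family	category	accessions
HSP70	chemical	PF00012
HSP20	chemical	PF00011
SOD	chemical	PF00081,PF02777,PF00080
glutathione_S-transferase	chemical	PF02798,PF00043
cytochrome_P450	chemical	PF00067
ferritin	chemical	PF00210
aldehyde_dehydrogenase	chemical	PF00171
C-type_lectin	pathogen	PF00059
NACHT	pathogen	PF05729
TIR	pathogen	PF01582
glycosyl_hydrolase	pathogen	PF00704
collagen	wounding	PF01391
von_Willebrand_A	wounding	PF00092
thrombospondin_1	wounding	PF00090
fibronectin_III	wounding	PF00041
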