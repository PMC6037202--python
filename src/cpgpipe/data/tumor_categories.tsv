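category	malignant	cns
breast	1	0
colorectal	1	0
kidney	1	0
nmsc	1	0
ovary	1	0
endometrium	1	0
melanoma	1	0
thyroid	1	0
hem_lymphoid	1	0
hem_myeloid	1	0
lung	1	0
soft_tissue_sarcoma	1	0
pituitary	0	1
cns	1	1
pheochromocytoma	0	0
paraganglioma	0	0
leiomyoma_cutaneous	0	0
leiomyoma_uterine	0	0
testicular	1	0
prostate	1	0
small_bowel	1	0
pancreatic_net	1	0
gi_net	1	0
stomach	1	0
bladder	1	0
cervix	1	0
parathyroid	0	0
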