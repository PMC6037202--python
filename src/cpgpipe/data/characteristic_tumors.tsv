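symbol	characteristic_tumors
BRCA1	breast;ovary
BRCA2	breast;ovary
PALB2	breast
CHEK2	breast
ATM	breast
PTEN	breast;thyroid;endometrium
FH	leiomyoma_cutaneous;leiomyoma_uterine;kidney
FLCN	kidney
MAX	pheochromocytoma
SDHB	pheochromocytoma;paraganglioma
RET	thyroid;pheochromocytoma;parathyroid
MET	kidney
MLH1	colorectal;endometrium
MSH2	colorectal;endometrium
MSH6	colorectal;endometrium
PMS2	colorectal;endometrium
MUTYH	colorectal
NTHL1	colorectal
NF1	pheochromocytoma;gi_net
SMAD4	colorectal;stomach
TSC1	kidney
TSC2	kidney
APC	colorectal
TP53	breast;soft_tissue_sarcoma
VHL	kidney;pheochromocytoma
MEN1	parathyroid;pituitary;pancreatic_net
KIT	gi_net
ALK	lung
CDKN1B	parathyroid;pituitary
EXT2	soft_tissue_sarcoma
BMPR1A	colorectal
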