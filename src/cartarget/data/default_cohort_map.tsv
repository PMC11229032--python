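# Default tumor -> GTEx control-tissue pairing.
# Transcribed from the standard TCGA/GTEx tissue correspondence; edit or
# replace via the --map flag.  Second column: comma-separated GTEx
# tissue names (may be empty: controls are then adjacent normals only).
ACC	Adrenal Gland
BLCA	Bladder
BRCA	Breast
CESC	Cervix Uteri
CHOL	Liver
COAD	Colon
DLBC	Blood
ESCA	Esophagus
GBM	Brain
HNSC
KICH	Kidney
KIRC	Kidney
KIRP	Kidney
LAML	Blood,Bone Marrow
LGG	Brain
LIHC	Liver
LUAD	Lung
LUSC	Lung
MESO
OV	Ovary
PAAD	Pancreas
PCPG	Adrenal Gland
PRAD	Prostate
READ	Colon
SARC
SKCM	Skin
STAD	Stomach
TGCT	Testis
THCA	Thyroid
THYM
UCEC	Uterus
UCS	Uterus
UVM
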