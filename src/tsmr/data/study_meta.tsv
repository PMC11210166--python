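TRAIT	N	POPULATION	CONSORTIUM	YEAR	SOURCE
Inflammatory diseases of prostate (prostatitis)	74658	European	Not available	2021	IEU Open GWAS
Benign prostatic hyperplasia	463010	European	MRC-IEU	2018	IEU Open GWAS
Malignant neoplasm of prostate	463010	European	MRC-IEU	2018	IEU Open GWAS
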