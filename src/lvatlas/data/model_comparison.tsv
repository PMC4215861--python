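model	n_parameters	deviance	aic	bic	auc
Baseline	7	1254.44	1268.44	1308.34	0.7404
MASSVOL	10	602.641	622.641	679.644	0.9530
ED PCA	20	411.088	451.088	565.094	0.9810
ES PCA	21	319.881	361.881	481.587	0.9883
ED&ES PCA	27	260.753	314.753	468.661	0.9905
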