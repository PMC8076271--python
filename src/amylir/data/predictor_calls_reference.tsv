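# Reference-set calls by five sequence-based predictors, compared with the
# IR-microscopy adjudication. consensus_with_ir is the printed percentage of
# the five predictors whose (binarized) call matches the binarized IR call.
id	sequence	ir_microscopy	amylogram	foldamyloid	pasta2	path_lr	path_rf	consensus_with_ir
FNPQGG	FNPQGG	No	No	No	No	No	No	100
FTFIQF	FTFIQF	Yes	Yes	Yes	No	Yes	Yes	80
ISFLIF	ISFLIF	Yes	Yes	Yes	Yes	Yes	Yes	100
KPAESD	KPAESD	No	No	No	No	No	No	100
LVFYQQ	LVFYQQ	Yes	Yes	Yes	No	Yes	Yes	80
NPQGGY	NPQGGY	No	No	No	No	No	No	100
SFLIFL	SFLIFL	Yes*	Yes	Yes	Yes	Yes	Yes	100
TKPAES	TKPAES	No	No	No	No	No	No	100
YLLYYT	YLLYYT	Yes	Yes	Yes	No	Yes	Yes	80
YTVIIE	YTVIIE	Yes	Yes	Yes	Yes	No	Yes	80
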