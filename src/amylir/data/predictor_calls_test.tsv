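# Test-set calls by five sequence-based predictors, plus the original
# database annotation and the IR-microscopy adjudication. Cell case ("YES",
# "no") kept verbatim from the source table; loaders normalize.
# WSFYLL: the printed consensus (80) contradicts the stated definition, under
# which the row's calls vs IR give 20; the printed value is kept verbatim and
# the row is flagged so reproduction checks can exclude it.
id	sequence	database	ir_microscopy	amylogram	path_lr	path_rf	foldamyloid	pasta2	consensus_with_ir	consensus_anomaly
ALEEYT	ALEEYT	Yes	No	No	No	No	No	No	100	0
ASSSNY	ASSSNY	Yes	No	No	No	No	No	No	100	0
DETVIV	DETVIV	No	Yes*	Yes	No	Yes	No	Yes	60	0
ELNIYQ	ELNIYQ	No	No	Yes	No	No	Yes	No	60	0
FGELFE	FGELFE	No	No	Yes	No	No	No	No	80	0
FQKQQK	FQKQQK	No	No	Yes	No	No	No	No	80	0
FTPTEK	FTPTEK	No	No	Yes	No	No	No	No	80	0
HGFNQQ	HGFNQQ	Yes	No	No	No	No	No	No	100	0
HLFNLT	HLFNLT	Yes	No	No	No	Yes	Yes	No	60	0
HSSNNF	HSSNNF	Yes	No	No	No	No	No	No	100	0
MIENIQ	MIENIQ	Yes	No	No	No	No	No	No	100	0
MIHFGN	MIHFGN	Yes	No	No	No	No	No	No	100	0
MMHFGN	MMHFGN	Yes	No	No	No	No	No	No	100	0
NIFNIT	NIFNIT	Yes	No	No	No	Yes	Yes	No	60	0
NNSGPN	NNSGPN	Yes	No	No	No	No	No	No	100	0
NTIFVQ	NTIFVQ	No	Yes	YES	Yes	Yes	Yes	No	80	0
QANKHI	QANKHI	Yes	No	No	No	No	No	No	100	0
QEMRHF	QEMRHF	Yes	No	No	No	No	No	No	100	0
SHVIIE	SHVIIE	No	Yes	Yes	No	No	Yes	Yes	60	0
STTIIE	STTIIE	No	No	Yes	No	No	No	No	80	0
STVVIE	STVVIE	No	Yes	Yes	No	Yes	Yes	Yes	80	0
SWVIIE	SWVIIE	No	Yes	Yes	No	Yes	Yes	Yes	80	0
WSFYLL	WSFYLL	No	No	Yes	Yes	Yes	Yes	No	80	1
YYTEFT	YYTEFT	No	no	Yes	No	No	No	No	80	0
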