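# Reference set: 10 hexapeptides whose database annotation, predictor call and
# experiments agree. Band dialect: slash-separated POS(grade,flags) tokens,
# '*' prefix marks the dominant maximum (printed bold in the source table).
# Class dialect: Yes = amyloid-positive, No = non-amyloid, Yes* = oligomer.
# SFLIFL: the two IR modes disagree; IR microscopy indicated oligomers that did
# not transform into fibrils, so its IR-microscopy class is stored as Yes*.
id	sequence	db_label	ir_microscopy_bands	ir_microscopy_class	atr_ftir_bands	atr_ftir_class	afm_class	consensus_with_db
FNPQGG	FNPQGG	No	1679(m)/*1641(s)	No	*1655(s,br)	No	No	Yes
FTFIQF	FTFIQF	Yes	1689(m,sh)/*1628(s)	Yes	1690(w)/*1622(s)	Yes	Yes*	Yes
ISFLIF	ISFLIF	Yes	1689(m,sh)/*1631(s)	Yes	1685(w)/*1631(s)	Yes	Yes	Yes
KPAESD	KPAESD	No	*1665(s,br)	No	*1678(s,br)/1640(m,sh)	No	No	Yes
LVFYQQ	LVFYQQ	Yes	*1631(s)	Yes	1683(w,sh)/*1629(s)	Yes*	Yes	Yes
NPQGGY	NPQGGY	No	*1658(s,br)	No	*1658(s,br)	No	No	Yes
SFLIFL	SFLIFL	Yes	1689(m)/*1633(s)	Yes*	*1632(s)	Yes	Yes*	Yes
TKPAES	TKPAES	No	*1652(s,br)	No	*1678(s)/1640(sh)	No	No	Yes
YLLYYT	YLLYYT	Yes	1686(m,sh)/*1629(s)	Yes	1685(m)/*1630(s)	Yes	Yes*	Yes
YTVIIE	YTVIIE	Yes	1685(m)/*1627(s)	Yes	1684(m)/*1626(s)	Yes	Yes	Yes
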