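# Test set: 24 hexapeptides whose database annotation disagreed with the
# sequence predictor; IR band annotations adjudicate the true class.
# Dialects as in reference_set.tsv. Cell case ("NO", "no") kept verbatim from
# the source table; loaders normalize. STTIIE is the one peptide where the two
# IR modes disagree (non-amyloid by IR microscopy, oligomer by ATR-FTIR);
# its consensus cell reads "Yes ambiguous" and both rows are kept verbatim.
id	sequence	db_label	ir_microscopy_bands	ir_microscopy_class	atr_ftir_bands	atr_ftir_class	consensus_with_db
ALEEYT	ALEEYT	Yes	*1655(s,br)	No	*1654(s)	No	No
ASSSNY	ASSSNY	Yes	*1649(m,sh)	No	*1655(m,br)	No	No
DETVIV	DETVIV	No	1685(w)/*1635(s)	Yes*	1685(m)/*1633(s)	Yes*	No
ELNIYQ	ELNIYQ	No	1661(w,sh)/*1635(s)	No	1681(m,br)/1668(m,br)/*1635(s)	No	Yes
FGELFE	FGELFE	No	*1660(s)/1650(w)	No	*1659(s)	No	Yes
FQKQQK	FQKQQK	No	*1660(s,br)	No	*1682(s,br)	No	Yes
FTPTEK	FTPTEK	No	*1660(s,br)	No	*1680(s,br)	No	Yes
HGFNQQ	HGFNQQ	Yes	*1662(s,br)	No	*1682(s,br)	No	No
HLFNLT	HLFNLT	Yes	*1674(s,br)	No	*1680(s,br)/1633(m,br)	No	No
HSSNNF	HSSNNF	Yes	*1649(m,br)	No	*1680(s)/1646(m,sh)	No	No
MIENIQ	MIENIQ	Yes	*1656(s,br)	No	*1655(s,br)	No	No
MIHFGN	MIHFGN	Yes	*1677(s,br)	No	*1680(s,br)/1646(m,br)	NO	NO
MMHFGN	MMHFGN	Yes	*1675(s)	No	*1676(s,br)	No	No
NIFNIT	NIFNIT	Yes	*1657(s)	No	*1663(s,br)	No	No
NNSGPN	NNSGPN	Yes	1676(sh)/*1648(s,br)	No	*1676(s,br)/1654(m,br)	No	No
NTIFVQ	NTIFVQ	No	*1629(s)	Yes	1682(w)/*1631(s)	Yes*	No
QANKHI	QANKHI	Yes	*1680(s,br)	No	*1681(s)/1653(sh)	No	No
QEMRHF	QEMRHF	Yes	*1679(s,br)	No	*1676(s,br)/1655(sh)	No	No
SHVIIE	SHVIIE	No	1688(m)/*1630(s)	Yes	1684(m)/*1633(s)	Yes	No
STTIIE	STTIIE	No	*1657(s,br)	No	1681(m)/*1630(s)	Yes*	Yes ambiguous
STVVIE	STVVIE	No	1685(w,br)/*1633(s)	Yes	1682(w,br)/*1630(s)	Yes*	NO
SWVIIE	SWVIIE	No	1682(w,sh)/*1631(s)	Yes	1684(w)/*1631(s)	Yes	No
WSFYLL	WSFYLL	No	*1658(s,br)	No	1675(w,sh)/*1637(s)	No	Yes
YYTEFT	YYTEFT	No	*1665(s,br)	No	*1659(s,br)	No	Yes
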