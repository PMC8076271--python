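# amylir

Amide I infrared adjudication and label-noise auditing of amyloid
hexapeptide annotations.

## The problem

Amyloid databases label short peptides as amyloid or non-amyloid based on
heterogeneous in-vitro evidence, and a fraction of those labels is wrong —
a classic weak-supervision problem for the sequence-based amyloidogenicity
predictors trained on them. `amylir` implements the full desk-scale
workflow for detecting and adjudicating such misannotations:

1. **Curation & surrogate prediction** — filter clean hexapeptides, encode
   them in a reduced amino-acid alphabet, score each peptide's amyloid
   probability with an out-of-fold tree ensemble over n-gram counts, and
   select *outliers* (confident contradictions of the database label) and
   *references* (confident agreements).
2. **IR spectral adjudication** — preprocess Amide I spectra (rubberband
   baseline, normalization to the Amide I maximum, Savitzky–Golay second
   derivative over 1580–1720 cm⁻¹), pick component bands as prominent
   second-derivative minima with aromatic side-chain exclusion
   (Phe 1600, Tyr 1616, Trp 1620 cm⁻¹), and classify each spectrum with
   band-position decision rules.
3. **Concordance audit** — score database labels and five sequence
   predictors against the IR adjudication (accuracy, sensitivity,
   specificity, per-peptide consensus) from packaged band-annotation
   tables of 34 experimentally characterized hexapeptides.
4. **Weak-label simulation** — a seeded end-to-end experiment showing that
   a predictor trained on noisily labeled data flags its own mislabeled
   training instances at a precision well above the label-flip rate.

## The band-rule model

Let *d* be the dominant Amide I band maximum (cm⁻¹) of the
second-derivative band list, and let a *minor* band be any non-dominant
band in the antiparallel window [1684, 1695]:

* 1611 ≤ *d* ≤ 1632 → **fibril** (amyloid-positive); cross-β sheet absorbs
  low, usually close to 1630 cm⁻¹.
* 1632 < *d* ≤ 1643 and a minor band present → **oligomer**
  (amyloid-positive); the high-frequency minor maximum, roughly five-fold
  weaker than the main band, is the antiparallel β-sheet signature.
* otherwise → **non-amyloid** (α-helix, disorder, turns and native β sheet
  without the antiparallel minor).

For scoring against binary predictors, oligomer collapses to positive.
All windows are configurable (`RuleConfig`, YAML-loadable).

## Worked example

```bash
amylir audit --outdir audit --self-check
```

prints the misannotation audit of the packaged 24-peptide test set —
peptides whose database label contradicted a sequence predictor, and which
IR microscopy then adjudicated:

```json
{
  "n_total": 24,
  "n_misannotated": 17,
  "database_false_positives": 12,
  "database_false_negatives": 5
}
```

17 of the 24 suspect peptides (71%) are indeed misannotated: for 12, the
database says amyloid but the spectra show no amyloid band pattern; for 5,
the database says non-amyloid but the spectra show fibril or oligomer
signatures. The command also writes the reproduced per-predictor
Acc/Sn/Sp tables and per-peptide consensus columns as TSV, and
`--self-check` exits non-zero if any reproducible cell disagrees with the
packaged tables.

The same classification runs on any two-column spectrum:

```bash
amylir classify-spectrum my_spectrum.txt --sequence YTVIIE
```

```json
{
  "subtype": "fibril",
  "positive": true,
  "dominant_position": 1625.0,
  "evidence": [
    "dominant_in_fibril_window",
    "oligomer_minor_present"
  ]
}
```

and the filtering simulation from a shell:

```bash
amylir noise-experiment --flip-rate 0.1 --threshold 0.9 --n 500 \
    --replicates 10 --seed 0 --out results/noise
```

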