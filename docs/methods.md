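# Methods

## Spectral preprocessing

Input spectra are single traces (wavenumber cm⁻¹, absorbance) covering at
least 1580–1720 cm⁻¹. The chain is: baseline correction → Amide I
normalization → Savitzky–Golay (SG) second derivative → band picking.

**Baseline.** Default is the rubberband method: the lower convex hull of
the (ν, A) point set is interpolated and subtracted, which removes offsets
and slowly varying drift without assuming a functional form. A `linear`
mode subtracts the chord between the window endpoints; over the short
analysis window the two agree closely, and linear is the safer choice for
traces that dip below their endpoints. For a collinear (degenerate) trace
the rubberband reduces to the chord.

**Normalization.** The trace is divided by its maximum over 1600–1700
cm⁻¹, so band classification is invariant to acquisition scale. A
non-positive maximum raises an error rather than producing a silent junk
spectrum.

**Second derivative (DII).** Computed with an SG filter, polynomial order
2, on the 1580–1720 cm⁻¹ window. A symmetric SG filter needs an odd
window; the default is **31 points** (the nearest odd width to a nominal
30), and both the width and its interpretation (points on the grid, not
cm⁻¹) are caller-configurable since conventions differ between
instruments. Two modes are provided: `single_pass` (default) evaluates
the second derivative of the local quadratic fit directly; `two_step`
takes a finite-difference second derivative and then smooths it with a
zeroth-order SG pass of the same window. On noise-free Gaussian bands
both locate minima identically to the grid resolution; `single_pass` is
the default because it is the standard, variance-optimal formulation.
The derivative requires a uniform grid (instrument exports are); no
resampling is performed implicitly.

**Band picking.** Component bands are local minima of DII. A minimum
survives if its prominence in −DII exceeds a *relative* threshold
(default 0.05 of the deepest excursion), which makes picking invariant to
positive rescaling of the trace. Minima within ±3 cm⁻¹ of the aromatic
side-chain positions (Phe 1600, Tyr 1616, Trp 1620 cm⁻¹) are discarded
when the peptide sequence contains the residue — ring vibrations, not
backbone structure. The surviving minimum with the deepest DII value
inside 1600–1700 cm⁻¹ is the dominant band. Intensity grades s/m/w are
assigned from relative DII depth (≥ 0.6, ≥ 0.25 of the maximum depth);
this is an explicit package convention — in the shipped expert tables the
grades are by eye — and grades never influence classification. Shape
flags (broad/shoulder) are parsed from annotations but not emitted by the
picker.

## Band decision rules

With *d* the dominant position and the oligomer minor window
[1684, 1695] cm⁻¹:

1. 1611 ≤ *d* ≤ 1632 → fibril, positive.
2. 1632 < *d* ≤ 1643 and some non-dominant band in the minor window →
   oligomer, positive.
3. otherwise → non-amyloid, negative.

Two window edges deviate from the nominal literature values, both driven
by the shipped expert tables: the fibril upper edge is **1632** (dominant
maxima at 1631 and 1632 appear in amyloid-positive rows; the fibril band
is "usually close to" 1630, not bounded by it), and the minor-window
lower edge is **1684** (a 1684 minor occurs in a positive row, while
1679–1681 minors occur only in negative rows). The ~five-fold
minor/major amplitude ratio is recorded as advisory evidence, not a gate:
annotation tables carry grades, not amplitudes. Every threshold is a
`RuleConfig` field and can be loaded from YAML.

Binary calls on the 68 packaged band lists reproduce the printed classes
68/68. Subtype (fibril vs oligomer) fidelity is deliberately *not*
asserted: the printed subtypes are not a function of the printed band
lists alone (e.g. a row with a bare 1629 dominant printed as oligomer),
so subtype agreement is reported but only the binary call is contracted.

## Packaged tables and their known anomalies

The four fixtures transcribe the band annotations, expert classes and
predictor calls for 10 reference and 24 test hexapeptides. Printed
quirks are preserved verbatim and normalized on load (case variants of
Yes/No cells). Two cells are internally inconsistent in the source
tables and are flagged rather than silently corrected:

* the WSFYLL consensus cell prints 80, while the row's five calls against
  its IR truth give 20 under the stated definition (`consensus_anomaly`
  flag in the fixture);
* the PASTA 2.0 full-test-set accuracy prints 0.92, while the same row's
  printed Sn = 0.8 and Sp = 1 force TP=4, FN=1, FP=0, TN=19 and hence
  Acc = 23/24 ≈ 0.96. Tests assert the value implied by the row's own
  counts.

One peptide (STTIIE) is non-amyloid by IR microscopy but oligomer by
ATR-FTIR; both rows are kept verbatim, and it is the single
cross-technique binary disagreement (23/24 agree).

## Synthetic spectra

The forward model is a sum of Gaussians plus a linear baseline plus white
noise. Gaussian (rather than Voigt) shapes are sufficient because the
pipeline relies only on the second-derivative peak-location property,
which Gaussians preserve. Class-conditional priors:

| class | dominant center | minor band |
|---|---|---|
| fibril | triangular(1620, mode 1630, 1632), width 4–7 | optional (p=0.5), 1685–1695, ratio 0.10–0.25 |
| oligomer | uniform 1628–1636, width 4–7 | mandatory, 1685–1695, ratio 0.15–0.30 |
| non-amyloid | α-helix 1650–1660 (broad, width 8–12), disordered 1644–1649, or turn 1660–1682 | none |

The triangular fibril law encodes "usually close to 1630"; a uniform law
would also place a quarter of fibril bands inside the ±3 cm⁻¹ tryptophan
exclusion zone at 1620, which real fibril statistics do not support.
Aromatic bands (small amplitude 0.04–0.08, width 2.5–4) are added at
1600/1616/1620 only for residues present in the sequence. Defaults:
grid 1580–1720 cm⁻¹ at 1 cm⁻¹ ascending; noise SD 0.01 (1% of the
unit-normalized dominant amplitude); baseline offset U(0, 0.05) and slope
U(−5·10⁻⁴, 5·10⁻⁴) per cm⁻¹ about 1650.

What the generator does **not** emulate: water-vapor and CO₂ interference
bands, detector nonlinearity, Mie/scattering baselines, band asymmetry,
amide II overlap, and pixel-map heterogeneity (only a mean-spectrum
reduction is supported). Passing recovery tests therefore demonstrate
correctness of the band logic under idealized optics, not robustness to
every instrumental artifact. Under these conditions the pipeline recovers
the planted binary class for ≥ 95% of 500 seeded spectra at default noise
and localizes the dominant band within ±2 cm⁻¹ for ≥ 98% of noise-free
spectra (the rare failures are fibril bands inside an applicable aromatic
exclusion zone with no surviving minimum, which raise an explicit error).

## Planted label rule

Hexapeptide datasets draw sequences uniformly. The hidden true label is
Bernoulli with P(amyloid | seq) = expit(*s* · z(seq)), where *s* is
`rule_strength` and z is the mean of a standardized per-residue composite
of Kyte–Doolittle hydropathy and Chou–Fasman β-sheet propensity, scaled
by √6 so z is approximately standard normal over random hexapeptides.
The composite is quantized to the default six physicochemical groups
(residues in a group share one score): the planted rule is then a pure
composition rule over the same groups the surrogate predictor's
reduced-alphabet n-gram features are built from, so "separable" means
separable in the predictor's own feature space. A logistic rule rather
than a hard threshold is used so that `rule_strength = 0` degenerates to
fair-coin labels while large strengths approach a deterministic
threshold; `bayes_probability` / `bayes_label` export the rule so tests
can compute the Bayes decision without any fitted model. Observed labels
flip the true ones independently with probability ε < 0.5.

## Surrogate predictor and outlier selection

Features are counts of contiguous n-grams (n = 1..2 by default) of the
sequence encoded in a reduced alphabet; the default alphabet is a
surrogate six-group physicochemical grouping (aliphatic, aromatic, polar,
basic, acidic, special) and is pluggable via two-column TSV. The learner
is a 200-tree random forest; any classifier with `predict_proba`
plugs in. Scoring is **out-of-fold** by default (5 stratified folds):
in-fit scoring of training data lets memorization mask outliers, though
an `in_fit` mode is provided and provenance is always recorded. A
peptide is an outlier at threshold τ ∈ (0.5, 1] when its predicted
amyloid probability contradicts its observed label with confidence ≥ τ;
references are the mirror image; a top-k ranking mode is provided since a
fixed cutoff and a ranked shortlist are both common selection styles.
Encoded duplicates collapse to one representative per (encoding, label);
encodings carrying both labels are ambiguous supervision and are dropped
from both classes and reported.

## Chemometrics

PCA on DII panels is mean-centered only (no unit-variance scaling — the
shared wavenumber scale is already commensurable). Components are
oriented so the largest-magnitude loading is positive, removing the sign
ambiguity from plots and regression tests. Separation of labeled groups
is quantified as the mean silhouette in the first two score dimensions;
silhouette was chosen because the panel separations being mirrored are
reported visually, with no printed coordinates, and a label-based
statistic is the least parameterized quantification. Two components are
inspected by default.

## Noise experiment

`run_noise_experiment` chains: dataset simulation → out-of-fold scoring →
outlier selection at τ → adjudication of each flagged peptide by
simulating a spectrum from its *hidden true* class and classifying it
through the full spectral pipeline. Reported metrics: filter precision
(flagged ∧ truly-flipped / flagged; undefined when nothing is flagged,
reported as `None`, never as 0), recall, enrichment = precision / ε, and
adjudication agreement. Default grids: ε ∈ {0.05, 0.1, 0.2, 0.3},
τ ∈ {0.7, 0.8, 0.9}, 10 replicates. The standard problem size used in
the test suite is 500 peptides per replicate with the strong rule
(strength 4), which keeps a full sweep in the minutes range on one core;
enrichment comfortably exceeds 1 across the ε grid there, and precision
collapses to ≈ ε when the rule is uninformative (strength 0), as it must
when flags are label-independent.

## Numerical conventions

* Concordance ratios are exact `Fraction`s internally; display rounding
  is half-up to two decimals. Undefined sensitivity/specificity (empty
  class) is `None`, never a silent 0 or 1.
* Oligomer calls binarize to positive before every comparison.
* Spectra are stored ascending in wavenumber; descending instrument
  exports are flipped on read.
* All stochastic components consume `numpy.random.default_rng` seeds;
  derived streams use seed sequences so sub-streams are independent.

## Limitations

* The band rules classify from the dominant band and one minor window;
  they do not deconvolve overlapping structures or quantify
  secondary-structure fractions.
* The reduced alphabet and predictor are explicit surrogates; no claim
  is made that they replicate any published predictor's internals.
* Enrichment numbers from the simulation characterize the synthetic
  data-generating process and do not transfer to real database-scale
  collections.
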