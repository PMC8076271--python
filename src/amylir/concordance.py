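"""Concordance statistics and the misannotation audit.

Every comparison first collapses three-way calls to the amyloid-positive
flag, with oligomers counted as positives: sequence predictors know only
two classes, so an experimentally confirmed oligomer scores as a correctly
identified amyloid.  Ratios are kept as exact rationals internally and
rounded half-up to two decimals only for display.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import pandas as pd

from .fixtures import PREDICTOR_METHODS, load_fixture
from .rules import binarize, classify_bands, RuleConfig

__all__ = [
    "ConcordanceStats",
    "MisannotationReport",
    "confusion_stats",
    "consensus_percent",
    "misannotation_audit",
    "reproduce_audit_tables",
    "reproduce_consensus",
    "band_rule_calls",
]


def _round2(x: Fraction | None) -> float | None:
    if x is None:
        return None
    d = Decimal(x.numerator) / Decimal(x.denominator)
    return float(d.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConcordanceStats:
    """Confusion counts of one method against a truth column."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def acc(self) -> Fraction:
        return Fraction(self.tp + self.tn, self.n)

    @property
    def sn(self) -> Fraction | None:
        """Sensitivity; ``None`` (undefined) when there are no actual positives."""
        pos = self.tp + self.fn
        return Fraction(self.tp, pos) if pos else None

    @property
    def sp(self) -> Fraction | None:
        """Specificity; ``None`` (undefined) when there are no actual negatives."""
        neg = self.tn + self.fp
        return Fraction(self.tn, neg) if neg else None

    def rounded(self) -> dict:
        """Display form: half-up two-decimal Acc/Sn/Sp."""
        return {"acc": _round2(self.acc), "sn": _round2(self.sn), "sp": _round2(self.sp)}


def confusion_stats(predictions: dict, truth: dict) -> ConcordanceStats:
    """Confusion counts over the peptides present in both mappings.

    ``predictions`` and ``truth`` map peptide id to a call (canonical or
    printed dialect); oligomer binarizes to positive before comparison.

    Raises
    ------
    ValueError
        If the id intersection is empty.
    """
    ids = [i for i in truth if i in predictions]
    if not ids:
        raise ValueError("no peptides shared between predictions and truth")
    tp = tn = fp = fn = 0
    for i in ids:
        p, t = binarize(predictions[i]), binarize(truth[i])
        if p and t:
            tp += 1
        elif not p and not t:
            tn += 1
        elif p and not t:
            fp += 1
        else:
            fn += 1
    return ConcordanceStats(tp=tp, tn=tn, fp=fp, fn=fn)


def consensus_percent(method_calls: dict, truth_call) -> float:
    """Percentage of the five predictors agreeing with the binarized truth.

    ``method_calls`` must contain one call per predictor method
    (:data:`~amylir.fixtures.PREDICTOR_METHODS`).

    Raises
    ------
    KeyError
        Naming the first missing predictor.
    """
    for m in PREDICTOR_METHODS:
        if m not in method_calls:
            raise KeyError(f"missing predictor call: {m}")
    t = binarize(truth_call)
    agree = sum(binarize(method_calls[m]) == t for m in PREDICTOR_METHODS)
    return 100.0 * agree / len(PREDICTOR_METHODS)


@dataclass(frozen=True)
class MisannotationReport:
    """Audit of database labels against adjudicated truth.

    ``n_false_positive_labels`` counts peptides the database calls amyloid
    while the truth is negative; ``n_false_negative_labels`` the reverse.
    ``misannotated_among_true_negatives`` / ``..._positives`` are the
    per-truth-class misannotation fractions (``None`` if a class is empty).
    """

    n_total: int
    n_false_positive_labels: int
    n_false_negative_labels: int
    n_true_negatives_total: int
    n_true_positives_total: int

    @property
    def n_misannotated(self) -> int:
        return self.n_false_positive_labels + self.n_false_negative_labels

    @property
    def misannotated_among_true_negatives(self) -> Fraction | None:
        if self.n_true_negatives_total == 0:
            return None
        return Fraction(self.n_false_positive_labels, self.n_true_negatives_total)

    @property
    def misannotated_among_true_positives(self) -> Fraction | None:
        if self.n_true_positives_total == 0:
            return None
        return Fraction(self.n_false_negative_labels, self.n_true_positives_total)


def misannotation_audit(db_calls: dict, truth_calls: dict) -> MisannotationReport:
    """Count database labels contradicted by the adjudicated truth.

    Raises
    ------
    ValueError
        If the id intersection is empty.
    """
    ids = [i for i in truth_calls if i in db_calls]
    if not ids:
        raise ValueError("no peptides shared between database and truth calls")
    fp = fn = npos = nneg = 0
    for i in ids:
        db, t = binarize(db_calls[i]), binarize(truth_calls[i])
        if t:
            npos += 1
            if not db:
                fn += 1
        else:
            nneg += 1
            if db:
                fp += 1
    return MisannotationReport(
        n_total=len(ids),
        n_false_positive_labels=fp,
        n_false_negative_labels=fn,
        n_true_negatives_total=nneg,
        n_true_positives_total=npos,
    )


def band_rule_calls(
    fixture: str = "test_set",
    mode: str = "ir_microscopy",
    config: RuleConfig | None = None,
) -> dict:
    """Classify each fixture peptide's band list; map id -> SpectralCall."""
    df = load_fixture(fixture)
    return {
        row["id"]: classify_bands(row[f"{mode}_band_list"], config)
        for _, row in df.iterrows()
    }


def _calls_frame(fixture_set: str) -> pd.DataFrame:
    name = {"reference": "predictor_calls_reference", "test": "predictor_calls_test"}[
        fixture_set
    ]
    return load_fixture(name)


def reproduce_audit_tables(
    fixture_set: str = "test", restrict_to_misannotated: bool = False
) -> pd.DataFrame:
    """Recompute per-predictor Acc/Sn/Sp against the IR-microscopy truth.

    With ``restrict_to_misannotated`` the comparison is limited to the
    peptides whose database label the audit flags as wrong (the test-set
    subset of 17).  Returns one row per predictor with exact counts and
    two-decimal display values.
    """
    df = _calls_frame(fixture_set)
    truth = dict(zip(df["id"], df["ir_microscopy_call"]))
    if restrict_to_misannotated:
        if "database_call" not in df:
            raise ValueError(f"{fixture_set!r} fixture carries no database column")
        db = dict(zip(df["id"], df["database_call"]))
        keep = {i for i in truth if binarize(db[i]) != binarize(truth[i])}
        if not keep:
            raise ValueError("no misannotated peptides in this fixture")
        truth = {i: c for i, c in truth.items() if i in keep}
    rows = []
    for method in PREDICTOR_METHODS:
        preds = dict(zip(df["id"], df[f"{method}_call"]))
        stats = confusion_stats(preds, truth)
        rows.append({"method": method, **stats.rounded(), "tp": stats.tp,
                     "tn": stats.tn, "fp": stats.fp, "fn": stats.fn, "n": stats.n})
    return pd.DataFrame(rows).set_index("method")


def reproduce_consensus(fixture_set: str = "test") -> pd.DataFrame:
    """Recompute each peptide's predictor-consensus percentage.

    Returns columns ``consensus`` (recomputed), ``printed`` (the fixture's
    printed value) and ``anomaly`` (True where the source table is known
    to contradict its own definition, and the printed value is kept
    verbatim rather than asserted).
    """
    df = _calls_frame(fixture_set)
    out = []
    for _, row in df.iterrows():
        calls = {m: row[f"{m}_call"] for m in PREDICTOR_METHODS}
        out.append(
            {
                "id": row["id"],
                "consensus": consensus_percent(calls, row["ir_microscopy_call"]),
                "printed": float(row["consensus_with_ir"]),
                "anomaly": bool(row["consensus_anomaly"]),
            }
        )
    return pd.DataFrame(out).set_index("id")
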