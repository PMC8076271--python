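"""Domain records, packaged experiment tables, and FASTA round-tripping.

The package ships four machine-readable tables describing 34 hexapeptides
(10 *reference*, 24 *test*): their database annotations, the component-band
lists read from two infrared modes (transmission-mode FTIR microscopy and
ATR-FTIR), atomic-force-microscopy calls where available, and the
amyloid/non-amyloid calls of five sequence-based predictors.  These tables
are the desk-scale ground truth every audit in :mod:`amylir.concordance`
recomputes from.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bands import BandAnnotation, parse_band_string

__all__ = [
    "AMINO_ACIDS",
    "PeptideRecord",
    "MethodCall",
    "FIXTURE_NAMES",
    "METHODS",
    "load_fixture",
    "peptide_records",
    "normalize_call",
    "write_fasta",
    "read_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Annotation sources a call may come from.
METHODS = (
    "database",
    "ir_microscopy",
    "atr_ftir",
    "afm",
    "amylogram",
    "path_lr",
    "path_rf",
    "foldamyloid",
    "pasta2",
)

#: Sequence-based predictors scored in the concordance audit.
PREDICTOR_METHODS = ("amylogram", "path_lr", "path_rf", "foldamyloid", "pasta2")

FIXTURE_NAMES = (
    "reference_set",
    "test_set",
    "predictor_calls_reference",
    "predictor_calls_test",
)

_CALL_ALIASES = {
    "yes": "positive",
    "no": "negative",
    "yes*": "oligomer",
}


def normalize_call(raw: str) -> str:
    """Map a printed cell ('Yes', 'NO', 'Yes*', ...) to a canonical call.

    Returns one of ``positive``, ``negative``, ``oligomer``.  Case is
    ignored: the source tables print a handful of cells as 'NO'/'no'/'YES'.
    """
    key = str(raw).strip().lower()
    if key in ("positive", "negative", "oligomer"):
        return key
    try:
        return _CALL_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognized call {raw!r}") from None


@dataclass(frozen=True)
class PeptideRecord:
    """A hexapeptide with its database annotation and provenance."""

    id: str
    sequence: str
    db_label: str  # "amyloid" | "non_amyloid"
    origin: str = "other"  # "amylhex" | "other" | "synthetic"
    subset: str = "none"  # "reference" | "test" | "none"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-standard residues {sorted(bad)} in {self.sequence!r}")
        if self.db_label not in ("amyloid", "non_amyloid"):
            raise ValueError(f"bad db_label {self.db_label!r}")
        if self.origin not in ("amylhex", "other", "synthetic"):
            raise ValueError(f"bad origin {self.origin!r}")
        if self.subset not in ("reference", "test", "none"):
            raise ValueError(f"bad subset {self.subset!r}")


@dataclass(frozen=True)
class MethodCall:
    """One method's amyloid call for one peptide."""

    peptide_id: str
    method: str
    call: str  # "positive" | "negative" | "oligomer"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.call not in ("positive", "negative", "oligomer"):
            raise ValueError(f"bad call {self.call!r}")
        if self.call == "oligomer" and self.method not in (
            "ir_microscopy",
            "atr_ftir",
            "afm",
        ):
            raise ValueError("oligomer calls only come from experimental methods")


def _data_path(name: str) -> Path:
    return Path(str(resources.files("amylir").joinpath("data", f"{name}.tsv")))


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged table as a DataFrame.

    ``reference_set`` / ``test_set`` gain parsed columns
    ``ir_microscopy_band_list`` / ``atr_ftir_band_list`` (lists of
    :class:`~amylir.bands.BandAnnotation`) and normalized ``*_call`` columns;
    predictor tables gain one normalized ``*_call`` column per method.

    Raises
    ------
    KeyError
        If ``name`` is not one of :data:`FIXTURE_NAMES`.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")
    df = pd.read_csv(_data_path(name), sep="\t", comment="#", dtype=str)
    df["consensus_anomaly"] = (
        df["consensus_anomaly"].astype(int).astype(bool)
        if "consensus_anomaly" in df
        else False
    )
    if name in ("reference_set", "test_set"):
        df["db_call"] = df["db_label"].map(normalize_call)
        for mode in ("ir_microscopy", "atr_ftir"):
            df[f"{mode}_band_list"] = df[f"{mode}_bands"].map(parse_band_string)
            df[f"{mode}_call"] = df[f"{mode}_class"].map(normalize_call)
        if "afm_class" in df:
            df["afm_call"] = df["afm_class"].map(normalize_call)
    else:
        for col in ("database", "ir_microscopy", *PREDICTOR_METHODS):
            if col in df:
                df[f"{col}_call"] = df[col].map(normalize_call)
        df["consensus_with_ir"] = df["consensus_with_ir"].astype(int)
    return df


def peptide_records(df: pd.DataFrame, subset: str = "none") -> list[PeptideRecord]:
    """Materialize :class:`PeptideRecord` objects from a band-table fixture."""
    label = {"positive": "amyloid", "negative": "non_amyloid"}
    return [
        PeptideRecord(
            id=row["id"],
            sequence=row["sequence"],
            db_label=label[normalize_call(row["db_label"])],
            origin="other",
            subset=subset,
        )
        for _, row in df.iterrows()
    ]


def write_fasta(peptides: Iterable[PeptideRecord], destination) -> int:
    """Write peptides as FASTA (id as header); returns the record count.

    Raises
    ------
    ValueError
        On duplicate peptide ids.
    """
    peptides = list(peptides)
    ids = [p.id for p in peptides]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate peptide ids: {dupes}")
    records = [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in peptides]
    return SeqIO.write(records, str(destination), "fasta")


def read_fasta(source, db_label: str = "non_amyloid", origin: str = "other") -> list[PeptideRecord]:
    """Read peptides from FASTA into records with a uniform provisional label."""
    return [
        PeptideRecord(id=rec.id, sequence=str(rec.seq).upper(), db_label=db_label, origin=origin)
        for rec in SeqIO.parse(str(source), "fasta")
    ]
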