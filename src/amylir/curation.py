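"""Dataset curation and a surrogate sequence predictor with confidence-based
outlier / reference selection.

The curation procedure mirrors how weakly labeled amyloid hexapeptide
collections are prepared: keep clean hexapeptides, split by dataset origin
(the early AmylHex collection carries a method bias, so it is handled as
its own stratum), re-express sequences in a reduced amino-acid alphabet,
and collapse encoded duplicates.  A tree-ensemble classifier over n-gram
counts of the reduced alphabet then scores every peptide; peptides whose
predicted class contradicts their database label with high confidence are
*outliers* (candidate misannotations), and confident agreements are
*references*.

The reduced alphabet shipped as default is a surrogate six-group
physicochemical grouping, not the alphabet of any published predictor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .fixtures import AMINO_ACIDS, PeptideRecord

__all__ = [
    "ReducedAlphabet",
    "DEFAULT_ALPHABET",
    "identity_alphabet",
    "PredictorProbability",
    "filter_hexapeptides",
    "split_by_origin",
    "encode_reduced",
    "deduplicate_encoded",
    "ngram_feature_names",
    "ngram_features",
    "feature_matrix",
    "oof_probabilities",
    "select_outliers",
    "select_references",
]


@dataclass(frozen=True)
class ReducedAlphabet:
    """Total mapping of the 20 standard residues onto group symbols."""

    name: str
    mapping: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        m = dict(self.mapping)
        missing = set(AMINO_ACIDS) - set(m)
        if missing:
            raise ValueError(f"alphabet {self.name!r} misses residues {sorted(missing)}")
        object.__setattr__(self, "mapping", tuple(sorted(m.items())))

    @property
    def map(self) -> dict[str, str]:
        return dict(self.mapping)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(g for _, g in self.mapping)))

    @classmethod
    def from_dict(cls, name: str, mapping: dict[str, str]) -> "ReducedAlphabet":
        return cls(name=name, mapping=tuple(mapping.items()))

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "ReducedAlphabet":
        """Load a two-column (residue, group) TSV."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["residue", "group"])
        return cls.from_dict(name or str(path), dict(zip(df["residue"], df["group"])))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.mapping).to_csv(path, sep="\t", header=False, index=False)


#: Surrogate six-group physicochemical alphabet: aliphatic hydrophobic (A),
#: aromatic (F), polar uncharged (S), basic (K), acidic (D), special (G).
DEFAULT_ALPHABET = ReducedAlphabet.from_dict(
    "hydro6",
    {
        **{r: "A" for r in "AVLIMC"},
        **{r: "F" for r in "FWY"},
        **{r: "S" for r in "STNQ"},
        **{r: "K" for r in "KRH"},
        **{r: "D" for r in "DE"},
        **{r: "G" for r in "GP"},
    },
)


def identity_alphabet() -> ReducedAlphabet:
    return ReducedAlphabet.from_dict("identity", {r: r for r in AMINO_ACIDS})


def filter_hexapeptides(records):
    """Keep exactly the length-6 sequences over the 20 standard residues.

    Accepts :class:`PeptideRecord` objects or raw sequence strings (raw
    input is how unvalidated database exports arrive); filtering, not
    validation — no errors on odd entries.
    """
    def seq(item):
        return item if isinstance(item, str) else item.sequence

    return [r for r in records if len(seq(r)) == 6 and set(seq(r)) <= set(AMINO_ACIDS)]


def split_by_origin(records: list[PeptideRecord]):
    """Partition records into (AmylHex-derived, other-origin), order-preserving."""
    amylhex = [r for r in records if r.origin == "amylhex"]
    other = [r for r in records if r.origin != "amylhex"]
    return amylhex, other


def encode_reduced(sequence: str, alphabet: ReducedAlphabet) -> str:
    """Positionwise image of ``sequence`` under the reduced alphabet."""
    m = alphabet.map
    try:
        return "".join(m[r] for r in sequence)
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} not in alphabet {alphabet.name!r}") from None


def deduplicate_encoded(records: list[PeptideRecord], alphabet: ReducedAlphabet):
    """Collapse records sharing an encoded form; drop label conflicts.

    Returns ``(kept, conflicts)``: one representative (first occurrence)
    per (encoded form, label); encoded forms carrying both labels are
    removed from both classes and reported in ``conflicts`` as dicts with
    keys ``encoded``, ``ids``, ``labels``.
    """
    groups: dict[str, list[PeptideRecord]] = {}
    for r in records:
        groups.setdefault(encode_reduced(r.sequence, alphabet), []).append(r)
    kept: list[PeptideRecord] = []
    conflicts: list[dict] = []
    for r in records:  # preserve input order for representatives
        enc = encode_reduced(r.sequence, alphabet)
        members = groups.get(enc)
        if members is None:
            continue
        labels = {m.db_label for m in members}
        if len(labels) > 1:
            conflicts.append(
                {"encoded": enc, "ids": [m.id for m in members], "labels": sorted(labels)}
            )
        else:
            kept.append(members[0])
        del groups[enc]
    return kept, conflicts


def ngram_feature_names(alphabet: ReducedAlphabet, max_n: int = 2) -> list[str]:
    """Fixed feature ordering: n ascending, grams lexicographic per n."""
    names = []
    for n in range(1, max_n + 1):
        names += ["".join(t) for t in itertools.product(alphabet.groups, repeat=n)]
    return names


def ngram_features(
    sequence: str, alphabet: ReducedAlphabet, max_n: int = 2
) -> np.ndarray:
    """Counts of contiguous n-grams (n = 1..max_n) of the encoded sequence.

    Raises
    ------
    ValueError
        If ``max_n`` exceeds the sequence length (the gram set is empty).
    """
    encoded = encode_reduced(sequence, alphabet)
    if max_n > len(encoded):
        raise ValueError(f"max_n={max_n} exceeds sequence length {len(encoded)}")
    index = {name: i for i, name in enumerate(ngram_feature_names(alphabet, max_n))}
    vec = np.zeros(len(index))
    for n in range(1, max_n + 1):
        for i in range(len(encoded) - n + 1):
            vec[index[encoded[i : i + n]]] += 1
    return vec


def feature_matrix(
    sequences, alphabet: ReducedAlphabet | None = None, max_n: int = 2
) -> np.ndarray:
    alphabet = alphabet or DEFAULT_ALPHABET
    return np.vstack([ngram_features(s, alphabet, max_n) for s in sequences])


@dataclass(frozen=True)
class PredictorProbability:
    """A peptide's predicted amyloid probability and how it was obtained."""

    peptide_id: str
    p_amyloid: float
    provenance: str  # "in_fit" | "out_of_fold" | "external_fixture"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_amyloid <= 1.0):
            raise ValueError("p_amyloid must lie in [0, 1]")
        if self.provenance not in ("in_fit", "out_of_fold", "external_fixture"):
            raise ValueError(f"bad provenance {self.provenance!r}")


def _default_learner(seed: int):
    return RandomForestClassifier(n_estimators=200, random_state=seed)


def oof_probabilities(
    sequences,
    labels,
    ids=None,
    k_folds: int = 5,
    seed: int = 0,
    learner=None,
    alphabet: ReducedAlphabet | None = None,
    max_n: int = 2,
    mode: str = "out_of_fold",
) -> list[PredictorProbability]:
    """Score each peptide's amyloid probability with a cross-fitted model.

    ``labels`` are ``"amyloid"`` / ``"non_amyloid"`` observed (database)
    labels.  With ``mode="out_of_fold"`` (default) each peptide is scored
    by a model fitted without its stratified fold, so memorized labels
    cannot mask outliers; ``mode="in_fit"`` scores the training data with
    the model fitted on all of it.  ``learner`` is any classifier with
    ``fit`` / ``predict_proba`` (tree ensemble by default).  Deterministic
    under ``seed``.

    Raises
    ------
    ValueError
        If fewer than ``2 * k_folds`` records are given, or a training
        fold ends up single-class (use fewer folds or stratify upstream).
    """
    sequences = list(sequences)
    y = np.asarray([1 if l == "amyloid" else 0 for l in labels])
    if ids is None:
        ids = [f"p{i}" for i in range(len(sequences))]
    if len(sequences) != len(y) or len(ids) != len(y):
        raise ValueError("sequences, labels and ids must be aligned")
    if len(sequences) < 2 * k_folds:
        raise ValueError(f"need at least {2 * k_folds} records for {k_folds}-fold scoring")
    X = feature_matrix(sequences, alphabet, max_n)
    learner = learner if learner is not None else _default_learner(seed)
    if mode == "in_fit":
        model = learner.fit(X, y)
        p = _positive_proba(model, X)
        return [PredictorProbability(i, float(pi), "in_fit") for i, pi in zip(ids, p)]
    if mode != "out_of_fold":
        raise ValueError(f"unknown mode {mode!r}")
    from sklearn.base import clone

    p = np.full(len(y), np.nan)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train, test in skf.split(X, y):
        if np.unique(y[train]).size < 2:
            raise ValueError(
                "single-class training fold; reduce k_folds or stratify the input"
            )
        model = clone(learner).fit(X[train], y[train])
        p[test] = _positive_proba(model, X[test])
    return [PredictorProbability(i, float(pi), "out_of_fold") for i, pi in zip(ids, p)]


def _positive_proba(model, X) -> np.ndarray:
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    return proba[:, classes.index(1)]


def _confidence_table(probs: list[PredictorProbability], labels) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "id": [p.peptide_id for p in probs],
            "p_amyloid": [p.p_amyloid for p in probs],
            "provenance": [p.provenance for p in probs],
            "observed_label": list(labels),
        }
    )
    if len(df) != len(probs):
        raise ValueError("labels must align with probabilities")
    return df


def select_outliers(
    probs: list[PredictorProbability],
    labels,
    tau: float = 0.9,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Peptides whose prediction contradicts their label with confidence.

    A peptide is an outlier when ``p_amyloid >= tau`` but its observed
    label is non-amyloid, or ``p_amyloid <= 1 - tau`` but its label is
    amyloid.  Output is sorted by disagreement confidence, descending.
    With ``top_k`` set, the ``tau`` cutoff is ignored and the ``top_k``
    most confidently contradicted peptides are returned instead.

    Raises
    ------
    ValueError
        If ``tau <= 0.5`` (everything would qualify).
    """
    if not 0.5 < tau <= 1.0:
        raise ValueError("tau must lie in (0.5, 1]")
    df = _confidence_table(probs, labels)
    df["confidence"] = np.where(
        df["observed_label"] == "non_amyloid", df["p_amyloid"], 1 - df["p_amyloid"]
    )
    df = df.sort_values("confidence", ascending=False, kind="stable")
    if top_k is not None:
        return df.head(top_k).reset_index(drop=True)
    return df[df["confidence"] >= tau].reset_index(drop=True)


def select_references(
    probs: list[PredictorProbability],
    labels,
    tau: float = 0.9,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Peptides whose prediction confidently agrees with their label.

    Mirror image of :func:`select_outliers`; sorted by agreement
    confidence, descending.
    """
    if not 0.5 < tau <= 1.0:
        raise ValueError("tau must lie in (0.5, 1]")
    df = _confidence_table(probs, labels)
    df["confidence"] = np.where(
        df["observed_label"] == "amyloid", df["p_amyloid"], 1 - df["p_amyloid"]
    )
    df = df.sort_values("confidence", ascending=False, kind="stable")
    if top_k is not None:
        return df.head(top_k).reset_index(drop=True)
    return df[df["confidence"] >= tau].reset_index(drop=True)
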