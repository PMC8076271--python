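"""Curation filters, reduced-alphabet encoding and the surrogate predictor."""

import numpy as np
import pytest

from amylir.curation import (
    DEFAULT_ALPHABET,
    ReducedAlphabet,
    deduplicate_encoded,
    encode_reduced,
    feature_matrix,
    filter_hexapeptides,
    identity_alphabet,
    ngram_feature_names,
    ngram_features,
    oof_probabilities,
    select_outliers,
    select_references,
    split_by_origin,
)
from amylir.fixtures import AMINO_ACIDS, PeptideRecord, load_fixture, peptide_records
from amylir.synthetic import LabelNoiseConfig, simulate_peptide_dataset

TOY = ReducedAlphabet.from_dict(
    "toy3",
    {**{r: "H" for r in "AVLIMCFWYG"}, **{r: "P" for r in "STNQP"},
     **{r: "C" for r in "KRHDE"}},
)


def rec(seq, label="amyloid", origin="other", id=None):
    return PeptideRecord(id or seq, seq, label, origin)


class TestFilters:
    def test_length_and_alphabet_rule(self):
        assert filter_hexapeptides(["FNPQGG", "FNPQG", "FNPXGG"]) == ["FNPQGG"]

    def test_empty_input(self):
        assert filter_hexapeptides([]) == []

    def test_all_34_fixture_peptides_kept(self):
        records = peptide_records(load_fixture("reference_set")) + peptide_records(
            load_fixture("test_set")
        )
        assert len(filter_hexapeptides(records)) == 34

    def test_split_by_origin_partitions(self):
        records = [rec("AAAAAA", origin="amylhex"), rec("CCCCCC"),
                   rec("DDDDDD", origin="amylhex", id="d"), rec("EEEEEE"),
                   rec("FFFFFF", origin="synthetic")]
        amylhex, other = split_by_origin(records)
        assert len(amylhex) + len(other) == 5
        assert [r.sequence for r in amylhex] == ["AAAAAA", "DDDDDD"]
        assert "FFFFFF" in [r.sequence for r in other]  # synthetic routes to other


class TestEncoding:
    def test_toy_mapping(self):
        assert encode_reduced("LVFYQQ", TOY) == "HHHHPP"

    def test_identity_alphabet_is_identity(self):
        assert encode_reduced("FNPQGG", identity_alphabet()) == "FNPQGG"

    def test_unknown_letter_rejected(self):
        with pytest.raises(ValueError):
            encode_reduced("LVFYQ?", TOY)

    def test_default_alphabet_total_over_20_residues(self):
        assert set(DEFAULT_ALPHABET.map) == set(AMINO_ACIDS)
        assert len(DEFAULT_ALPHABET.groups) == 6

    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "alpha.tsv"
        DEFAULT_ALPHABET.to_tsv(path)
        back = ReducedAlphabet.from_tsv(path, "hydro6")
        assert back.map == DEFAULT_ALPHABET.map


class TestDeduplicate:
    def test_same_label_duplicates_collapse(self):
        records = [rec("LVFYQQ"), rec("IVFYQQ", id="x")]  # same toy encoding
        kept, conflicts = deduplicate_encoded(records, TOY)
        assert len(kept) == 1 and conflicts == []

    def test_conflicting_labels_dropped_and_reported(self):
        records = [rec("LVFYQQ", "amyloid"), rec("IVFYQQ", "non_amyloid", id="x")]
        kept, conflicts = deduplicate_encoded(records, TOY)
        assert kept == [] and len(conflicts) == 1
        assert conflicts[0]["labels"] == ["amyloid", "non_amyloid"]

    def test_matches_brute_force_pairwise_scan(self):
        """Oracle: O(n^2) duplicate scan on a 200-record synthetic set."""
        df = simulate_peptide_dataset(LabelNoiseConfig(200, 0.0, 4.0, seed=9))
        records = [
            PeptideRecord(i, s, l)
            for i, s, l in zip(df["id"], df["sequence"], df["true_label"])
        ]
        kept, conflicts = deduplicate_encoded(records, TOY)
        enc = [encode_reduced(r.sequence, TOY) for r in records]
        groups = {}
        for r, e in zip(records, enc):
            groups.setdefault(e, []).append(r)
        expected_conflicts = sum(
            1 for g in groups.values() if len({r.db_label for r in g}) > 1
        )
        expected_kept = sum(
            1 for g in groups.values() if len({r.db_label for r in g}) == 1
        )
        assert len(conflicts) == expected_conflicts
        assert len(kept) == expected_kept


class TestNgrams:
    def test_counts_for_repeated_symbol(self):
        alpha = ReducedAlphabet.from_dict("toy", {r: "H" for r in AMINO_ACIDS})
        vec = ngram_features("AAA", alpha, max_n=2)
        names = ngram_feature_names(alpha, max_n=2)
        assert dict(zip(names, vec)) == {"H": 3, "HH": 2}

    def test_unigram_counts_sum_to_length(self):
        vec = ngram_features("FNPQGG", DEFAULT_ALPHABET, max_n=1)
        assert vec.sum() == 6

    def test_max_n_beyond_length_rejected(self):
        with pytest.raises(ValueError):
            ngram_features("AAA", DEFAULT_ALPHABET, max_n=4)


@pytest.fixture(scope="module")
def separable():
    """Noise-free dataset under a near-deterministic planted rule."""
    return simulate_peptide_dataset(LabelNoiseConfig(1000, 0.0, 25.0, seed=4))


class TestOofProbabilities:

    def test_separable_data_scored_accurately_out_of_fold(self, separable):
        probs = oof_probabilities(separable["sequence"], separable["true_label"],
                                  ids=list(separable["id"]), seed=1)
        pred = np.array([p.p_amyloid > 0.5 for p in probs])
        truth = (separable["true_label"] == "amyloid").to_numpy()
        assert (pred == truth).mean() > 0.9
        assert all(p.provenance == "out_of_fold" for p in probs)

    def test_shuffled_labels_give_uninformative_probabilities(self):
        df = simulate_peptide_dataset(LabelNoiseConfig(1000, 0.0, 4.0, seed=6))
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(df["true_label"].to_numpy())
        probs = oof_probabilities(df["sequence"], shuffled, seed=2)
        p = np.array([x.p_amyloid for x in probs])
        amyloid = shuffled == "amyloid"
        assert abs(p[amyloid].mean() - p[~amyloid].mean()) < 0.1

    def test_deterministic_under_seed(self, separable):
        a = oof_probabilities(separable["sequence"], separable["true_label"], seed=3)
        b = oof_probabilities(separable["sequence"], separable["true_label"], seed=3)
        assert [x.p_amyloid for x in a] == [x.p_amyloid for x in b]

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            oof_probabilities(["AAAAAA"] * 8, ["amyloid"] * 4 + ["non_amyloid"] * 4,
                              k_folds=5)


class TestSelection:
    def probs(self, values):
        from amylir.curation import PredictorProbability

        return [PredictorProbability(f"p{i}", v, "out_of_fold")
                for i, v in enumerate(values)]

    def test_confident_contradiction_is_outlier(self):
        out = select_outliers(self.probs([0.95]), ["non_amyloid"], tau=0.9)
        assert list(out["id"]) == ["p0"]

    def test_confident_agreement_is_reference(self):
        ref = select_references(self.probs([0.95]), ["amyloid"], tau=0.9)
        assert list(ref["id"]) == ["p0"]
        assert select_outliers(self.probs([0.95]), ["amyloid"], tau=0.9).empty

    def test_low_confidence_is_neither(self):
        assert select_outliers(self.probs([0.6]), ["non_amyloid"], tau=0.9).empty
        assert select_references(self.probs([0.6]), ["amyloid"], tau=0.9).empty

    def test_tau_at_half_or_below_rejected(self):
        with pytest.raises(ValueError):
            select_outliers(self.probs([0.9]), ["amyloid"], tau=0.5)

    def test_outliers_and_references_disjoint_and_monotone_in_tau(self):
        rng = np.random.default_rng(5)
        p = self.probs(rng.random(100))
        labels = list(rng.choice(["amyloid", "non_amyloid"], 100))
        prev_out = prev_ref = None
        for tau in (0.6, 0.75, 0.9, 0.99):
            out = set(select_outliers(p, labels, tau)["id"])
            ref = set(select_references(p, labels, tau)["id"])
            assert out & ref == set()
            if prev_out is not None:
                assert out <= prev_out and ref <= prev_ref
            prev_out, prev_ref = out, ref

    def test_top_k_ranking_mode(self):
        p = self.probs([0.99, 0.8, 0.6])
        out = select_outliers(p, ["non_amyloid"] * 3, tau=0.9, top_k=2)
        assert list(out["id"]) == ["p0", "p1"]
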