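"""Sentence splitting, intake features, per-user scaling, RF aggregation,
co-consumption."""

import numpy as np
import pytest

from forumvigil import resources
from forumvigil.corpus import KeywordTable
from forumvigil.intake import (
    DrugList,
    IntakeModel,
    detect_coconsumption,
    extract_intake_features,
    load_intake_lexicon,
    predict_intake,
    scale_features_per_user,
    sentence_records,
    split_sentences,
)

from conftest import make_clean


@pytest.fixture(scope="module")
def table():
    return KeywordTable.from_tsv(resources.path(resources.KEYWORDS))


@pytest.fixture(scope="module")
def drugs():
    return DrugList.from_tsv(resources.path(resources.DRUGS))


@pytest.fixture(scope="module")
def lexicons():
    return load_intake_lexicon(resources.path(resources.INTAKE_LEXICON))


class TestSplitSentences:
    def test_two_sentences(self):
        spans = split_sentences("J'ai mal. J'ai pris doliprane!")
        assert len(spans) == 2

    def test_no_terminal_punctuation_single(self):
        assert len(split_sentences("pas de ponctuation finale")) == 1

    @pytest.mark.parametrize(
        "text",
        [
            "Un. Deux! Trois?",
            "M. Dupont est venu. Il va bien.",
            "dose de 10.5 mg par jour. ensuite rien",
            "sans fin",
            "",
        ],
    )
    def test_spans_reconstruct_text(self, text):
        spans = split_sentences(text)
        assert "".join(text[s:e] for s, e in spans) == text

    def test_abbreviation_not_split(self):
        assert len(split_sentences("M. Dupont est venu hier soir")) == 1


class TestFeatures:
    def test_lexicon_hits(self, table, drugs, lexicons):
        post = make_clean("j'ai pris du doliprane")
        rec = sentence_records(post, table, drugs)[0]
        f = extract_intake_features(rec, *lexicons)
        assert f.intake_lexicon_hits == 1
        assert f.nonintake_lexicon_hits == 0

    def test_exclamation_proportion_hand_count(self, table, drugs, lexicons):
        # "doliprane???!!!": 15 non-space characters, 3 of them '!'
        post = make_clean("doliprane???!!!")
        rec = sentence_records(post, table, drugs)[0]
        f = extract_intake_features(rec, *lexicons)
        assert f.exclamation_proportion == pytest.approx(3 / 15)
        assert f.exclamation_proportion == pytest.approx(2 / 10)

    def test_drug_position_undefined_without_drug(self, lexicons):
        post = make_clean("aucun produit mentionne ici")
        rec = sentence_records(post)[0]
        f = extract_intake_features(rec, *lexicons)
        assert f.drug_position is None

    def test_drug_position_relative(self, table, drugs, lexicons):
        post = make_clean("hier soir doliprane")
        rec = sentence_records(post, table, drugs)[0]
        f = extract_intake_features(rec, *lexicons)
        assert f.drug_position == pytest.approx(1.0)


class TestScaling:
    def test_single_sentence_user_all_zero(self):
        X = np.array([[3.0, 1.0, 0.5]])
        assert np.allclose(scale_features_per_user(X, ["u1"]), 0.0)

    def test_volume_invariance_of_relative_patterns(self):
        base = np.array([[1.0, 0.0], [2.0, 1.0], [3.0, 2.0]])
        X = np.vstack([base, np.tile(base, (3, 1))])
        users = ["a"] * 3 + ["b"] * 9
        scaled = scale_features_per_user(X, users)
        assert np.allclose(scaled[:3], scaled[3:6])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        users = ["u1"] * 5 + ["u2"] * 5
        once = scale_features_per_user(X, users)
        assert np.allclose(scale_features_per_user(once, users), once)

    def test_zero_variance_column_maps_to_zero(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0]])
        scaled = scale_features_per_user(X, ["u", "u"])
        assert np.allclose(scaled[:, 0], 0.0)


class TestModel:
    def _training_data(self, rng, n=120):
        X = rng.normal(size=(n, 3))
        y = X[:, 0] > 0
        return X, y

    def test_single_class_training_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="single class"):
            IntakeModel(n_estimators=10).fit(X, [True] * 5)

    def test_post_aggregation_any_positive(self, table, drugs, lexicons):
        rng = np.random.default_rng(0)
        X, y = self._training_data(rng)
        model = IntakeModel(n_estimators=50, seed=0).fit(X, y)
        post = make_clean("Phrase un. Phrase deux. Phrase trois.", post_id="p9")
        records = sentence_records(post, table, drugs)
        pos = np.array([[2.0, 0, 0], [-2.0, 0, 0], [-2.0, 0, 0]])
        pred = predict_intake(model, records, pos)
        assert pred.post_intake["p9"] is True
        neg = np.array([[-2.0, 0, 0]] * 3)
        pred = predict_intake(model, records, neg)
        assert pred.post_intake["p9"] is False

    def test_monotone_adding_positive_sentence(self, table, drugs, lexicons):
        rng = np.random.default_rng(1)
        X, y = self._training_data(rng)
        model = IntakeModel(n_estimators=50, seed=0).fit(X, y)
        post = make_clean("Un. Deux.", post_id="p")
        records = sentence_records(post, table, drugs)
        base = np.array([[2.0, 0, 0], [-2.0, 0, 0]])
        assert predict_intake(model, records, base).post_intake["p"] is True


class TestCoconsumption:
    def test_restricted_to_intake_posts(self, table, drugs):
        posts = [
            make_clean("j'ai pris doliprane et tramadol", post_id="p1"),
            make_clean("doliprane et tramadol dans l'armoire", post_id="p2"),
        ]
        res = detect_coconsumption(posts, {"p1": True, "p2": False}, drugs, table)
        assert res.post_counts == {"tramadol": 1}
        assert res.n_intake_posts == 1
        assert res.user_pairs == {("u1", "tramadol")}

    def test_toy_ratio(self, table, drugs):
        posts = [
            make_clean(f"doliprane pris avec ibuprofene {i}", post_id=f"a{i}")
            for i in range(3)
        ] + [make_clean(f"doliprane seul {i}", post_id=f"b{i}") for i in range(4)]
        intake = {p.post_id: True for p in posts}
        res = detect_coconsumption(posts, intake, drugs, table)
        assert res.post_counts["ibuprofen"] == 3
        assert res.n_intake_posts == 7

    def test_counts_never_exceed_denominator(self, table, drugs):
        posts = [
            make_clean(f"doliprane avec tramadol et tramadol {i}", post_id=f"p{i}")
            for i in range(5)
        ]
        res = detect_coconsumption(posts, {p.post_id: True for p in posts}, drugs, table)
        assert all(c <= res.n_intake_posts for c in res.post_counts.values())

    def test_paracetamol_products_not_counted_as_codrug(self, table, drugs):
        posts = [make_clean("dafalgan codeine pris hier", post_id="p1")]
        res = detect_coconsumption(posts, {"p1": True}, drugs, table)
        assert "codeine" not in res.post_counts
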