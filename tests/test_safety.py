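"""Child exclusion, PAE features, BM25 dependence scoring, overdose parsing,
unapproved indications."""

import math

import numpy as np
import pytest

from forumvigil import resources
from forumvigil._match import DictionaryMatcher
from forumvigil._text import tokenize
from forumvigil.concepts import load_dictionary, tag_concepts
from forumvigil.corpus import KeywordTable
from forumvigil.safety import (
    DependenceResult,
    DependenceScorer,
    DoseUnitTable,
    PAEClassifier,
    PAEFeatures,
    SmPCIndex,
    compute_pae_features,
    count_overdose_users,
    detect_overdose,
    filter_child_posts,
    find_unapproved_indications,
    is_child_context,
    parse_daily_doses,
    sample_for_annotation,
)

from conftest import make_clean


@pytest.fixture(scope="module")
def table():
    return KeywordTable.from_tsv(resources.path(resources.KEYWORDS))


@pytest.fixture(scope="module")
def od_matcher():
    from forumvigil.safety import load_term_list

    return DictionaryMatcher(
        (t, None) for t in load_term_list(resources.path(resources.OVERDOSE_LEXICON))
    )


class TestChildFilter:
    def test_child_post_excluded(self):
        assert is_child_context("mon fils de 8 ans a pris doliprane")

    def test_adult_self_use_retained(self):
        assert not is_child_context("j'ai 30 ans, j'ai pris doliprane")

    def test_teenager_and_older_child_retained(self):
        assert not is_child_context("mon fils de 17 ans a pris doliprane")

    def test_infant_without_age_excluded(self):
        assert is_child_context("bébé a pris du doliprane hier soir")

    def test_filter_scope(self):
        posts = [
            make_clean("mon fils de 8 ans a pris doliprane", post_id="c"),
            make_clean("j'ai pris doliprane", post_id="a"),
        ]
        assert [p.post_id for p in filter_child_posts(posts)] == ["a"]


class TestPAE:
    def test_adjacent_tokens_distance_one(self, table):
        post = make_clean("doliprane nausee ce soir")
        mention = tag_concepts(
            post.cleaned_text, load_dictionary(resources.path(resources.CONCEPTS)), "p1"
        )[0]
        spans = [(s, e) for s, e, _c, _b in table.find_mentions(post.cleaned_text)]
        f = compute_pae_features(post, mention, spans, [mention])
        assert f.concept_drug_distance == 1

    def test_hand_tokenized_feature_triple(self, table):
        # "j'ai pris du doliprane et ensuite nausee nausee"
        # tokens: j ai pris du doliprane(4) et ensuite nausee(7) nausee(8)
        post = make_clean("j'ai pris du doliprane et ensuite nausee nausee")
        d = load_dictionary(resources.path(resources.CONCEPTS))
        mentions = tag_concepts(post.cleaned_text, d, "p1")
        spans = [(s, e) for s, e, _c, _b in table.find_mentions(post.cleaned_text)]
        f = compute_pae_features(post, mentions[0], spans, mentions)
        assert f.concept_drug_distance == 3
        assert f.message_length == 9
        assert f.concept_count == 2

    def test_no_drug_mention_is_error(self):
        post = make_clean("nausee sans produit")
        d = load_dictionary(resources.path(resources.CONCEPTS))
        mention = tag_concepts(post.cleaned_text, d, "p1")[0]
        with pytest.raises(ValueError, match="no drug mention"):
            compute_pae_features(post, mention, [], [mention])

    def test_classifier_separates_by_distance(self):
        rng = np.random.default_rng(0)
        pos = [PAEFeatures(int(d), 30, 1) for d in rng.integers(1, 4, 40)]
        neg = [PAEFeatures(int(d), 30, 1) for d in rng.integers(10, 25, 40)]
        clf = PAEClassifier().fit(pos + neg, [True] * 40 + [False] * 40)
        assert clf.predict(PAEFeatures(2, 30, 1))
        assert not clf.predict(PAEFeatures(18, 30, 1))

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            PAEClassifier().fit([PAEFeatures(1, 10, 1)] * 3, [True] * 3)


class TestDependenceBM25:
    def make_toy(self):
        lexicon = ["accro", "manque", "sevrage"]
        posts = [
            make_clean("je suis accro au doliprane et le manque me detruit", post_id="p1"),
            make_clean("le sevrage du doliprane est dur. le doliprane me va bien", post_id="p2"),
            make_clean("bonjour tout le monde sans rapport aucun", post_id="p3"),
        ]
        return lexicon, posts

    def hand_bm25(self, scorer, posts, table):
        """Independent Okapi BM25 computed from first principles."""
        from forumvigil.intake import sentence_records

        all_sents, cand = [], []
        for p in posts:
            for rec in sentence_records(p, table):
                toks = tokenize(rec.text)
                all_sents.append(toks)
                has_drug = bool(rec.drug_mentions)
                has_lex = any(t in ("accro", "manque", "sevrage") for t in toks)
                if has_drug and has_lex:
                    cand.append((p.post_id, toks))
        N = len(all_sents)
        avgdl = sum(len(t) for _pid, t in cand) / len(cand)
        k1, b = 1.2, 0.75
        scores = {}
        for pid, toks in cand:
            s = 0.0
            for term in ("accro", "manque", "sevrage"):
                df = sum(term in sent for sent in all_sents)
                idf = math.log(1 + (N - df + 0.5) / (df + 0.5))
                tf = toks.count(term)
                if tf:
                    s += idf * tf * (k1 + 1) / (tf + k1 * (1 - b + b * len(toks) / avgdl))
            scores[pid] = scores.get(pid, 0.0) + s
        return scores

    def test_matches_hand_oracle_to_1e9(self, table):
        lexicon, posts = self.make_toy()
        scorer = DependenceScorer(lexicon).fit(posts, table)
        expected = self.hand_bm25(scorer, posts, table)
        for p in posts:
            res = scorer.score_post(p, table)
            assert res.message_score == pytest.approx(expected.get(p.post_id, 0.0), abs=1e-9)

    def test_no_lexicon_word_scores_zero(self, table):
        lexicon, posts = self.make_toy()
        scorer = DependenceScorer(lexicon).fit(posts, table)
        res = scorer.score_post(posts[2], table)
        assert res.message_score == 0.0
        assert res.candidate_sentences == ()
        assert not res.flagged

    def test_threshold_inclusive_at_40(self):
        exactly = DependenceResult("p", "u", (0,), (40.0,), 40.0, 40.0, 40.0 >= 40.0)
        below = DependenceResult("p", "u", (0,), (39.9,), 39.9, 40.0, 39.9 >= 40.0)
        assert exactly.flagged
        assert not below.flagged

    def test_message_score_is_sum_of_sentences(self, table):
        lexicon, posts = self.make_toy()
        scorer = DependenceScorer(lexicon).fit(posts, table)
        res = scorer.score_post(posts[0], table)
        assert res.message_score == pytest.approx(sum(res.sentence_scores))

    def test_appending_candidate_sentence_never_decreases(self, table):
        lexicon, posts = self.make_toy()
        scorer = DependenceScorer(lexicon).fit(posts, table)
        base = scorer.score_post(posts[0], table).message_score
        extended = make_clean(
            posts[0].cleaned_text + ". le sevrage du doliprane recommence", post_id="px"
        )
        assert scorer.score_post(extended, table).message_score >= base

    def test_empty_lexicon_is_configuration_error(self):
        with pytest.raises(ValueError):
            DependenceScorer([])


class TestOverdose:
    def test_ten_grams_per_day(self, table, od_matcher):
        post = make_clean("je prends 10 g de doliprane par jour")
        res = detect_overdose(post, od_matcher, keyword_table=table, threshold_mg=4000)
        assert res.flagged and res.mode == "dose"
        assert res.parsed_daily_dose_mg == 10000
        assert res.percent_above == pytest.approx(150.0)

    def test_units_times_strength_times_frequency(self, table, od_matcher):
        post = make_clean("2 comprimés de 1000 mg, 3 fois par jour de doliprane")
        res = detect_overdose(post, od_matcher, keyword_table=table, threshold_mg=4000)
        assert res.parsed_daily_dose_mg == 6000
        assert res.percent_above == pytest.approx(50.0)

    def test_dose_equal_to_threshold_not_flagged(self, table, od_matcher):
        post = make_clean("je prends 4 g de doliprane par jour")
        res = detect_overdose(post, od_matcher, keyword_table=table, threshold_mg=4000)
        assert not res.flagged
        assert res.percent_above is None

    def test_lexical_term_flags_without_percent(self, table, od_matcher):
        post = make_clean("c'etait une overdose de doliprane je crois")
        res = detect_overdose(post, od_matcher, keyword_table=table, threshold_mg=4000)
        assert res.flagged and res.mode == "lexical"
        assert res.percent_above is None

    def test_unknown_strength_skipped_with_warning(self, od_matcher):
        with pytest.warns(UserWarning, match="skipped"):
            doses = parse_daily_doses("j'ai pris 2 comprimes hier", mg_per_unit=None)
        assert doses == []

    def test_product_strength_from_unit_table(self, table, od_matcher):
        dose_table = DoseUnitTable.from_tsv(resources.path(resources.DOSE_UNITS))
        post = make_clean("j'ai pris 6 comprimes de doliprane, 2 fois par jour")
        res = detect_overdose(post, od_matcher, dose_table, table, threshold_mg=4000)
        assert res.parsed_daily_dose_mg == 12000  # 6 x 1000 mg x 2

    def test_higher_strength_assumed_on_discrepancy(self):
        t = DoseUnitTable([("generique", 500.0), ("generique", 1000.0)])
        assert t.lookup("generique") == 1000.0

    def test_percent_above_scale_invariance(self, table, od_matcher):
        p1 = detect_overdose(
            make_clean("je prends 10 g de doliprane par jour"),
            od_matcher, keyword_table=table, threshold_mg=4000,
        )
        p2 = detect_overdose(
            make_clean("je prends 20 g de doliprane par jour"),
            od_matcher, keyword_table=table, threshold_mg=8000,
        )
        assert p1.percent_above == pytest.approx(p2.percent_above)

    def test_users_counted_once(self, table, od_matcher):
        posts = [
            make_clean(f"je prends 10 g de doliprane par jour {i}", post_id=f"p{i}",
                       user_id="u1")
            for i in range(3)
        ] + [make_clean("overdose de doliprane", post_id="p9", user_id="u1")]
        results = [
            detect_overdose(p, od_matcher, keyword_table=table, threshold_mg=4000)
            for p in posts
        ]
        assert count_overdose_users(results) == {"Doliprane": 1}

    def test_six_flagged_posts_four_users(self, table, od_matcher):
        posts = [
            make_clean(f"je prends 10 g de doliprane par jour {i}", post_id=f"p{i}",
                       user_id=f"u{i % 4}")
            for i in range(6)
        ]
        results = [
            detect_overdose(p, od_matcher, keyword_table=table, threshold_mg=4000)
            for p in posts
        ]
        assert count_overdose_users(results) == {"Doliprane": 4}


@pytest.fixture(scope="module")
def setup():
    d = load_dictionary(resources.path(resources.CONCEPTS))
    smpc = SmPCIndex.from_tsv(resources.path(resources.SMPC))
    return d, smpc


class TestUnapproved:

    def _mentions(self, posts, d):
        return {p.post_id: tag_concepts(p.cleaned_text, d, p.post_id) for p in posts}

    def test_approved_concept_excluded(self, table, setup):
        d, smpc = setup
        posts = [make_clean("j'ai pris doliprane contre la douleur", post_id="p1")]
        cands = find_unapproved_indications(
            posts, self._mentions(posts, d), {"p1": ["paracetamol_only"]}, smpc
        )
        assert cands == {}

    def test_unapproved_fatigue_is_candidate(self, table, setup):
        d, smpc = setup
        posts = [make_clean("j'ai pris doliprane contre la fatigue", post_id="p1")]
        cands = find_unapproved_indications(
            posts, self._mentions(posts, d), {"p1": ["paracetamol_only"]}, smpc
        )
        assert cands == {"C_FATIGUE": ["p1"]}

    def test_mixed_concepts_excluded_when_any_approved(self, table, setup):
        d, smpc = setup
        posts = [make_clean("doliprane pour la douleur et la fatigue", post_id="p1")]
        cands = find_unapproved_indications(
            posts, self._mentions(posts, d), {"p1": ["paracetamol_only"]}, smpc
        )
        assert cands == {}

    def test_sampling_exact_and_reproducible(self):
        candidates = [f"p{i}" for i in range(200)]
        s1 = sample_for_annotation(candidates, 0.10, seed=5)
        s2 = sample_for_annotation(candidates, 0.10, seed=5)
        assert len(s1) == 20
        assert s1 == s2
        assert sample_for_annotation(candidates, 0.10, seed=6) != s1
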