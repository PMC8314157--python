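"""Corpus cleaning, deduplication, language filtering and group assignment."""

import json

import pytest
from hypothesis import given
from hypothesis import strategies as st

from forumvigil import resources
from forumvigil.corpus import (
    AGGREGATE,
    PARACETAMOL_ONLY,
    PARACETAMOL_OPIOIDS,
    REASON_DUPLICATE,
    REASON_EMPTY,
    REASON_NON_FRENCH,
    CorpusError,
    KeywordTable,
    assign_groups,
    clean_post,
    deduplicate,
    filter_language,
    load_corpus,
)

from conftest import make_clean, make_raw


@pytest.fixture(scope="module")
def table():
    return KeywordTable.from_tsv(resources.path(resources.KEYWORDS))


class TestCleanPost:
    def test_no_markers_is_identity_after_whitespace_normalization(self):
        p = clean_post(make_raw(text="  bonjour   tout le monde \n"))
        assert p.cleaned_text == "bonjour tout le monde"
        assert not p.discarded

    def test_quote_block_removed(self):
        p = clean_post(make_raw(text="avis? [quote]j'ai pris doliprane[/quote] merci"))
        assert p.cleaned_text == "avis? merci"

    def test_nested_quote_blocks_removed(self):
        p = clean_post(
            make_raw(text="a [quote]x [quote]y[/quote] z[/quote] b")
        )
        assert p.cleaned_text == "a b"

    def test_signature_only_post_discarded_empty(self):
        p = clean_post(make_raw(text="[signature]ma signature[/signature]"))
        assert p.discarded and p.reason == REASON_EMPTY

    def test_idempotent(self):
        p = clean_post(make_raw(text="avis? [quote]q[/quote] merci  beaucoup"))
        again = clean_post(make_raw(text=p.cleaned_text))
        assert again.cleaned_text == p.cleaned_text

    @given(st.text(max_size=80))
    def test_idempotent_property(self, text):
        first = clean_post(make_raw(text=text))
        second = clean_post(make_raw(text=first.cleaned_text))
        assert second.cleaned_text == first.cleaned_text


class TestDeduplicate:
    def test_earlier_copy_kept(self):
        a = make_clean("meme texte", post_id="a", ts="2005-01-02T00:00:00")
        b = make_clean("meme texte", post_id="b", ts="2005-01-01T00:00:00")
        out = deduplicate([a, b])
        by_id = {p.post_id: p for p in out}
        assert by_id["a"].discarded and by_id["a"].reason == REASON_DUPLICATE
        assert not by_id["b"].discarded

    def test_same_text_different_users_both_kept(self):
        a = make_clean("bonjour", post_id="a", user_id="u1")
        b = make_clean("bonjour", post_id="b", user_id="u2")
        assert all(not p.discarded for p in deduplicate([a, b]))

    def test_five_posts_two_duplicates_three_survive(self):
        posts = [
            make_clean("un", post_id="p1", ts="2005-01-01T00:00:00"),
            make_clean("deux", post_id="p2", ts="2005-01-02T00:00:00"),
            make_clean("un", post_id="p3", ts="2005-01-03T00:00:00"),
            make_clean("deux", post_id="p4", ts="2005-01-04T00:00:00"),
            make_clean("trois", post_id="p5", ts="2005-01-05T00:00:00"),
        ]
        out = deduplicate(posts)
        assert sum(not p.discarded for p in out) == 3

    def test_idempotent_and_never_increases(self):
        posts = [
            make_clean("x", post_id=f"p{i}", ts=f"2005-01-0{i + 1}T00:00:00")
            for i in range(5)
        ]
        once = deduplicate(posts)
        twice = deduplicate(once)
        assert once == twice
        assert sum(not p.discarded for p in once) <= len(posts)


class TestLanguageFilter:
    def test_tagged_french_kept_english_discarded(self):
        fr = make_clean("bonjour je suis la", post_id="a", language="fr")
        en = make_clean("hello there everyone", post_id="b", language="en")
        out = {p.post_id: p for p in filter_language([fr, en])}
        assert not out["a"].discarded
        assert out["b"].discarded and out["b"].reason == REASON_NON_FRENCH

    def test_counts_by_construction(self):
        posts = [
            make_clean(f"texte {i}", post_id=f"p{i}", language="fr") for i in range(7)
        ] + [make_clean(f"text {i}", post_id=f"e{i}", language="en") for i in range(3)]
        out = filter_language(posts)
        assert sum(not p.discarded for p in out) == 7

    def test_detector_failure_fails_open(self):
        def broken(_text):
            raise RuntimeError("backend down")

        p = make_clean("quelque chose")
        with pytest.warns(UserWarning):
            out = filter_language([p], detector=broken)
        assert not out[0].discarded

    def test_untagged_uses_detector(self):
        p = make_clean("je suis la et je ne sais pas")
        assert not filter_language([p])[0].discarded


class TestGroups:
    def test_paracetamol_only(self, table):
        p = make_clean("j'ai pris du doliprane hier")
        assert assign_groups(p, table).groups == {PARACETAMOL_ONLY, AGGREGATE}

    def test_opioid_keyword(self, table):
        p = make_clean("on m'a prescrit de l'ixprim")
        assert assign_groups(p, table).groups == {PARACETAMOL_OPIOIDS, AGGREGATE}

    def test_multiple_groups(self, table):
        p = make_clean("doliprane le matin et ixprim le soir")
        assert assign_groups(p, table).groups == {
            PARACETAMOL_ONLY,
            PARACETAMOL_OPIOIDS,
            AGGREGATE,
        }

    def test_case_and_diacritic_insensitive(self, table):
        assert (
            assign_groups(make_clean("DOLIPRANE"), table).groups
            == assign_groups(make_clean("dolipràne"), table).groups
            == {PARACETAMOL_ONLY, AGGREGATE}
        )

    def test_no_match_empty_groups(self, table):
        assert assign_groups(make_clean("rien d'interessant ici"), table).groups == frozenset()

    def test_whole_word_matching(self, table):
        # a keyword must not fire inside an unrelated longer word
        assert assign_groups(make_clean("dolipranesque"), table).groups == frozenset()

    def test_combination_brand_shadows_base_brand(self, table):
        p = make_clean("du dafalgan codeine ce soir")
        assert assign_groups(p, table).groups == {PARACETAMOL_OPIOIDS, AGGREGATE}

    def test_empty_keyword_table_is_configuration_error(self):
        with pytest.raises(CorpusError):
            KeywordTable([])

    def test_aggregate_is_union_of_subgroups(self, table):
        posts = [
            make_clean(t, post_id=f"p{i}")
            for i, t in enumerate(
                ["doliprane", "ixprim", "doliprane et ixprim", "rien", "fervex"]
            )
        ]
        assigns = [assign_groups(p, table) for p in posts]
        agg = {a.post_id for a in assigns if AGGREGATE in a.groups}
        union = {
            a.post_id
            for a in assigns
            if a.groups & {PARACETAMOL_ONLY, PARACETAMOL_OPIOIDS, "ParacetamolOthers"}
        }
        assert agg == union


class TestCorpusIO:
    def test_load_error_names_line(self, tmp_path):
        path = tmp_path / "bad.jsonl"
        path.write_text(
            json.dumps(
                {
                    "post_id": "a",
                    "user_id": "u",
                    "forum_id": "f",
                    "timestamp": "2005-01-01T00:00:00",
                    "text": "ok",
                }
            )
            + "\nnot json\n"
        )
        with pytest.raises(CorpusError, match="line 2"):
            load_corpus(path)

    def test_duplicate_post_id_rejected(self, tmp_path):
        rec = json.dumps(
            {
                "post_id": "a",
                "user_id": "u",
                "forum_id": "f",
                "timestamp": "2005-01-01T00:00:00",
                "text": "ok",
            }
        )
        path = tmp_path / "dup.jsonl"
        path.write_text(rec + "\n" + rec + "\n")
        with pytest.raises(CorpusError, match="duplicate post_id"):
            load_corpus(path)
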