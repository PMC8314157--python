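"""Per-post drug-intake classification and simultaneous-consumption detection.

A post asserts intake when the web user says they actually took the product
("j'ai pris un doliprane"), as opposed to mentioning it otherwise (advice,
questions, somebody else's intake).  Classification is at sentence level:
posts are split into sentences, each sentence gets lexical (intake /
non-intake lexical-field hits), stylistic (exclamation and pronoun
proportions) and syntactic (length, drug position) features, features are
standardized within each user so prolific posters do not dominate the
feature scale, and a seeded random forest predicts per sentence.  A post is
an intake post iff at least one of its sentences is positive.

Simultaneous consumption then runs dictionary NER with the medical-product
list over intake posts only, counting posts per co-mentioned drug against
the denominator of paracetamol-intake posts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from forumvigil._match import DictionaryMatcher
from forumvigil._text import fold, token_spans, tokenize
from forumvigil.corpus import CleanPost, KeywordTable

_PRONOUNS = frozenset(
    "je j tu il elle on nous vous ils elles me moi te toi se lui leur mien tien".split()
)

FEATURE_NAMES = (
    "intake_lexicon_hits",
    "nonintake_lexicon_hits",
    "exclamation_proportion",
    "pronoun_proportion",
    "sentence_length",
    "drug_position",
    "has_drug",
)


@dataclass(frozen=True)
class DrugMention:
    start: int
    end: int
    canonical: str
    list_source: str  # paracetamol_keywords | drug_list


@dataclass(frozen=True)
class SentenceRecord:
    post_id: str
    user_id: str
    index: int
    span: tuple[int, int]  # on the post's cleaned_text; spans partition it
    text: str
    drug_mentions: tuple[DrugMention, ...] = ()


@dataclass(frozen=True)
class IntakeFeatures:
    intake_lexicon_hits: int
    nonintake_lexicon_hits: int
    exclamation_proportion: float
    pronoun_proportion: float
    sentence_length: int
    drug_position: float | None  # None when the sentence has no drug mention

    def as_vector(self) -> np.ndarray:
        has_drug = self.drug_position is not None
        return np.array(
            [
                self.intake_lexicon_hits,
                self.nonintake_lexicon_hits,
                self.exclamation_proportion,
                self.pronoun_proportion,
                self.sentence_length,
                self.drug_position if has_drug else 0.0,
                float(has_drug),
            ],
            dtype=float,
        )


@dataclass
class IntakePrediction:
    sentence_probabilities: dict[tuple[str, int], float]  # (post_id, index) -> p
    post_intake: dict[str, bool]


# ---------------------------------------------------------------------------
# Sentence splitting

_ABBREVIATIONS = frozenset("m mme mlle dr etc ex env cf nb st".split())
_TERMINAL_RE = re.compile(r"[.!?]+")


def split_sentences(post_text: str) -> list[tuple[int, int]]:
    """Sentence spans partitioning ``post_text`` (concatenation reconstructs it).

    Splits after runs of terminal punctuation, guarding common French
    abbreviations and decimal numbers; trailing whitespace stays with the
    sentence it follows.
    """
    if not post_text:
        return []
    folded = fold(post_text)
    cuts = []
    for m in _TERMINAL_RE.finditer(folded):
        end = m.end()
        if end >= len(folded):
            continue
        before = folded[: m.start()]
        word = re.findall(r"[\w]+$", before)
        if m.group() == "." and word and word[-1] in _ABBREVIATIONS:
            continue
        if m.group() == "." and word and word[-1].isdigit() and folded[end : end + 1].isdigit():
            continue  # decimal like 10.5
        # absorb following whitespace into this sentence
        while end < len(folded) and folded[end].isspace():
            end += 1
        if end < len(folded):
            cuts.append(end)
    spans = []
    start = 0
    for cut in cuts:
        spans.append((start, cut))
        start = cut
    spans.append((start, len(post_text)))
    return spans


def sentence_records(
    post: CleanPost,
    keyword_table: KeywordTable | None = None,
    drug_list: "DrugList | None" = None,
) -> list[SentenceRecord]:
    records = []
    for i, (start, end) in enumerate(split_sentences(post.cleaned_text)):
        text = post.cleaned_text[start:end]
        mentions: list[DrugMention] = []
        if keyword_table is not None:
            for s, e, _cat, brand in keyword_table.find_mentions(text):
                mentions.append(DrugMention(s, e, brand, "paracetamol_keywords"))
        if drug_list is not None:
            taken = [(m.start, m.end) for m in mentions]
            for m in drug_list.matcher.find(text):
                if not any(s < m.end and m.start < e for s, e in taken):
                    mentions.append(DrugMention(m.start, m.end, m.payload, "drug_list"))
        mentions.sort(key=lambda m: m.start)
        records.append(
            SentenceRecord(
                post_id=post.post_id,
                user_id=post.user_id,
                index=i,
                span=(start, end),
                text=text,
                drug_mentions=tuple(mentions),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Lexicons and features

def load_intake_lexicon(path: str | Path) -> tuple[DictionaryMatcher, DictionaryMatcher]:
    """TSV of (term, field) with field in {intake, nonintake} → two matchers."""
    intake_terms, nonintake_terms = [], []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["term", "field"]:
            raise ValueError(f"{path}: expected header ['term', 'field'], got {header}")
        for line in fh:
            if not line.strip():
                continue
            term, fieldname = line.rstrip("\n").split("\t")
            if fieldname == "intake":
                intake_terms.append((term, None))
            elif fieldname == "nonintake":
                nonintake_terms.append((term, None))
            else:
                raise ValueError(f"{path}: bad field {fieldname!r}")
    return DictionaryMatcher(intake_terms), DictionaryMatcher(nonintake_terms)


def extract_intake_features(
    sentence: SentenceRecord,
    intake_matcher: DictionaryMatcher,
    nonintake_matcher: DictionaryMatcher,
) -> IntakeFeatures:
    text = sentence.text
    tokens = tokenize(text)
    n_tokens = len(tokens)
    non_ws = sum(1 for ch in text if not ch.isspace())
    excl = text.count("!")
    pronouns = sum(1 for t in tokens if t in _PRONOUNS)
    drug_position = None
    if sentence.drug_mentions:
        first = sentence.drug_mentions[0]
        spans = token_spans(text)
        tok_idx = next((i for i, (s, _e) in enumerate(spans) if s >= first.start), 0)
        drug_position = tok_idx / max(1, n_tokens - 1)
    return IntakeFeatures(
        intake_lexicon_hits=len(intake_matcher.find(text)),
        nonintake_lexicon_hits=len(nonintake_matcher.find(text)),
        exclamation_proportion=excl / non_ws if non_ws else 0.0,
        pronoun_proportion=pronouns / n_tokens if n_tokens else 0.0,
        sentence_length=n_tokens,
        drug_position=drug_position,
    )


def scale_features_per_user(
    X: np.ndarray, user_ids: Sequence[str]
) -> np.ndarray:
    """Within-user standardization of each feature column.

    Subtract the user's mean and divide by the user's standard deviation;
    a zero deviation (including single-sentence users) maps to 0, so the
    output is bounded regardless of how much a user posted.  Idempotent.
    """
    X = np.asarray(X, dtype=float)
    out = np.zeros_like(X)
    user_ids = np.asarray(user_ids)
    for user in np.unique(user_ids):
        rows = user_ids == user
        block = X[rows]
        mean = block.mean(axis=0)
        sd = block.std(axis=0)
        centered = block - mean
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = np.where(sd > 0, centered / np.where(sd > 0, sd, 1.0), 0.0)
        out[rows] = scaled
    return out


# ---------------------------------------------------------------------------
# Random-forest intake model

class IntakeModel:
    """Seeded random forest (500 trees) over per-user-scaled sentence features."""

    def __init__(self, n_estimators: int = 500, seed: int = 0, threshold: float = 0.5):
        self.threshold = threshold
        self._rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
        self._fitted = False

    def fit(self, X_scaled: np.ndarray, y: Sequence[bool]) -> "IntakeModel":
        y = np.asarray(y, dtype=bool)
        if len(np.unique(y)) < 2:
            raise ValueError("training set has a single class")
        self._rf.fit(X_scaled, y)
        self._fitted = True
        return self

    def predict_proba(self, X_scaled: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("model not fitted")
        pos = list(self._rf.classes_).index(True)
        return self._rf.predict_proba(X_scaled)[:, pos]


def predict_intake(
    model: IntakeModel,
    records: Sequence[SentenceRecord],
    X_scaled: np.ndarray,
) -> IntakePrediction:
    """Per-sentence probabilities aggregated per post by any-positive."""
    probs = model.predict_proba(X_scaled)
    sentence_probabilities = {
        (r.post_id, r.index): float(p) for r, p in zip(records, probs)
    }
    post_intake: dict[str, bool] = {}
    for r, p in zip(records, probs):
        post_intake[r.post_id] = bool(
            post_intake.get(r.post_id, False) or p >= model.threshold
        )
    return IntakePrediction(sentence_probabilities, post_intake)


def featurize_corpus(
    posts: Sequence[CleanPost],
    keyword_table: KeywordTable,
    drug_list: "DrugList | None",
    intake_matcher: DictionaryMatcher,
    nonintake_matcher: DictionaryMatcher,
) -> tuple[list[SentenceRecord], np.ndarray]:
    """Sentence records and the per-user-scaled feature matrix for a corpus."""
    records: list[SentenceRecord] = []
    for p in posts:
        if p.discarded:
            continue
        records.extend(sentence_records(p, keyword_table, drug_list))
    X = np.array(
        [
            extract_intake_features(r, intake_matcher, nonintake_matcher).as_vector()
            for r in records
        ]
    )
    if len(records) == 0:
        return records, np.zeros((0, len(FEATURE_NAMES)))
    X_scaled = scale_features_per_user(X, [r.user_id for r in records])
    return records, X_scaled


# ---------------------------------------------------------------------------
# Drug list and co-consumption

class DrugList:
    """Medical-product list (surface_form → canonical molecule, class)."""

    def __init__(self, rows: Iterable[tuple[str, str, str]]):
        rows = list(rows)
        self.canonical_class = {}
        entries = []
        for surface, canonical, cls in rows:
            entries.append((surface, canonical))
            self.canonical_class[canonical] = cls
        self.matcher = DictionaryMatcher(entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DrugList":
        rows = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["surface_form", "canonical", "class"]:
                raise ValueError(
                    f"{path}: expected header ['surface_form', 'canonical', 'class'], got {header}"
                )
            for line in fh:
                if not line.strip():
                    continue
                rows.append(tuple(line.rstrip("\n").split("\t")))
        return cls(rows)


@dataclass
class CoconsumptionResult:
    post_counts: dict[str, int]  # canonical drug -> number of intake posts mentioning it
    user_pairs: set[tuple[str, str]]  # (user_id, canonical drug)
    n_intake_posts: int


def detect_coconsumption(
    posts: Sequence[CleanPost],
    post_intake: Mapping[str, bool],
    drug_list: DrugList,
    keyword_table: KeywordTable,
) -> CoconsumptionResult:
    """Count co-mentioned drugs over posts asserting paracetamol intake.

    Only posts whose intake prediction is positive enter the analysis; the
    denominator is the number of such posts.  Paracetamol-product keywords
    themselves are not co-mentions.
    """
    intake_posts = [p for p in posts if not p.discarded and post_intake.get(p.post_id)]
    post_counts: dict[str, int] = {}
    user_pairs: set[tuple[str, str]] = set()
    for p in intake_posts:
        para_spans = [
            (s, e) for s, e, _c, _b in keyword_table.find_mentions(p.cleaned_text)
        ]
        drugs = set()
        for m in drug_list.matcher.find(p.cleaned_text):
            if any(s < m.end and m.start < e for s, e in para_spans):
                continue
            drugs.add(m.payload)
        for d in drugs:
            post_counts[d] = post_counts.get(d, 0) + 1
            user_pairs.add((p.user_id, d))
    return CoconsumptionResult(post_counts, user_pairs, len(intake_posts))
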