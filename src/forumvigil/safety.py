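"""Misuse and adverse-event detectors.

Four detectors run over the intake-positive, adult slice of the corpus:

* **Potential adverse events (PAE)** — a weighted radial-kernel SVM
  (cost 100, gamma 0.1) over three features of a (post, concept) pair:
  token distance from the concept to the closest drug mention, message
  length in tokens, and the concept's occurrence count in the message.
* **Dependence** — sentences containing a drug name and at least one term of
  the dependency lexical field are scored with Okapi BM25 against a
  reference pattern built from that lexical field; the message score is the
  sum of its candidate-sentence scores and the message is flagged when the
  score reaches the threshold (default 40, inclusive).
* **Overdose** — dose expressions ("10 g par jour", "2 comprimés de 1000 mg,
  3 fois par jour") are parsed to a daily milligram dose and compared with
  the recommended daily threshold (default 4000 mg paracetamol for adults,
  strictly greater flags); independently, any term of the overdose lexical
  field flags the post.  Users are counted once per drug across both modes.
* **Unapproved indications** — intake posts whose stated-use concepts all
  fall outside the approved-indication set of the product category become
  candidates, grouped by concept; a seeded 10% sample is drawn for manual
  review (the review itself is outside the pipeline).

Posts describing use in children younger than 15 are excluded from all four.

BM25 here uses the non-negative idf ``ln(1 + (N - df + 0.5)/(df + 0.5))``
with document frequency taken over all sentences of the corpus and length
normalization against the mean candidate-sentence length, with the classical
parameters k1=1.2, b=0.75.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from forumvigil._match import DictionaryMatcher
from forumvigil._text import fold, token_spans, tokenize
from forumvigil.concepts import ConceptMention
from forumvigil.corpus import CleanPost, KeywordTable
from forumvigil.intake import DrugList, sentence_records


def load_term_list(path: str | Path) -> list[str]:
    """Plain-text lexicon, one term (word or phrase) per line; # comments."""
    terms = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                terms.append(line)
    if not terms:
        raise ValueError(f"{path}: empty lexicon")
    return terms


# ---------------------------------------------------------------------------
# Child-use exclusion

_CHILD_NOUN = r"(?:fils|fille|enfant|garcon|fillette|bebe|nourrisson|bb)"
_CHILD_AGE_RE = re.compile(
    rf"\b(?:mon|ma|notre|le|la)\s+{_CHILD_NOUN}\b(?:[^.!?]*?\b(?:de|a)\s+(\d+)\s+ans)?"
)
_INFANT_RE = re.compile(r"\b(?:bebe|nourrisson)\b")


def is_child_context(text: str) -> bool:
    """True when the post describes use in a subject younger than 15."""
    folded = fold(text)
    for m in _CHILD_AGE_RE.finditer(folded):
        age = m.group(1)
        if age is None or int(age) < 15:
            return True
    return bool(_INFANT_RE.search(folded))


def filter_child_posts(posts: Sequence[CleanPost]) -> list[CleanPost]:
    """Posts retained for the misuse analyses (adult contexts only).

    The exclusion is scoped to misuse detection; concept counts and the other
    report tables are unaffected.
    """
    return [p for p in posts if not is_child_context(p.cleaned_text)]


# ---------------------------------------------------------------------------
# Potential adverse events

@dataclass(frozen=True)
class PAEFeatures:
    concept_drug_distance: int  # tokens between concept and closest drug mention
    message_length: int
    concept_count: int

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.concept_drug_distance, self.message_length, self.concept_count],
            dtype=float,
        )


def _token_index(spans: list[tuple[int, int]], char_start: int) -> int:
    for i, (s, e) in enumerate(spans):
        if e > char_start:
            return i
    return max(0, len(spans) - 1)


def compute_pae_features(
    post: CleanPost,
    concept_mention: ConceptMention,
    drug_spans: Sequence[tuple[int, int]],
    all_mentions: Sequence[ConceptMention],
) -> PAEFeatures:
    """Feature triple for one (post, concept-mention) pair.

    Distance is in tokens between the concept mention and the closest drug
    mention (adjacent tokens → distance 1).
    """
    if not drug_spans:
        raise ValueError(f"post {post.post_id}: no drug mention, cannot compute PAE features")
    spans = token_spans(post.cleaned_text)
    c_idx = _token_index(spans, concept_mention.start)
    distance = min(abs(c_idx - _token_index(spans, s)) for s, _e in drug_spans)
    concept_count = sum(
        1 for m in all_mentions if m.concept_id == concept_mention.concept_id
    )
    return PAEFeatures(
        concept_drug_distance=distance,
        message_length=len(spans),
        concept_count=concept_count,
    )


class PAEClassifier:
    """Class-weighted radial SVM, cost 100, gamma 0.1, over the feature triple."""

    def __init__(self, cost: float = 100.0, gamma: float = 0.1):
        self._svm = SVC(C=cost, gamma=gamma, kernel="rbf", class_weight="balanced")
        self._fitted = False

    def fit(self, features: Sequence[PAEFeatures], labels: Sequence[bool]) -> "PAEClassifier":
        X = np.array([f.as_vector() for f in features])
        y = np.asarray(labels, dtype=bool)
        if len(np.unique(y)) < 2:
            raise ValueError("PAE training set has a single class")
        self._svm.fit(X, y)
        self._fitted = True
        return self

    def predict(self, features: PAEFeatures) -> bool:
        if not self._fitted:
            raise RuntimeError("PAE classifier not fitted")
        return bool(self._svm.predict(features.as_vector().reshape(1, -1))[0])


# ---------------------------------------------------------------------------
# Dependence (BM25)

@dataclass(frozen=True)
class DependenceResult:
    post_id: str
    user_id: str
    candidate_sentences: tuple[int, ...]  # sentence indices within the post
    sentence_scores: tuple[float, ...]
    message_score: float
    threshold: float
    flagged: bool


class DependenceScorer:
    """Okapi BM25 of the dependence reference pattern against candidate sentences.

    The reference pattern is the token sequence of the dependency lexical
    field; candidate sentences contain a drug name and at least one lexicon
    term.  Document frequencies come from every sentence of the corpus; the
    length normalization uses the mean candidate-sentence token length.
    """

    def __init__(
        self,
        dependency_lexicon: Sequence[str],
        k1: float = 1.2,
        b: float = 0.75,
        threshold: float = 40.0,
    ):
        if not dependency_lexicon:
            raise ValueError("empty dependency lexicon")
        self.k1, self.b, self.threshold = k1, b, threshold
        self._lex_matcher = DictionaryMatcher((t, None) for t in dependency_lexicon)
        # reference pattern: token sequence of the whole lexical field
        self.pattern_terms = tuple(dict.fromkeys(
            tok for term in dependency_lexicon for tok in tokenize(term)
        ))
        self._df: dict[str, int] = {}
        self._n_sentences = 0
        self._avgdl = 1.0
        self._fitted = False

    def fit(
        self,
        posts: Sequence[CleanPost],
        keyword_table: KeywordTable,
        drug_list: DrugList | None = None,
    ) -> "DependenceScorer":
        """Collect corpus sentence statistics (df, mean candidate length)."""
        candidate_lengths = []
        self._df = {t: 0 for t in self.pattern_terms}
        self._n_sentences = 0
        for post in posts:
            if post.discarded:
                continue
            for rec in sentence_records(post, keyword_table, drug_list):
                toks = tokenize(rec.text)
                self._n_sentences += 1
                present = set(toks)
                for t in self.pattern_terms:
                    if t in present:
                        self._df[t] += 1
                if rec.drug_mentions and self._lex_matcher.find(rec.text):
                    candidate_lengths.append(len(toks))
        self._avgdl = float(np.mean(candidate_lengths)) if candidate_lengths else 1.0
        self._fitted = True
        return self

    def idf(self, term: str) -> float:
        n = self._df.get(term, 0)
        return math.log(1.0 + (self._n_sentences - n + 0.5) / (n + 0.5))

    def sentence_score(self, sentence_tokens: Sequence[str]) -> float:
        if not self._fitted:
            raise RuntimeError("scorer not fitted")
        dl = len(sentence_tokens)
        norm = 1.0 - self.b + self.b * dl / self._avgdl
        score = 0.0
        for t in self.pattern_terms:
            tf = sum(1 for tok in sentence_tokens if tok == t)
            if tf:
                score += self.idf(t) * tf * (self.k1 + 1.0) / (tf + self.k1 * norm)
        return score

    def score_post(
        self,
        post: CleanPost,
        keyword_table: KeywordTable,
        drug_list: DrugList | None = None,
    ) -> DependenceResult:
        indices, scores = [], []
        for rec in sentence_records(post, keyword_table, drug_list):
            if rec.drug_mentions and self._lex_matcher.find(rec.text):
                indices.append(rec.index)
                scores.append(self.sentence_score(tokenize(rec.text)))
        total = float(sum(scores))
        return DependenceResult(
            post_id=post.post_id,
            user_id=post.user_id,
            candidate_sentences=tuple(indices),
            sentence_scores=tuple(scores),
            message_score=total,
            threshold=self.threshold,
            flagged=total >= self.threshold,
        )


# ---------------------------------------------------------------------------
# Overdose

@dataclass(frozen=True)
class OverdoseResult:
    post_id: str
    user_id: str
    drug: str | None
    parsed_daily_dose_mg: float | None
    threshold_mg: float
    percent_above: float | None
    mode: str | None  # dose | lexical | None
    flagged: bool


class DoseUnitTable:
    """Milligrams of paracetamol per unit (pill/sachet) of each product.

    When a product is listed with several strengths the higher one is
    assumed, per the conservative convention for ambiguous regimens.
    """

    def __init__(self, rows: Iterable[tuple[str, float]]):
        self.mg_per_unit: dict[str, float] = {}
        for product, mg in rows:
            key = fold(product)
            self.mg_per_unit[key] = max(self.mg_per_unit.get(key, 0.0), float(mg))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DoseUnitTable":
        rows = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["product", "mg_per_unit"]:
                raise ValueError(f"{path}: expected header ['product', 'mg_per_unit'], got {header}")
            for line in fh:
                if not line.strip():
                    continue
                product, mg = line.rstrip("\n").split("\t")
                rows.append((product, float(mg)))
        return cls(rows)

    def lookup(self, product: str) -> float | None:
        return self.mg_per_unit.get(fold(product))


_NUM = r"(\d+(?:[.,]\d+)?)"
_MASS_RE = re.compile(rf"\b{_NUM}\s*(mg|milligrammes?|g|gr|grammes?)\b")
_UNIT_RE = re.compile(
    rf"\b{_NUM}\s*(comprimes?|cachets?|gelules?|sachets?|cp)\b"
    rf"(?:\s*(?:de|a)\s*{_NUM}\s*(mg|g)\b)?"
)
_FREQ_RE = re.compile(rf"\b{_NUM}\s*fois\s*par\s*jour\b")


def _to_mg(amount: str, unit: str) -> float:
    value = float(amount.replace(",", "."))
    return value if unit.startswith("m") else value * 1000.0


def parse_daily_doses(text: str, mg_per_unit: float | None = None) -> list[float]:
    """Daily milligram doses of every dose expression found in ``text``.

    Each expression is ``amount [× frequency per day]``; unit counts without
    an explicit strength use ``mg_per_unit`` (the product's strength) and are
    skipped with a warning when no strength is known.
    """
    folded = fold(text)
    freq_m = _FREQ_RE.search(folded)
    freq = float(freq_m.group(1).replace(",", ".")) if freq_m else 1.0
    doses = []
    unit_spans = []
    for m in _UNIT_RE.finditer(folded):
        unit_spans.append(m.span())
        count = float(m.group(1).replace(",", "."))
        if m.group(3):
            per_unit = _to_mg(m.group(3), m.group(4))
        elif mg_per_unit is not None:
            per_unit = mg_per_unit
        else:
            warnings.warn(f"unit count without known strength skipped: {m.group(0)!r}")
            continue
        doses.append(count * per_unit * freq)
    for m in _MASS_RE.finditer(folded):
        # masses inside a unit expression ("2 comprimés de 1000 mg") were consumed above
        if any(s <= m.start() < e for s, e in unit_spans):
            continue
        doses.append(_to_mg(m.group(1), m.group(2)) * freq)
    return doses


def detect_overdose(
    post: CleanPost,
    overdose_matcher: DictionaryMatcher,
    dose_unit_table: DoseUnitTable | None = None,
    keyword_table: KeywordTable | None = None,
    threshold_mg: float = 4000.0,
) -> OverdoseResult:
    """Flag a post whose daily dose exceeds the threshold or whose text hits
    the overdose lexical field.

    Among several parsed dose expressions the highest daily dose is assumed.
    The dose flag requires a dose strictly greater than the threshold; a dose
    exactly at the threshold never flags.
    """
    drug = None
    mg_unit = None
    if keyword_table is not None:
        mentions = keyword_table.find_mentions(post.cleaned_text)
        if mentions:
            drug = mentions[0][3]
            if dose_unit_table is not None:
                mg_unit = dose_unit_table.lookup(drug)
    doses = parse_daily_doses(post.cleaned_text, mg_unit)
    daily = max(doses) if doses else None
    dose_flag = daily is not None and daily > threshold_mg
    lexical_flag = bool(overdose_matcher.find(post.cleaned_text))
    percent_above = (
        (daily - threshold_mg) / threshold_mg * 100.0 if dose_flag else None
    )
    mode = "dose" if dose_flag else ("lexical" if lexical_flag else None)
    return OverdoseResult(
        post_id=post.post_id,
        user_id=post.user_id,
        drug=drug,
        parsed_daily_dose_mg=daily,
        threshold_mg=threshold_mg,
        percent_above=percent_above,
        mode=mode,
        flagged=dose_flag or lexical_flag,
    )


def count_overdose_users(results: Sequence[OverdoseResult]) -> dict[str, int]:
    """Distinct flagged users per drug, dose and lexical modes pooled.

    A user flagged by several posts, or by both detection modes, counts once.
    """
    users: dict[str, set[str]] = {}
    for r in results:
        if r.flagged:
            users.setdefault(r.drug or "unknown", set()).add(r.user_id)
    return {drug: len(u) for drug, u in users.items()}


# ---------------------------------------------------------------------------
# Unapproved indications

class SmPCIndex:
    """Approved-indication concept ids per drug category."""

    def __init__(self, approved: Mapping[str, Iterable[str]]):
        self.approved = {cat: frozenset(ids) for cat, ids in approved.items()}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SmPCIndex":
        approved: dict[str, set[str]] = {}
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["category", "concept_id"]:
                raise ValueError(f"{path}: expected header ['category', 'concept_id'], got {header}")
            for line in fh:
                if not line.strip():
                    continue
                cat, cid = line.rstrip("\n").split("\t")
                approved.setdefault(cat, set()).add(cid)
        return cls(approved)

    def is_approved(self, category: str, concept_id: str) -> bool:
        return concept_id in self.approved.get(category, frozenset())


def find_unapproved_indications(
    posts: Sequence[CleanPost],
    mentions_by_post: Mapping[str, Sequence[ConceptMention]],
    categories_by_post: Mapping[str, Sequence[str]],
    smpc: SmPCIndex,
    known_concepts: frozenset[str] | None = None,
) -> dict[str, list[str]]:
    """Candidate unapproved-indication posts grouped by concept id.

    A post is a candidate when every concept it states is outside the SmPC
    approved set of every product category the post matched.  Posts with at
    least one approved concept are excluded (their use is on-label).
    """
    candidates: dict[str, list[str]] = {}
    for post in posts:
        mentions = mentions_by_post.get(post.post_id, ())
        cats = categories_by_post.get(post.post_id, ())
        concept_ids = []
        for m in mentions:
            if known_concepts is not None and m.concept_id not in known_concepts:
                warnings.warn(f"unknown concept {m.concept_id!r} skipped")
                continue
            concept_ids.append(m.concept_id)
        if not concept_ids:
            continue
        if any(smpc.is_approved(cat, cid) for cid in concept_ids for cat in cats):
            continue
        for cid in dict.fromkeys(concept_ids):
            candidates.setdefault(cid, []).append(post.post_id)
    return candidates


def sample_for_annotation(
    candidates: Sequence[str], fraction: float = 0.10, seed: int = 0
) -> list[str]:
    """Seeded simple random sample of candidate post ids for manual review."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    n = int(round(len(candidates) * fraction))
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(candidates), size=n, replace=False)) if n else []
    return [candidates[i] for i in idx]
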