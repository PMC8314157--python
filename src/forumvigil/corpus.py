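"""Corpus loading, cleaning, deduplication, language filtering and group assignment.

The on-disk corpus format is line-delimited JSON, one post per line, with
fields ``post_id``, ``user_id``, ``forum_id``, ``timestamp`` (ISO-8601) and
``text``; an optional ``language`` tag may be supplied by upstream tooling
(the synthetic generator always writes one).  Cleaned corpora add
``cleaned_text``, ``language``, ``discarded`` and ``reason``.

Posts are assigned to analysis groups from a keyword table of
paracetamol-containing products: *Paracetamol Only* (paracetamol is the sole
active analgesic), *Paracetamol and Opioids* (combination products such as
tramadol or codeine plus paracetamol), *Paracetamol and Others* (combinations
with non-opioid actives), and the *Aggregate* group containing every post
matching any keyword.  A post mentioning products from several categories
belongs to several groups.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Callable, Iterable, Sequence

from forumvigil._match import DictionaryMatcher, normalize_ws
from forumvigil._text import fold, tokenize

logger = logging.getLogger(__name__)

# Group labels
PARACETAMOL_ONLY = "ParacetamolOnly"
PARACETAMOL_OPIOIDS = "ParacetamolOpioids"
PARACETAMOL_OTHERS = "ParacetamolOthers"
AGGREGATE = "Aggregate"

GROUPS = (PARACETAMOL_ONLY, PARACETAMOL_OPIOIDS, PARACETAMOL_OTHERS, AGGREGATE)

_CATEGORY_TO_GROUP = {
    "paracetamol_only": PARACETAMOL_ONLY,
    "paracetamol_opioid": PARACETAMOL_OPIOIDS,
    "paracetamol_other": PARACETAMOL_OTHERS,
}

# Discard reason codes
REASON_DUPLICATE = "duplicate"
REASON_NON_FRENCH = "non_french"
REASON_UNRELATED = "unrelated"
REASON_EMPTY = "empty_after_cleaning"


class CorpusError(ValueError):
    """Unparseable corpus record or invalid configuration."""


@dataclass(frozen=True)
class RawPost:
    post_id: str
    user_id: str
    forum_id: str
    timestamp: datetime
    text: str
    language: str | None = None  # optional upstream tag


@dataclass(frozen=True)
class CleanPost:
    post_id: str
    user_id: str
    forum_id: str
    timestamp: datetime
    text: str
    cleaned_text: str
    language: str | None = None
    discarded: bool = False
    reason: str | None = None

    def discard(self, reason: str) -> "CleanPost":
        return replace(self, discarded=True, reason=reason)


@dataclass(frozen=True)
class GroupAssignment:
    post_id: str
    groups: frozenset[str] = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# I/O

_REQUIRED_FIELDS = ("post_id", "user_id", "forum_id", "timestamp", "text")


def load_corpus(path: str | Path) -> list[RawPost]:
    """Read a line-delimited JSON corpus; errors name the offending line."""
    posts = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                for f in _REQUIRED_FIELDS:
                    if rec.get(f) is None:
                        raise KeyError(f)
                ts = datetime.fromisoformat(rec["timestamp"])
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise CorpusError(f"{path}: unparseable record at line {lineno}: {exc}") from exc
            if rec["post_id"] in seen:
                raise CorpusError(f"{path}: duplicate post_id {rec['post_id']!r} at line {lineno}")
            seen.add(rec["post_id"])
            posts.append(
                RawPost(
                    post_id=str(rec["post_id"]),
                    user_id=str(rec["user_id"]),
                    forum_id=str(rec["forum_id"]),
                    timestamp=ts,
                    text=str(rec["text"]),
                    language=rec.get("language"),
                )
            )
    return posts


def save_corpus(posts: Iterable[RawPost], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            rec = {
                "post_id": p.post_id,
                "user_id": p.user_id,
                "forum_id": p.forum_id,
                "timestamp": p.timestamp.isoformat(),
                "text": p.text,
            }
            if p.language is not None:
                rec["language"] = p.language
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def save_clean_corpus(posts: Iterable[CleanPost], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in posts:
            rec = {
                "post_id": p.post_id,
                "user_id": p.user_id,
                "forum_id": p.forum_id,
                "timestamp": p.timestamp.isoformat(),
                "text": p.text,
                "cleaned_text": p.cleaned_text,
                "language": p.language,
                "discarded": p.discarded,
                "reason": p.reason,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def load_clean_corpus(path: str | Path) -> list[CleanPost]:
    posts = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                posts.append(
                    CleanPost(
                        post_id=str(rec["post_id"]),
                        user_id=str(rec["user_id"]),
                        forum_id=str(rec["forum_id"]),
                        timestamp=datetime.fromisoformat(rec["timestamp"]),
                        text=str(rec["text"]),
                        cleaned_text=str(rec["cleaned_text"]),
                        language=rec.get("language"),
                        discarded=bool(rec.get("discarded", False)),
                        reason=rec.get("reason"),
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise CorpusError(f"{path}: unparseable record at line {lineno}: {exc}") from exc
    return posts


# ---------------------------------------------------------------------------
# Cleaning

# Quote and signature blocks are delimited by explicit markers in the corpus
# format (forum scrapers normalise per-site HTML into these).
import re

# innermost blocks first (no opener inside), iterated for nested quoting
_QUOTE_RE = re.compile(
    r"\[quote\](?:(?!\[quote\]).)*?\[/quote\]", re.DOTALL | re.IGNORECASE
)
_SIG_RE = re.compile(
    r"\[signature\](?:(?!\[signature\]).)*?\[/signature\]", re.DOTALL | re.IGNORECASE
)


def strip_blocks(text: str) -> str:
    """Remove quote and signature blocks, innermost-first until stable."""
    prev = None
    while prev != text:
        prev = text
        text = _QUOTE_RE.sub(" ", text)
        text = _SIG_RE.sub(" ", text)
    return text


def clean_post(raw: RawPost) -> CleanPost:
    """Strip quote/signature blocks and normalise whitespace.

    A post whose text is exhausted by the removed blocks is discarded with
    reason ``empty_after_cleaning``.
    """
    if raw.text is None:
        raise CorpusError(f"post {raw.post_id}: null text")
    cleaned = normalize_ws(strip_blocks(raw.text))
    post = CleanPost(
        post_id=raw.post_id,
        user_id=raw.user_id,
        forum_id=raw.forum_id,
        timestamp=raw.timestamp,
        text=raw.text,
        cleaned_text=cleaned,
        language=raw.language,
    )
    if not cleaned:
        return post.discard(REASON_EMPTY)
    return post


def deduplicate(posts: Sequence[CleanPost]) -> list[CleanPost]:
    """Mark exact duplicates (same user, identical cleaned text) as discarded.

    The earliest copy by timestamp survives (file order breaks ties); the
    rule is scoped per user, so a common short post shared by different users
    is never removed.  Idempotent, order-preserving.
    """
    best: dict[tuple[str, str], CleanPost] = {}
    for p in posts:
        if p.discarded:
            continue
        key = (p.user_id, p.cleaned_text)
        if key not in best or p.timestamp < best[key].timestamp:
            best[key] = p
    out = []
    for p in posts:
        if p.discarded:
            out.append(p)
        elif best[(p.user_id, p.cleaned_text)] is not p:
            out.append(p.discard(REASON_DUPLICATE))
        else:
            out.append(p)
    return out


_FRENCH_MARKERS = frozenset(
    "je tu il elle on nous vous ils elles le la les un une des du de et ou est "
    "suis ai pas ne que qui pour avec dans mon ma mes son sa ses ce cette".split()
)
_ENGLISH_MARKERS = frozenset(
    "the and you for have this that with not are was but they what from "
    "your can will one all would there their".split()
)


def heuristic_language(text: str) -> str:
    """Tiny stopword-vote language detector (``fr``/``en``/``unknown``)."""
    tokens = tokenize(text)
    fr = sum(t in _FRENCH_MARKERS for t in tokens)
    en = sum(t in _ENGLISH_MARKERS for t in tokens)
    if fr > en:
        return "fr"
    if en > fr:
        return "en"
    return "unknown"


def filter_language(
    posts: Sequence[CleanPost],
    detector: Callable[[str], str] | None = None,
) -> list[CleanPost]:
    """Discard non-French posts.

    An explicit ``language`` tag wins; otherwise the detector (default: a
    stopword-vote heuristic) is consulted.  Detector failure or an
    ``unknown`` verdict lets the post pass (fail-open) with a warning, so a
    flaky backend can never silently shrink the corpus.
    """
    detector = detector or heuristic_language
    out = []
    for p in posts:
        if p.discarded:
            out.append(p)
            continue
        tag = p.language
        if tag is None:
            try:
                tag = detector(p.cleaned_text)
            except Exception as exc:  # fail-open
                warnings.warn(f"language detector failed on {p.post_id}: {exc}")
                tag = "fr"
        if tag is not None and tag.lower().startswith("fr"):
            out.append(replace(p, language=tag))
        elif tag == "unknown" or tag is None:
            warnings.warn(f"post {p.post_id}: language undetermined, passing")
            out.append(replace(p, language=tag))
        else:
            out.append(replace(p, language=tag).discard(REASON_NON_FRENCH))
    return out


# ---------------------------------------------------------------------------
# Keyword table and group assignment

_VALID_CATEGORIES = frozenset(_CATEGORY_TO_GROUP)


class KeywordTable:
    """Paracetamol-product keyword table (keyword, category, canonical_brand).

    Matching is whole-word, case/diacritic-folded, leftmost-longest, so a
    short keyword never fires inside an unrelated longer word and a
    combination brand ("dafalgan codeine") shadows its base brand at the same
    position.
    """

    def __init__(self, rows: Iterable[tuple[str, str, str]]):
        rows = list(rows)
        if not rows:
            raise CorpusError("empty keyword table")
        for kw, cat, _brand in rows:
            if cat not in _VALID_CATEGORIES:
                raise CorpusError(f"keyword {kw!r}: unknown category {cat!r}")
        self.rows = rows
        self._matcher = DictionaryMatcher(
            (kw, (cat, brand)) for kw, cat, brand in rows
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KeywordTable":
        rows = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            expected = ["keyword", "category", "canonical_brand"]
            if header != expected:
                raise CorpusError(f"{path}: expected header {expected}, got {header}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 3:
                    raise CorpusError(f"{path}: malformed row at line {lineno}")
                rows.append(tuple(parts))
        return cls(rows)

    def find_mentions(self, text: str):
        """Keyword matches in ``text`` as (start, end, category, brand)."""
        return [
            (m.start, m.end, m.payload[0], m.payload[1])
            for m in self._matcher.find(text)
        ]


def assign_groups(post: CleanPost, table: KeywordTable) -> GroupAssignment:
    """Map a post's matched product keywords to its analysis groups.

    The Aggregate group is present whenever any keyword matched; a post with
    no match gets an empty group set and leaves the analysis corpus.
    """
    if post.discarded:
        raise CorpusError(f"post {post.post_id} is discarded ({post.reason})")
    cats = {cat for _s, _e, cat, _b in table.find_mentions(post.cleaned_text)}
    groups = {_CATEGORY_TO_GROUP[c] for c in cats}
    if groups:
        groups.add(AGGREGATE)
    return GroupAssignment(post_id=post.post_id, groups=frozenset(groups))


def clean_corpus(
    raws: Sequence[RawPost],
    detector: Callable[[str], str] | None = None,
) -> list[CleanPost]:
    """clean → deduplicate → language-filter, logging record counts."""
    cleaned = [clean_post(r) for r in raws]
    cleaned = deduplicate(cleaned)
    cleaned = filter_language(cleaned, detector)
    kept = sum(not p.discarded for p in cleaned)
    logger.info("clean_corpus: %d in, %d kept, %d discarded", len(raws), kept, len(raws) - kept)
    return cleaned
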