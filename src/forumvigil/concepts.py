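"""Medical-concept tagging against a preferred-term dictionary.

The dictionary has the shape of a regulatory terminology of preferred terms
(concept_id, preferred_term) enriched with a consumer-vocabulary layer: each
``consumer`` surface form (e.g. "mal au crane") maps to a concept that also
has a ``standard`` surface form (e.g. "cephalee").  The licensed terminology
itself is not distributed; a small demo dictionary ships for tests and the
synthetic corpus.

Tagging is leftmost-longest non-overlapping dictionary matching on folded
text; every occurrence yields one mention, with 0-based half-open character
offsets on the post's cleaned text.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from forumvigil._match import DictionaryMatcher


class DictionaryError(ValueError):
    """Invalid concept dictionary file."""


@dataclass(frozen=True)
class ConceptEntry:
    surface_form: str
    concept_id: str
    preferred_term: str
    layer: str  # standard | consumer


@dataclass(frozen=True)
class ConceptMention:
    post_id: str | None
    start: int
    end: int
    concept_id: str
    preferred_term: str
    layer: str


class ConceptDictionary:
    def __init__(self, entries: Iterable[ConceptEntry]):
        entries = list(entries)
        standard_ids = {e.concept_id for e in entries if e.layer == "standard"}
        for e in entries:
            if e.layer not in ("standard", "consumer"):
                raise DictionaryError(f"{e.surface_form!r}: unknown layer {e.layer!r}")
            if e.layer == "consumer" and e.concept_id not in standard_ids:
                raise DictionaryError(
                    f"consumer form {e.surface_form!r} maps to concept "
                    f"{e.concept_id!r} with no standard entry"
                )
        try:
            self._matcher = DictionaryMatcher((e.surface_form, e) for e in entries)
        except ValueError as exc:
            raise DictionaryError(str(exc)) from exc
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def concept_ids(self) -> frozenset[str]:
        return frozenset(e.concept_id for e in self.entries)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConceptDictionary":
        expected = ["surface_form", "concept_id", "preferred_term", "layer"]
        entries = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != expected:
                raise DictionaryError(f"{path}: expected header {expected}, got {header}")
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 4:
                    raise DictionaryError(f"{path}: malformed row at line {lineno}")
                entries.append(ConceptEntry(*parts))
        return cls(entries)


def load_dictionary(path: str | Path) -> ConceptDictionary:
    return ConceptDictionary.from_tsv(path)


def tag_concepts(
    text: str, dictionary: ConceptDictionary, post_id: str | None = None
) -> list[ConceptMention]:
    """All concept mentions in ``text``, one per occurrence, left to right."""
    return [
        ConceptMention(
            post_id=post_id,
            start=m.start,
            end=m.end,
            concept_id=m.payload.concept_id,
            preferred_term=m.payload.preferred_term,
            layer=m.payload.layer,
        )
        for m in dictionary._matcher.find(text)
    ]
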