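"""Dictionary matcher: leftmost-longest, non-overlapping, whole-word.

Shared by keyword-group assignment, the medical-concept tagger and drug-list
named-entity recognition.  Surface forms are folded (case/diacritic
insensitive); multi-word forms must appear with single spaces between words.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Any, Iterable

from forumvigil._text import _WORD_RE, fold


@dataclass(frozen=True)
class Match:
    start: int
    end: int  # half-open
    surface: str  # folded surface form as stored in the dictionary
    payload: Any


class DictionaryMatcher:
    """Greedy left-to-right scanner over folded text.

    At each word start the longest dictionary surface form anchored there and
    ending at a word boundary wins; the scan resumes after it, so matches
    never overlap.
    """

    def __init__(self, entries: Iterable[tuple[str, Any]]):
        self._index: dict[str, Any] = {}
        self._max_words = 1
        for surface, payload in entries:
            key = " ".join(fold(surface).split())
            if not key:
                raise ValueError("empty surface form")
            if key in self._index:
                raise ValueError(f"duplicate surface form after folding: {key!r}")
            self._index[key] = payload
            self._max_words = max(self._max_words, key.count(" ") + 1)

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, surface: str) -> bool:
        return " ".join(fold(surface).split()) in self._index

    def payload(self, surface: str) -> Any:
        return self._index[" ".join(fold(surface).split())]

    def find(self, text: str) -> list[Match]:
        folded = fold(text)
        spans = [m.span() for m in _WORD_RE.finditer(folded)]
        matches: list[Match] = []
        i = 0
        n = len(spans)
        while i < n:
            hit = None
            for length in range(min(self._max_words, n - i), 0, -1):
                start = spans[i][0]
                end = spans[i + length - 1][1]
                candidate = folded[start:end]
                if candidate in self._index:
                    hit = (start, end, candidate, length)
                    break
            if hit is None:
                i += 1
            else:
                start, end, candidate, length = hit
                matches.append(Match(start, end, candidate, self._index[candidate]))
                i += length
        return matches


_WS_RE = re.compile(r"\s+")


def normalize_ws(text: str) -> str:
    """Collapse whitespace runs to single spaces and strip the ends."""
    return _WS_RE.sub(" ", text).strip()
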