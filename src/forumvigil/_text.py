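"""Length-preserving text folding and a light regex tokenizer.

French forum text is matched case- and diacritic-insensitively throughout the
pipeline.  Folding is done character by character so that every character
offset in the folded string maps to the same offset in the original text --
mentions can then be located on the folded text and reported as spans on the
original.
"""

from __future__ import annotations

import re
import unicodedata
from functools import lru_cache

_WORD_RE = re.compile(r"[0-9a-zÀ-ɏ]+", re.IGNORECASE)


@lru_cache(maxsize=4096)
def _fold_char(ch: str) -> str:
    low = ch.lower()
    if len(low) != 1:  # rare expansions (e.g. İ) — keep original length
        low = ch
    decomposed = unicodedata.normalize("NFD", low)
    base = "".join(c for c in decomposed if not unicodedata.combining(c))
    return base if len(base) == 1 else low


def fold(text: str) -> str:
    """Lowercase and strip diacritics, preserving string length.

    ``fold("Tête")`` is ``"tete"``; offsets into the folded string are valid
    offsets into ``text``.
    """
    return "".join(_fold_char(ch) for ch in text)


def tokenize(text: str) -> list[str]:
    """Word tokens of the folded text, in order."""
    return _WORD_RE.findall(fold(text))


def token_spans(text: str) -> list[tuple[int, int]]:
    """(start, end) character spans of word tokens, half-open, on ``text``."""
    return [m.span() for m in _WORD_RE.finditer(fold(text))]
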