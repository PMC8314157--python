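"""User gender and age inference from post text.

Gender rides on French gendered morphology: past participles, adjectives and
self-descriptions carry the writer's gender almost deterministically
("je suis allée" vs "allé"), so a lexicon of gendered word forms decides
first whenever its votes are unanimous.  Users without any gendered marker
fall through to a linear support-vector classifier (cost C=1) over token
unigrams of their concatenated posts; a decision margin below the threshold
yields ``unknown`` rather than a guess.

Age comes from explicit first-person statements ("j'ai 34 ans"); third-person
ages ("ma fille a 5 ans") are out of scope of the pattern and ignored.  Ages
are binned as 0-20, 21-30, 31-40, 41-50, 51-60, 60+ — the last two resolved
as [51,60] and [61,inf) so every age falls in exactly one bin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from sklearn.feature_extraction.text import CountVectorizer
from sklearn.svm import LinearSVC

from forumvigil._text import fold, tokenize
from forumvigil.corpus import CleanPost

FEMALE = "female"
MALE = "male"
UNKNOWN = "unknown"

AGE_BINS = ("0-20", "21-30", "31-40", "41-50", "51-60", "60+")


@dataclass(frozen=True)
class UserProfile:
    user_id: str
    gender: str
    age_years: int | None
    age_bin: str


def load_gender_lexicon(path: str | Path) -> dict[str, str]:
    """TSV of (form, gender) rows mapping folded word forms to female/male."""
    lex: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["form", "gender"]:
            raise ValueError(f"{path}: expected header ['form', 'gender'], got {header}")
        for line in fh:
            if not line.strip():
                continue
            form, gender = line.rstrip("\n").split("\t")
            if gender not in (FEMALE, MALE):
                raise ValueError(f"{path}: bad gender {gender!r} for form {form!r}")
            lex[fold(form)] = gender
    return lex


class GenderClassifier:
    """Linear SVM (cost 1) over token unigrams of a user's concatenated posts."""

    def __init__(self, margin_threshold: float = 0.5):
        self.margin_threshold = margin_threshold
        self._vec = CountVectorizer(analyzer=tokenize)
        self._svm = LinearSVC(C=1.0)
        self._fitted = False

    def fit(self, texts: Sequence[str], labels: Sequence[str]) -> "GenderClassifier":
        if set(labels) - {FEMALE, MALE}:
            raise ValueError("training labels must be female/male")
        X = self._vec.fit_transform(texts)
        self._svm.fit(X, list(labels))
        self._fitted = True
        return self

    def predict(self, text: str) -> str:
        if not self._fitted:
            return UNKNOWN
        X = self._vec.transform([text])
        margin = float(self._svm.decision_function(X)[0])
        if abs(margin) < self.margin_threshold:
            return UNKNOWN
        return self._svm.classes_[int(margin > 0)]


def detect_gender(
    user_texts: Sequence[str],
    gender_lexicon: Mapping[str, str],
    model: GenderClassifier | None = None,
) -> str:
    """Rule layer first: unanimous lexicon votes decide; else the classifier.

    Never raises — with no lexicon hit and no (trained) model the result is
    ``unknown``.
    """
    votes = set()
    for text in user_texts:
        for tok in tokenize(text):
            g = gender_lexicon.get(tok)
            if g is not None:
                votes.add(g)
    if len(votes) == 1:
        return votes.pop()
    if model is not None:
        return model.predict(" ".join(user_texts))
    return UNKNOWN


# First-person age statement; the subject must be "je" ("j'ai 34 ans"),
# which excludes third-person forms like "ma fille a 5 ans".
_AGE_RE = re.compile(r"\bj\W{0,2}ai\s+(\d{1,3})\s+ans\b")


def extract_age(user_texts: Sequence[str]) -> int | None:
    """Age from first-person statements; texts in chronological order.

    When a user states different ages in different posts, the most recent
    post wins (people age; later statements supersede earlier ones).
    """
    age = None
    for text in user_texts:
        matches = _AGE_RE.findall(fold(text))
        if matches:
            age = int(matches[-1])
    return age


def bin_age(age_years: int | None) -> str:
    if age_years is None:
        return "Unknown"
    if age_years < 0:
        raise ValueError("age must be nonnegative")
    for upper, label in ((20, "0-20"), (30, "21-30"), (40, "31-40"), (50, "41-50"), (60, "51-60")):
        if age_years <= upper:
            return label
    return "60+"


def build_profiles(
    posts: Iterable[CleanPost],
    gender_lexicon: Mapping[str, str],
    model: GenderClassifier | None = None,
) -> list[UserProfile]:
    """Per-user profiles from the non-discarded posts of a cleaned corpus."""
    by_user: dict[str, list[CleanPost]] = {}
    for p in posts:
        if not p.discarded:
            by_user.setdefault(p.user_id, []).append(p)
    profiles = []
    for user_id in sorted(by_user):
        texts = [p.cleaned_text for p in sorted(by_user[user_id], key=lambda p: p.timestamp)]
        gender = detect_gender(texts, gender_lexicon, model)
        age = extract_age(texts)
        profiles.append(
            UserProfile(user_id=user_id, gender=gender, age_years=age, age_bin=bin_age(age))
        )
    return profiles
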