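"""Seeded synthetic French-like forum corpora with ground-truth labels.

The generator emulates the statistical structure the pipeline assumes:
seasonal monthly post volume with optional regime shifts (winter peak,
December-February), a configurable gender mix (default 71% female / 12%
male / 17% unknown), an age mixture over the report's age bins, and posts
assembled from templates that plant group keywords, intake vs non-intake
phrasing, medical concepts, adverse-event contexts, dependence phrasing,
dose expressions and child-use contexts — all drawn from the same bundled
lexicons the detectors load, so every planted signal is recoverable and
recorded in a per-post ground-truth table.

Generation is template-based rather than free text: label/text consistency
is guaranteed by construction, which is what makes desk-scale round-trip
evaluation meaningful.  Identical (config, seed) produces byte-identical
output.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from forumvigil import resources
from forumvigil.corpus import RawPost, save_corpus

_AGE_BIN_RANGES = {
    "0-20": (8, 20),
    "21-30": (21, 30),
    "31-40": (31, 40),
    "41-50": (41, 50),
    "51-60": (51, 60),
    "60+": (61, 85),
}

# Default age mixture follows the aggregate-user age distribution of the
# study population this generator emulates.
_DEFAULT_AGE_DIST = {
    "0-20": 0.1008,
    "21-30": 0.2612,
    "31-40": 0.2686,
    "41-50": 0.1154,
    "51-60": 0.0587,
    "60+": 0.1250,
    "Unknown": 0.0703,
}


@dataclass(frozen=True)
class MisuseRates:
    """Per-post probabilities of planted signal classes.

    Intake is drawn per post; the misuse signals (dependence phrasing,
    overdose phrasing, adverse-event context) are drawn only for adult
    intake posts, matching the corpus slice the detectors operate on.
    """

    intake: float = 0.55
    dependence: float = 0.05
    overdose: float = 0.05
    pae: float = 0.10


@dataclass(frozen=True)
class GeneratorConfig:
    n_users: int = 200
    n_posts: int = 2000
    start_month: str = "2003-01"
    end_month: str = "2006-12"
    seasonal_amplitude: float = 0.3
    # (start_month, end_month, volume multiplier), inclusive ISO months
    regime_schedule: tuple[tuple[str, str, float], ...] = ()
    gender_mix: tuple[float, float, float] = (0.71, 0.12, 0.17)  # female, male, unknown
    age_distribution: dict = field(default_factory=lambda: dict(_DEFAULT_AGE_DIST))
    misuse_rates: MisuseRates = field(default_factory=MisuseRates)
    p_concept: float = 0.5
    p_codrug: float = 0.25
    p_gender_marker: float = 0.5
    p_english: float = 0.02
    p_duplicate: float = 0.02
    p_quote: float = 0.15
    p_signature: float = 0.15
    p_empty: float = 0.01
    p_child: float = 0.03
    noise: float = 0.0  # typo-corruption rate; exercises classifier paths
    seed: int = 0

    def __post_init__(self):
        if not (self.n_posts == 0 or self.n_posts >= self.n_users >= 1):
            raise ValueError("need n_posts >= n_users >= 1 (or n_posts == 0)")
        if abs(sum(self.gender_mix) - 1.0) > 1e-9:
            raise ValueError("gender_mix must sum to 1")
        if abs(sum(self.age_distribution.values()) - 1.0) > 1e-3:
            raise ValueError("age_distribution must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "misuse_rates" in raw:
            raw["misuse_rates"] = MisuseRates(**raw["misuse_rates"])
        if "regime_schedule" in raw:
            raw["regime_schedule"] = tuple(tuple(r) for r in raw["regime_schedule"])
        if "gender_mix" in raw:
            raw["gender_mix"] = tuple(raw["gender_mix"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Timestamp sampling

def month_rates(config: GeneratorConfig) -> tuple[pd.PeriodIndex, np.ndarray]:
    """Expected post count per calendar month under the config.

    Rate(month) = base x (1 + amplitude*cos(2*pi*(month-1)/12)) x regime
    multiplier, phased so the peak falls on January (winter); the base rate
    normalizes the total expectation to ``n_posts``.
    """
    months = pd.period_range(config.start_month, config.end_month, freq="M")
    if len(months) == 0:
        raise ValueError("empty date_range")
    factors = 1.0 + config.seasonal_amplitude * np.cos(
        2.0 * np.pi * (months.month.to_numpy() - 1) / 12.0
    )
    for start, end, mult in config.regime_schedule:
        lo, hi = pd.Period(start, freq="M"), pd.Period(end, freq="M")
        mask = (months >= lo) & (months <= hi)
        factors = np.where(mask, factors * mult, factors)
    if factors.sum() <= 0:
        raise ValueError("degenerate rate schedule")
    base = config.n_posts / factors.sum()
    return months, base * factors


def sample_timestamps(config: GeneratorConfig, rng: np.random.Generator) -> list[datetime]:
    """Poisson month counts around the seasonal/regime rate, then uniform
    placement within each month.  Deterministic per (config, seed)."""
    months, rates = month_rates(config)
    stamps: list[datetime] = []
    for period, lam in zip(months, rates):
        count = int(rng.poisson(lam))
        days_in_month = calendar.monthrange(period.year, period.month)[1]
        days = rng.integers(1, days_in_month + 1, size=count)
        minutes = rng.integers(0, 24 * 60, size=count)
        for d, m in zip(days, minutes):
            stamps.append(
                datetime(period.year, period.month, int(d)) + timedelta(minutes=int(m))
            )
    stamps.sort()
    return stamps


# ---------------------------------------------------------------------------
# Template fragments

_FEMALE_MARKERS = (
    "je suis allee a la pharmacie ce matin.",
    "je suis contente du conseil recu.",
    "je suis inquiete ce soir.",
    "je suis epuisee par cette semaine.",
)
_MALE_MARKERS = (
    "je suis alle a la pharmacie ce matin.",
    "je suis content du conseil recu.",
    "je suis inquiet ce soir.",
    "je suis epuise par cette semaine.",
)

_INTAKE_MAIN = (
    "j'ai pris du {drug} hier soir{codrug}.",
    "je prends du {drug} depuis trois jours{codrug}.",
    "j'ai avale un {drug} avant le repas{codrug}.",
)
_NONINTAKE_MAIN = (
    "mon medecin m'a conseille le {drug} mais je me pose la question.",
    "on m'a parle du {drug} sur un autre forum.",
    "le pharmacien m'a recommande le {drug} pour plus tard.",
)
_BENIGN_DOSE = " j'ai pris 1 comprime de 500 mg ce matin."

_PAE_MAIN = (
    "j'ai pris du {drug} et aussitot {concept} terrible.",
    "je prends du {drug} puis {concept} violente ce soir.",
)
_PAE_CONCEPTS = ("nausee", "vomissement", "vertige", "somnolence")

_CONCEPT_SENTENCE = (
    "cela fait des jours que je supporte {concept} sans relache.",
    "la {concept} ne me quitte jamais cette saison.",
)
_STANDALONE_CONCEPTS = (
    "douleur",
    "fatigue",
    "insomnie",
    "fievre",
    "migraine",
    "mal de tete",
    "rhume",
)
# the concepts above that the demo SmPC marks unapproved for every category
UNAPPROVED_CONCEPTS = frozenset({"fatigue", "insomnie"})

_DEPENDENCE_BLOCK = (
    "la desintoxication me fait peur car je suis accro au {drug} et le manque me detruit.",
    "le sevrage du {drug} est un echec et ma dependance grandit avec cette addiction.",
    "impossible d'arreter le {drug} car je dois augmenter les doses malgre la rechute.",
)

_OVERDOSE_DOSE = (
    ("je prends {g} g de {drug} par jour en ce moment.", "g"),
    ("j'avale {n} comprimes de 1000 mg, {f} fois par jour de {drug}.", "units"),
)
_OVERDOSE_LEXICAL = (
    "c'est une overdose de {drug}, je le sais bien.",
    "j'ai peur du surdosage avec le {drug} chaque soir.",
)

_CHILD_MAIN = (
    "mon fils de {age} ans a pris du {drug} hier.",
    "ma fille de {age} ans a pris du {drug} ce matin.",
)

_ENGLISH_POSTS = (
    "I took some tablets yesterday and the pain was gone by morning.",
    "Has anyone tried this for a cold? The doctor said it would help.",
)

_QUOTE_BLOCK = "[quote]un autre membre a pris du tramadol pour la meme chose[/quote] "
_SIG_BLOCK = " [signature]membre fidele du forum depuis des annees[/signature]"

_FILLERS = (
    "la journee a ete longue et le moral suit comme il peut.",
    "merci d'avance pour vos retours sur ce sujet.",
    "je passe souvent ici lire vos messages le soir.",
)

_CONCEPT_IDS = {
    "douleur": "C_PAIN",
    "fatigue": "C_FATIGUE",
    "insomnie": "C_INSOMNIA",
    "fievre": "C_PYREXIA",
    "migraine": "C_MIGRAINE",
    "mal de tete": "C_HEADACHE",
    "rhume": "C_NASOPHARYNGITIS",
    "nausee": "C_NAUSEA",
    "vomissement": "C_VOMITING",
    "vertige": "C_DIZZINESS",
    "somnolence": "C_SOMNOLENCE",
}

_CATEGORY_GROUP = {
    "paracetamol_only": "ParacetamolOnly",
    "paracetamol_opioid": "ParacetamolOpioids",
    "paracetamol_other": "ParacetamolOthers",
}

_CODRUGS = (
    ("tramadol", "tramadol"),
    ("ibuprofene", "ibuprofen"),
    ("codeine", "codeine"),
    ("cafeine", "caffeine"),
    ("aspirine", "aspirin"),
    ("xanax", "alprazolam"),
)


@dataclass
class _User:
    user_id: str
    gender: str
    age: int | None
    stated_age: bool = False


def _load_keywords() -> list[tuple[str, str, str]]:
    rows = []
    with open(resources.path(resources.KEYWORDS), encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            if line.strip():
                rows.append(tuple(line.rstrip("\n").split("\t")))
    return rows


def _sample_users(config: GeneratorConfig, rng: np.random.Generator) -> list[_User]:
    genders = rng.choice(
        ["female", "male", "unknown"], size=config.n_users, p=list(config.gender_mix)
    )
    bins = list(config.age_distribution)
    probs = np.array([config.age_distribution[b] for b in bins], dtype=float)
    probs /= probs.sum()
    users = []
    for i in range(config.n_users):
        b = rng.choice(bins, p=probs)
        if b == "Unknown":
            age = None
        else:
            lo, hi = _AGE_BIN_RANGES[b]
            age = int(rng.integers(lo, hi + 1))
        users.append(_User(user_id=f"u{i:05d}", gender=str(genders[i]), age=age))
    return users


def _corrupt(text: str, rng: np.random.Generator) -> str:
    """Swap one random pair of adjacent letters (typo noise)."""
    idx = [i for i in range(len(text) - 1) if text[i].isalpha() and text[i + 1].isalpha()]
    if not idx:
        return text
    i = int(rng.choice(idx))
    return text[:i] + text[i + 1] + text[i] + text[i + 2 :]


def render_post(
    user: _User,
    rng: np.random.Generator,
    config: GeneratorConfig,
    keywords: Sequence[tuple[str, str, str]],
) -> tuple[str, dict]:
    """One post's text plus its ground-truth row (timestamps added later)."""
    truth: dict = {
        "user_id": user.user_id,
        "language": "fr",
        "duplicate": False,
        "empty": False,
        "child": False,
        "groups": "",
        "intake": False,
        "concepts": "",
        "pae": False,
        "pae_concept": "",
        "drug": "",
        "codrugs": "",
        "dose_mg": "",
        "dependence": False,
        "overdose": False,
        "overdose_mode": "",
        "unapproved_candidate": False,
        "user_gender": user.gender,
        "user_age": "" if user.age is None else user.age,
    }
    r = config.misuse_rates

    if rng.random() < config.p_english:
        truth["language"] = "en"
        return str(rng.choice(_ENGLISH_POSTS)), truth
    if rng.random() < config.p_empty:
        truth["empty"] = True
        return _SIG_BLOCK.strip(), truth

    kw, category, brand = keywords[int(rng.integers(len(keywords)))]
    truth["drug"] = brand
    truth["groups"] = "|".join(sorted({_CATEGORY_GROUP[category], "Aggregate"}))

    sentences: list[str] = []
    if user.gender == "female" and rng.random() < config.p_gender_marker:
        sentences.append(str(rng.choice(_FEMALE_MARKERS)))
    elif user.gender == "male" and rng.random() < config.p_gender_marker:
        sentences.append(str(rng.choice(_MALE_MARKERS)))
    if user.age is not None and not user.stated_age:
        sentences.append(f"j'ai {user.age} ans et je viens souvent ici.")
        user.stated_age = True

    concepts: list[str] = []
    child = rng.random() < config.p_child
    if child:
        truth["child"] = True
        age = int(rng.integers(1, 13))
        sentences.append(str(rng.choice(_CHILD_MAIN)).format(age=age, drug=kw))
    else:
        intake = rng.random() < r.intake
        truth["intake"] = intake
        if intake:
            pae = rng.random() < r.pae
            codrug = ""
            if rng.random() < config.p_codrug:
                surface, canonical = _CODRUGS[int(rng.integers(len(_CODRUGS)))]
                codrug = f" avec du {surface}"
                truth["codrugs"] = canonical
            if pae:
                concept = str(rng.choice(_PAE_CONCEPTS))
                concepts.append(_CONCEPT_IDS[concept])
                truth["pae"] = True
                truth["pae_concept"] = _CONCEPT_IDS[concept]
                sentences.append(
                    str(rng.choice(_PAE_MAIN)).format(drug=kw, concept=concept)
                )
                if codrug:
                    sentences[-1] += f" je l'associe{codrug}."
            else:
                main = str(rng.choice(_INTAKE_MAIN)).format(drug=kw, codrug=codrug)
                if rng.random() < 0.3:
                    main += _BENIGN_DOSE
                sentences.append(main)
                if rng.random() < config.p_concept:
                    concept = str(rng.choice(_STANDALONE_CONCEPTS))
                    concepts.append(_CONCEPT_IDS[concept])
                    sentences.append(
                        str(rng.choice(_CONCEPT_SENTENCE)).format(concept=concept)
                    )
            if rng.random() < r.dependence:
                truth["dependence"] = True
                sentences.extend(s.format(drug=kw) for s in _DEPENDENCE_BLOCK)
            if rng.random() < r.overdose:
                truth["overdose"] = True
                if rng.random() < 0.7:
                    truth["overdose_mode"] = "dose"
                    template, kind = _OVERDOSE_DOSE[int(rng.integers(len(_OVERDOSE_DOSE)))]
                    if kind == "g":
                        g = int(rng.choice([6, 8, 10, 12]))
                        truth["dose_mg"] = g * 1000
                        sentences.append(template.format(g=g, drug=kw))
                    else:
                        n_u, f = [(2, 3), (3, 3), (4, 2), (8, 3)][int(rng.integers(4))]
                        truth["dose_mg"] = n_u * 1000 * f
                        sentences.append(template.format(n=n_u, f=f, drug=kw))
                else:
                    truth["overdose_mode"] = "lexical"
                    sentences.append(
                        str(rng.choice(_OVERDOSE_LEXICAL)).format(drug=kw)
                    )
        else:
            sentences.append(str(rng.choice(_NONINTAKE_MAIN)).format(drug=kw))
            if rng.random() < config.p_concept:
                concept = str(rng.choice(_STANDALONE_CONCEPTS))
                concepts.append(_CONCEPT_IDS[concept])
                sentences.append(
                    str(rng.choice(_CONCEPT_SENTENCE)).format(concept=concept)
                )
        if (
            truth["intake"]
            and concepts
            and not truth["pae"]
            and all(_is_unapproved(c) for c in concepts)
        ):
            truth["unapproved_candidate"] = True

    if rng.random() < 0.4:
        sentences.append(str(rng.choice(_FILLERS)))
    truth["concepts"] = "|".join(dict.fromkeys(concepts))

    text = " ".join(sentences)
    if config.noise > 0 and rng.random() < config.noise:
        text = _corrupt(text, rng)
    if rng.random() < config.p_quote:
        text = _QUOTE_BLOCK + text
    if rng.random() < config.p_signature:
        text = text + _SIG_BLOCK
    return text, truth


_UNAPPROVED_IDS = frozenset({"C_FATIGUE", "C_INSOMNIA"})


def _is_unapproved(concept_id: str) -> bool:
    return concept_id in _UNAPPROVED_IDS


def generate_corpus(config: GeneratorConfig) -> tuple[list[RawPost], pd.DataFrame]:
    """Full synthetic corpus plus its ground-truth table.

    Returns posts sorted by timestamp and a DataFrame keyed by post_id with
    per-post labels and the user's gender/age.
    """
    rng = np.random.default_rng(config.seed)
    if config.n_posts == 0:
        return [], pd.DataFrame()
    users = _sample_users(config, rng)
    stamps = sample_timestamps(config, rng)
    posts: list[RawPost] = []
    rows: list[dict] = []
    for i, ts in enumerate(stamps):
        user = users[int(rng.integers(len(users)))]
        text, truth = render_post(user, rng, config, _KEYWORDS)
        post_id = f"p{i:06d}"
        truth["post_id"] = post_id
        truth["timestamp"] = ts.isoformat()
        posts.append(
            RawPost(
                post_id=post_id,
                user_id=user.user_id,
                forum_id=f"f{int(rng.integers(1, 19)):02d}",
                timestamp=ts,
                text=text,
                language=truth["language"],
            )
        )
        rows.append(truth)

    # exact later duplicates of random earlier posts (same user, same text)
    n_dup = int(round(config.p_duplicate * len(posts)))
    if n_dup and posts:
        for j, src in enumerate(rng.choice(len(posts), size=n_dup, replace=False)):
            orig, orig_truth = posts[int(src)], rows[int(src)]
            post_id = f"d{j:06d}"
            dup_truth = dict(orig_truth)
            dup_truth.update(post_id=post_id, duplicate=True)
            ts = orig.timestamp + timedelta(days=1)
            dup_truth["timestamp"] = ts.isoformat()
            posts.append(replace(orig, post_id=post_id, timestamp=ts))
            rows.append(dup_truth)

    order = sorted(range(len(posts)), key=lambda i: (posts[i].timestamp, posts[i].post_id))
    posts = [posts[i] for i in order]
    truth = pd.DataFrame([rows[i] for i in order]).set_index("post_id")
    return posts, truth


_KEYWORDS = _load_keywords()


def write_corpus(
    posts: Sequence[RawPost], truth: pd.DataFrame, posts_path: str | Path, truth_path: str | Path
) -> None:
    save_corpus(posts, posts_path)
    truth.to_csv(truth_path, sep="\t")
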