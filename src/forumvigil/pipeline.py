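"""End-to-end pipeline orchestration.

Stages run in a fixed order (clean → groups → demographics → concepts →
topics → intake → co-consumption → safety → activity → report); every stage
logs its input/output record counts and a rerun with the same configuration
and seed is bit-identical.  One global seed fans out to per-stage seeds by
fixed offsets so each stage is also individually reproducible.

The learned stages (gender SVM, intake random forest, adverse-event SVM)
need sentence/pair labels to train on.  On synthetic corpora the generator's
ground-truth table provides them; gender additionally self-trains on the
users the morphological rule layer labels unambiguously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from forumvigil import concepts as concepts_mod
from forumvigil import demographics as demo_mod
from forumvigil import intake as intake_mod
from forumvigil import reporting, resources, safety
from forumvigil import topics as topics_mod
from forumvigil.activity import build_monthly_series, deseasonalize, segment_activity
from forumvigil.corpus import (
    AGGREGATE,
    KeywordTable,
    assign_groups,
    clean_corpus,
    load_corpus,
)

logger = logging.getLogger(__name__)

_SEED_OFFSETS = {"gender": 1, "topics": 2, "intake": 3, "pae": 4, "sampling": 5, "hmm": 6}


@dataclass
class PipelineConfig:
    corpus_path: str
    truth_path: str | None = None  # ground-truth TSV for the supervised stages
    keywords_path: str = str(resources.path(resources.KEYWORDS))
    concepts_path: str = str(resources.path(resources.CONCEPTS))
    drugs_path: str = str(resources.path(resources.DRUGS))
    gender_lexicon_path: str = str(resources.path(resources.GENDER_LEXICON))
    intake_lexicon_path: str = str(resources.path(resources.INTAKE_LEXICON))
    dependency_lexicon_path: str = str(resources.path(resources.DEPENDENCY_LEXICON))
    overdose_lexicon_path: str = str(resources.path(resources.OVERDOSE_LEXICON))
    smpc_path: str = str(resources.path(resources.SMPC))
    dose_units_path: str = str(resources.path(resources.DOSE_UNITS))
    stopwords_path: str = str(resources.path(resources.STOPWORDS))
    n_topics: int = 6
    min_count: int = 2
    bm25_k1: float = 1.2
    bm25_b: float = 0.75
    dependence_threshold: float = 40.0
    dose_threshold_mg: float = 4000.0
    rf_trees: int = 500
    sampling_fraction: float = 0.10
    hmm_restarts: int = 10
    min_run: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in (
            "corpus_path",
            "keywords_path",
            "concepts_path",
            "drugs_path",
            "gender_lexicon_path",
            "intake_lexicon_path",
            "dependency_lexicon_path",
            "overdose_lexicon_path",
            "smpc_path",
            "dose_units_path",
            "stopwords_path",
        ):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.truth_path and not Path(self.truth_path).exists():
            raise FileNotFoundError(f"truth_path: {self.truth_path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _SEED_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineResult:
    posts: list  # analysis posts (non-discarded, grouped)
    assignments: list
    profiles: list
    concept_mentions: list
    topic_result: object
    doc_topics: dict
    intake_prediction: object
    coconsumption: object
    pae: list  # (post_id, concept_id, flagged)
    dependence: list
    overdose: list
    unapproved: dict
    annotation_sample: list
    activity: object | None
    monthly: object | None
    report: reporting.GroupReport
    counts: dict = field(default_factory=dict)


def _rule_sentence_label(features: intake_mod.IntakeFeatures) -> bool:
    """Weak first-person intake rule used to localize post-level labels."""
    return (
        features.intake_lexicon_hits > 0
        and features.nonintake_lexicon_hits == 0
        and features.pronoun_proportion > 0
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    truth = None
    if config.truth_path:
        truth = pd.read_csv(config.truth_path, sep="\t", index_col="post_id")

    def stage(name):
        logger.info("stage: %s", name)

    counts: dict[str, int] = {}

    # --- clean ------------------------------------------------------------
    stage("clean")
    raws = load_corpus(config.corpus_path)
    cleaned = clean_corpus(raws)
    kept = [p for p in cleaned if not p.discarded]
    counts["raw"] = len(raws)
    counts["kept"] = len(kept)

    # --- groups -----------------------------------------------------------
    stage("groups")
    table = KeywordTable.from_tsv(config.keywords_path)
    assignments = [assign_groups(p, table) for p in kept]
    posts = [p for p, a in zip(kept, assignments) if a.groups]
    assignments = [a for a in assignments if a.groups]
    counts["grouped"] = len(posts)
    logger.info("groups: %d of %d posts matched a keyword", len(posts), len(kept))

    # --- demographics -----------------------------------------------------
    stage("demographics")
    lexicon = demo_mod.load_gender_lexicon(config.gender_lexicon_path)
    by_user: dict[str, list] = {}
    for p in posts:
        by_user.setdefault(p.user_id, []).append(p)
    rule_texts, rule_labels = [], []
    for uid, ps in sorted(by_user.items()):
        texts = [q.cleaned_text for q in sorted(ps, key=lambda q: q.timestamp)]
        g = demo_mod.detect_gender(texts, lexicon, model=None)
        if g != demo_mod.UNKNOWN:
            rule_texts.append(" ".join(texts))
            rule_labels.append(g)
    model = None
    if len(set(rule_labels)) == 2:
        model = demo_mod.GenderClassifier().fit(rule_texts, rule_labels)
    profiles = demo_mod.build_profiles(posts, lexicon, model)

    # --- concepts ---------------------------------------------------------
    stage("concepts")
    dictionary = concepts_mod.load_dictionary(config.concepts_path)
    mentions: list[concepts_mod.ConceptMention] = []
    for p in posts:
        mentions.extend(concepts_mod.tag_concepts(p.cleaned_text, dictionary, p.post_id))
    counts["concept_mentions"] = len(mentions)

    # --- topics -----------------------------------------------------------
    stage("topics")
    stop = topics_mod.load_stopwords(config.stopwords_path)
    dtm, vocab = topics_mod.build_dtm(
        [p.cleaned_text for p in posts], stopwords=stop, min_count=config.min_count
    )
    topic_result = topics_mod.fit_topics(
        dtm, vocab, K=config.n_topics, seed=config.stage_seed("topics")
    )
    dominant = topic_result.dominant_topics()
    doc_topics = {p.post_id: int(t) for p, t in zip(posts, dominant)}

    # --- intake -----------------------------------------------------------
    stage("intake")
    drug_list = intake_mod.DrugList.from_tsv(config.drugs_path)
    intake_m, nonintake_m = intake_mod.load_intake_lexicon(config.intake_lexicon_path)
    records, X_scaled = intake_mod.featurize_corpus(posts, table, drug_list, intake_m, nonintake_m)
    feats = [
        intake_mod.extract_intake_features(r, intake_m, nonintake_m) for r in records
    ]
    post_truth_intake = (
        truth["intake"].astype(bool).to_dict() if truth is not None else None
    )
    labels = []
    for r, f in zip(records, feats):
        lab = _rule_sentence_label(f)
        if post_truth_intake is not None:
            lab = lab and bool(post_truth_intake.get(r.post_id, True))
        labels.append(lab)
    model_i = intake_mod.IntakeModel(
        n_estimators=config.rf_trees, seed=config.stage_seed("intake")
    ).fit(X_scaled, labels)
    prediction = intake_mod.predict_intake(model_i, records, X_scaled)
    for p in posts:  # sentence-less or drug-less posts default to no intake
        prediction.post_intake.setdefault(p.post_id, False)
    counts["intake_posts"] = sum(prediction.post_intake.values())

    # --- co-consumption ---------------------------------------------------
    stage("coconsumption")
    cocon = intake_mod.detect_coconsumption(posts, prediction.post_intake, drug_list, table)

    # --- safety -----------------------------------------------------------
    stage("safety")
    adult_posts = safety.filter_child_posts(posts)
    counts["adult_posts"] = len(adult_posts)
    misuse_posts = [p for p in adult_posts if prediction.post_intake.get(p.post_id)]
    mentions_by_post: dict[str, list] = {}
    for m in mentions:
        mentions_by_post.setdefault(m.post_id, []).append(m)

    # PAE: pairs (post, concept mention) on intake posts with drug mentions
    pae_results: list[tuple[str, str, bool]] = []
    pae_model = None
    pae_pairs, pae_feats, pae_labels = [], [], []
    for p in misuse_posts:
        ms = mentions_by_post.get(p.post_id, [])
        if not ms:
            continue
        drug_spans = [(s, e) for s, e, _c, _b in table.find_mentions(p.cleaned_text)]
        if not drug_spans:
            continue
        for m in ms:
            f = safety.compute_pae_features(p, m, drug_spans, ms)
            pae_pairs.append((p.post_id, m.concept_id))
            pae_feats.append(f)
            if truth is not None and p.post_id in truth.index:
                row = truth.loc[p.post_id]
                pae_labels.append(bool(row["pae"]) and row.get("pae_concept") == m.concept_id)
    if truth is not None and len(set(pae_labels)) == 2:
        pae_model = safety.PAEClassifier().fit(pae_feats, pae_labels)
        pae_results = [
            (pid, cid, pae_model.predict(f))
            for (pid, cid), f in zip(pae_pairs, pae_feats)
        ]

    dep_lex = safety.load_term_list(config.dependency_lexicon_path)
    scorer = safety.DependenceScorer(
        dep_lex, k1=config.bm25_k1, b=config.bm25_b, threshold=config.dependence_threshold
    ).fit(posts, table, drug_list)
    dependence = [scorer.score_post(p, table, drug_list) for p in misuse_posts]

    od_matcher = safety.DictionaryMatcher(
        (t, None) for t in safety.load_term_list(config.overdose_lexicon_path)
    )
    dose_table = safety.DoseUnitTable.from_tsv(config.dose_units_path)
    overdose = [
        safety.detect_overdose(
            p, od_matcher, dose_table, table, threshold_mg=config.dose_threshold_mg
        )
        for p in misuse_posts
    ]

    smpc = safety.SmPCIndex.from_tsv(config.smpc_path)
    cats_by_post = {
        p.post_id: sorted({c for _s, _e, c, _b in table.find_mentions(p.cleaned_text)})
        for p in misuse_posts
    }
    unapproved = safety.find_unapproved_indications(
        misuse_posts, mentions_by_post, cats_by_post, smpc, dictionary.concept_ids
    )
    all_candidates = sorted({pid for pids in unapproved.values() for pid in pids})
    sample = safety.sample_for_annotation(
        all_candidates, config.sampling_fraction, seed=config.stage_seed("sampling")
    )

    # --- activity ---------------------------------------------------------
    stage("activity")
    monthly = build_monthly_series(posts)
    segmentation = None
    if len(monthly) >= 24:
        monthly = deseasonalize(monthly)
        segmentation = segment_activity(
            monthly,
            seed=config.stage_seed("hmm"),
            restarts=config.hmm_restarts,
            min_run=config.min_run,
        )

    # --- report -----------------------------------------------------------
    stage("report")
    report = reporting.build_report(
        {
            "posts": posts,
            "groups": assignments,
            "profiles": profiles,
            "concept_mentions": mentions,
            "doc_topics": doc_topics,
            "intake": prediction.post_intake,
            "coconsumption": cocon,
            "pae": pae_results,
            "dependence": dependence,
            "overdose": overdose,
        }
    )
    report.extras["counts"] = counts
    report.extras["unapproved_candidates"] = {k: len(v) for k, v in sorted(unapproved.items())}
    report.extras["annotation_sample_size"] = len(sample)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.write(outdir)
        if segmentation is not None:
            pd.DataFrame(
                {
                    "month": monthly.months.astype(str),
                    "count": monthly.counts,
                    "deseasonalized": monthly.deseasonalized,
                    "state": segmentation.states,
                }
            ).to_csv(outdir / "activity.tsv", sep="\t", index=False)
        rows = []
        for k in range(topic_result.K):
            for rank, (tok, score) in enumerate(
                topics_mod.characteristic_tokens(topic_result, k), start=1
            ):
                rows.append({"topic": k, "rank": rank, "token": tok, "score": score})
        pd.DataFrame(rows).to_csv(outdir / "topic_tokens.tsv", sep="\t", index=False)

    return PipelineResult(
        posts=posts,
        assignments=assignments,
        profiles=profiles,
        concept_mentions=mentions,
        topic_result=topic_result,
        doc_topics=doc_topics,
        intake_prediction=prediction,
        coconsumption=cocon,
        pae=pae_results,
        dependence=dependence,
        overdose=overdose,
        unapproved=unapproved,
        annotation_sample=sample,
        activity=segmentation,
        monthly=monthly,
        report=report,
        counts=counts,
    )
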