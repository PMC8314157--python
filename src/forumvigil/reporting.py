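"""Aggregate report tables with the study's printed rounding conventions.

Every percentage in a report is ``100 * numerator / denominator`` rounded
half-up to two decimals, matching the count/percent pairs style
"(14,897/20,883, 71.34%)".  Denominators differ between tables (users vs
posts vs intake posts) and each table states its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from forumvigil.corpus import AGGREGATE, GROUPS


def proportion(numerator: int, denominator: int) -> float:
    """Percentage ``100*numerator/denominator`` rounded half-up to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be nonnegative")
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def top_n_table(
    counts: Mapping[str, int], n: int, denominator: int
) -> list[tuple[str, int, float]]:
    """Rows (label, count, percent), count-descending, ties lexicographic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:n]
    return [(label, c, proportion(c, denominator)) for label, c in ranked]


@dataclass
class GroupReport:
    """The assembled study tables for one pipeline run."""

    group_sizes: pd.DataFrame  # group, posts, users, post_pct, user_pct
    demographics: pd.DataFrame  # Table-1 style: section, label, per-group n/pct
    concepts: pd.DataFrame  # Table-2 style: per-group top concepts (once per post)
    topics: pd.DataFrame  # Table-3 style: per-group topic prevalence
    pae: pd.DataFrame  # Table-4 style: top potential adverse events
    coconsumption: pd.DataFrame
    misuse: pd.DataFrame  # dependence/overdose prevalence rows
    extras: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in (
            "group_sizes",
            "demographics",
            "concepts",
            "topics",
            "pae",
            "coconsumption",
            "misuse",
        ):
            getattr(self, name).to_csv(outdir / f"{name}.tsv", sep="\t", index=False)
        summary = {"tables": {}, **self.extras}
        for name in ("group_sizes", "misuse"):
            summary["tables"][name] = getattr(self, name).to_dict(orient="records")
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, ensure_ascii=False, indent=2, default=str)


def _require(outputs: Mapping[str, object], stage: str):
    if stage not in outputs or outputs[stage] is None:
        raise ValueError(f"missing stage output: {stage}")
    return outputs[stage]


def build_report(outputs: Mapping[str, object], top_n: int = 10) -> GroupReport:
    """Assemble the aggregate tables from the pipeline stage outputs.

    ``outputs`` maps stage names to their results:

    - ``groups``: list of GroupAssignment
    - ``posts``: list of non-discarded CleanPost
    - ``profiles``: list of demographics.UserProfile
    - ``concept_mentions``: list of concepts.ConceptMention
    - ``doc_topics``: mapping post_id -> dominant topic index (or None)
    - ``intake``: mapping post_id -> bool
    - ``coconsumption``: intake.CoconsumptionResult
    - ``pae``: list of (post_id, concept_id, flagged)
    - ``dependence``: list of safety.DependenceResult
    - ``overdose``: list of safety.OverdoseResult
    """
    posts = {p.post_id: p for p in _require(outputs, "posts")}
    assignments = _require(outputs, "groups")
    profiles = {pr.user_id: pr for pr in _require(outputs, "profiles")}
    mentions = _require(outputs, "concept_mentions")
    doc_topics = _require(outputs, "doc_topics")
    intake = _require(outputs, "intake")
    cocon = _require(outputs, "coconsumption")
    pae = _require(outputs, "pae")
    dependence = _require(outputs, "dependence")
    overdose = _require(outputs, "overdose")

    group_posts: dict[str, set[str]] = {g: set() for g in GROUPS}
    for a in assignments:
        for g in a.groups:
            group_posts[g].add(a.post_id)
    group_users = {
        g: {posts[pid].user_id for pid in pids if pid in posts}
        for g, pids in group_posts.items()
    }

    agg_posts = len(group_posts[AGGREGATE]) or 1
    agg_users = len(group_users[AGGREGATE]) or 1
    group_sizes = pd.DataFrame(
        [
            {
                "group": g,
                "posts": len(group_posts[g]),
                "users": len(group_users[g]),
                "post_pct": proportion(len(group_posts[g]), agg_posts),
                "user_pct": proportion(len(group_users[g]), agg_users),
            }
            for g in GROUPS
        ]
    )

    # Table-1 style demographics, per group over its distinct users
    from forumvigil.demographics import AGE_BINS

    demo_rows = []
    for section, labels in (
        ("gender", ["female", "male", "unknown"]),
        ("age_bin", list(AGE_BINS) + ["Unknown"]),
    ):
        for label in labels:
            row = {"section": section, "label": label}
            for g in GROUPS:
                users = group_users[g]
                denom = len(users) or 1
                n = sum(
                    1
                    for u in users
                    if u in profiles and getattr(profiles[u], section) == label
                )
                row[f"{g}_n"] = n
                row[f"{g}_pct"] = proportion(n, denom)
            demo_rows.append(row)
    demographics = pd.DataFrame(demo_rows)

    # Table-2 style concepts: a concept counts once per post
    concept_posts: dict[str, set[str]] = {}
    for m in mentions:
        concept_posts.setdefault(m.preferred_term, set()).add(m.post_id)
    posts_with_concepts = set().union(*concept_posts.values()) if concept_posts else set()
    concept_rows = []
    for g in GROUPS:
        in_group = group_posts[g] & posts_with_concepts
        denom = len(in_group) or 1
        counts = {
            term: len(pids & group_posts[g]) for term, pids in concept_posts.items()
        }
        counts = {t: c for t, c in counts.items() if c}
        for term, c, pct in top_n_table(counts, top_n, denom) if counts else []:
            concept_rows.append(
                {"group": g, "concept": term, "posts": c, "pct": pct, "denominator": denom}
            )
    concepts_df = pd.DataFrame(
        concept_rows, columns=["group", "concept", "posts", "pct", "denominator"]
    )

    # Table-3 style topic prevalence over posts with a dominant topic
    topic_rows = []
    assigned = {pid: t for pid, t in doc_topics.items() if t is not None}
    for g in GROUPS:
        in_group = group_posts[g] & set(assigned)
        denom = len(in_group) or 1
        counts: dict[str, int] = {}
        for pid in in_group:
            counts[f"topic_{assigned[pid]}"] = counts.get(f"topic_{assigned[pid]}", 0) + 1
        for label, c, pct in top_n_table(counts, top_n, denom) if counts else []:
            topic_rows.append(
                {"group": g, "topic": label, "posts": c, "pct": pct, "denominator": denom}
            )
    topics_df = pd.DataFrame(
        topic_rows, columns=["group", "topic", "posts", "pct", "denominator"]
    )

    # Table-4 style PAE trends over intake posts with concepts, per group
    pae_rows = []
    intake_posts = {pid for pid, flag in intake.items() if flag}
    pae_post_concepts: dict[str, set[str]] = {}
    for pid, concept_id, flagged in pae:
        if flagged:
            pae_post_concepts.setdefault(concept_id, set()).add(pid)
    for g in GROUPS:
        denom_posts = group_posts[g] & intake_posts & posts_with_concepts
        denom = len(denom_posts) or 1
        counts = {
            cid: len(pids & group_posts[g]) for cid, pids in pae_post_concepts.items()
        }
        counts = {c: n for c, n in counts.items() if n}
        for label, c, pct in top_n_table(counts, top_n, denom) if counts else []:
            pae_rows.append(
                {"group": g, "concept_id": label, "posts": c, "pct": pct, "denominator": denom}
            )
    pae_df = pd.DataFrame(
        pae_rows, columns=["group", "concept_id", "posts", "pct", "denominator"]
    )

    cocon_df = pd.DataFrame(
        [
            {
                "drug": drug,
                "posts": c,
                "pct": proportion(c, cocon.n_intake_posts or 1),
                "denominator": cocon.n_intake_posts,
            }
            for drug, c in sorted(
                cocon.post_counts.items(), key=lambda kv: (-kv[1], kv[0])
            )
        ],
        columns=["drug", "posts", "pct", "denominator"],
    )

    # Misuse prevalence: once-per-user and per-post rates within each group
    dep_posts = {r.post_id for r in dependence if r.flagged}
    od_posts = {r.post_id for r in overdose if r.flagged}
    misuse_rows = []
    for g in GROUPS:
        gp, gu = group_posts[g], group_users[g]
        for kind, ps in (("dependence", dep_posts), ("overdose", od_posts)):
            in_group = ps & gp
            # a user counts once, and only via posts flagged within this group
            users = {posts[pid].user_id for pid in in_group if pid in posts}
            misuse_rows.append(
                {
                    "group": g,
                    "kind": kind,
                    "posts": len(in_group),
                    "post_pct": proportion(len(in_group), len(gp) or 1),
                    "users": len(users),
                    "user_pct": proportion(len(users), len(gu) or 1),
                }
            )
    misuse = pd.DataFrame(misuse_rows)

    return GroupReport(
        group_sizes=group_sizes,
        demographics=demographics,
        concepts=concepts_df,
        topics=topics_df,
        pae=pae_df,
        coconsumption=cocon_df,
        misuse=misuse,
    )
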