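"""Shared fixtures: a seeded synthetic study corpus and one pipeline run.

The synthetic corpus (2000 expected posts, template-clean, noise 0) plays the
role of the study data; the session-scoped pipeline run is shared by the
stage-level and acceptance tests so the full pipeline executes once.
"""

from __future__ import annotations

import warnings
from datetime import datetime

import pytest
from hypothesis import HealthCheck, settings

from forumvigil.corpus import RawPost, clean_post
from forumvigil.pipeline import PipelineConfig, run_pipeline
from forumvigil.synthetic import GeneratorConfig, generate_corpus, write_corpus

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

CORPUS_SEED = 1
PIPELINE_SEED = 7


def make_raw(post_id="p1", user_id="u1", text="bonjour", ts="2005-03-01T10:00:00", **kw):
    return RawPost(
        post_id=post_id,
        user_id=user_id,
        forum_id=kw.get("forum_id", "f01"),
        timestamp=datetime.fromisoformat(ts),
        text=text,
        language=kw.get("language"),
    )


def make_clean(text, **kw):
    return clean_post(make_raw(text=text, **kw))


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Synthetic study corpus with ground truth, written to disk."""
    d = tmp_path_factory.mktemp("study")
    cfg = GeneratorConfig(seed=CORPUS_SEED)
    posts, truth = generate_corpus(cfg)
    write_corpus(posts, truth, d / "posts.jsonl", d / "truth.tsv")
    return {
        "config": cfg,
        "posts": posts,
        "truth": truth,
        "posts_path": d / "posts.jsonl",
        "truth_path": d / "truth.tsv",
        "dir": d,
    }


@pytest.fixture(scope="session")
def pipeline(study, tmp_path_factory):
    """One full pipeline run over the synthetic study corpus."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig(
        corpus_path=str(study["posts_path"]),
        truth_path=str(study["truth_path"]),
        seed=PIPELINE_SEED,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(config, outdir=outdir)
    return {"result": result, "config": config, "outdir": outdir, **study}
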