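"""Topic modelling of the analysis corpus.

Posts are modelled with latent Dirichlet allocation fitted by batch
variational expectation-maximization: each post is a mixture over K topics,
each topic a probability distribution over tokens (unigrams and bigrams of
the folded, stopword-filtered text).  Each topic is then summarized by its
15 *characteristic tokens*: the per-topic token probability is weighted by
the inverse of the token's mean probability in the other topics, so tokens
specific to the topic outrank globally frequent ones, and the top 15 by
weighted score are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import LatentDirichletAllocation

from forumvigil._text import tokenize

_EPS = 1e-12


def load_stopwords(path: str | Path) -> frozenset[str]:
    with open(path, encoding="utf-8") as fh:
        return frozenset(w.strip() for w in fh if w.strip() and not w.startswith("#"))


def build_dtm(
    texts: Sequence[str],
    stopwords: frozenset[str] = frozenset(),
    min_count: int = 2,
    bigrams: bool = True,
) -> tuple[sp.csr_matrix, list[str]]:
    """Document-term count matrix over folded unigram (+bigram) tokens.

    Tokens whose total corpus count is below ``min_count`` are dropped.
    Raises when the vocabulary comes out empty.
    """
    docs_tokens = []
    for text in texts:
        toks = [t for t in tokenize(text) if t not in stopwords and not t.isdigit()]
        grams = list(toks)
        if bigrams:
            grams += [f"{a} {b}" for a, b in zip(toks, toks[1:])]
        docs_tokens.append(grams)
    totals: dict[str, int] = {}
    for grams in docs_tokens:
        for g in grams:
            totals[g] = totals.get(g, 0) + 1
    vocabulary = sorted(g for g, c in totals.items() if c >= min_count)
    if not vocabulary:
        raise ValueError("empty vocabulary after preprocessing")
    index = {g: i for i, g in enumerate(vocabulary)}
    rows, cols, data = [], [], []
    for d, grams in enumerate(docs_tokens):
        counts: dict[int, int] = {}
        for g in grams:
            j = index.get(g)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for j, c in counts.items():
            rows.append(d)
            cols.append(j)
            data.append(c)
    dtm = sp.csr_matrix(
        (data, (rows, cols)), shape=(len(texts), len(vocabulary)), dtype=np.int64
    )
    return dtm, vocabulary


@dataclass
class TopicModelResult:
    topic_term: np.ndarray  # K x V, rows sum to 1
    doc_topic: np.ndarray  # D x K, rows sum to 1
    vocabulary: list[str]
    K: int
    converged: bool
    n_iter: int
    bound: float  # variational log-likelihood bound (higher is better)

    def dominant_topics(self) -> np.ndarray:
        return self.doc_topic.argmax(axis=1)


def fit_topics(
    dtm: sp.spmatrix,
    vocabulary: Sequence[str],
    K: int,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> TopicModelResult:
    """Fit LDA by batch variational EM, seeded and deterministic.

    Non-convergence within ``max_iter`` returns the result with a warning
    (``converged=False``) rather than raising.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if dtm.shape[0] == 0 or dtm.sum() == 0:
        raise ValueError("empty document-term matrix")
    lda = LatentDirichletAllocation(
        n_components=K,
        learning_method="batch",
        max_iter=max_iter,
        evaluate_every=1,
        perp_tol=tol,
        random_state=seed,
    )
    doc_topic = lda.fit_transform(dtm)
    topic_term = lda.components_ / lda.components_.sum(axis=1, keepdims=True)
    converged = lda.n_iter_ < max_iter
    if not converged:
        warnings.warn(f"LDA did not converge within {max_iter} iterations")
    return TopicModelResult(
        topic_term=topic_term,
        doc_topic=doc_topic / doc_topic.sum(axis=1, keepdims=True),
        vocabulary=list(vocabulary),
        K=K,
        converged=converged,
        n_iter=int(lda.n_iter_),
        bound=float(lda.score(dtm)),
    )


def elbo_trace(
    dtm: sp.spmatrix, K: int, seed: int, iters: int = 10
) -> list[float]:
    """Variational bound after 1..iters EM iterations.

    Batch variational EM with a fixed seed produces nested iterate sequences,
    so refitting with growing ``max_iter`` traces the bound after each
    iteration.
    """
    trace = []
    for m in range(1, iters + 1):
        lda = LatentDirichletAllocation(
            n_components=K, learning_method="batch", max_iter=m, random_state=seed
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lda.fit(dtm)
        trace.append(float(lda.score(dtm)))
    return trace


def characteristic_tokens(
    result: TopicModelResult, k: int, n: int = 15
) -> list[tuple[str, float]]:
    """Ranked characteristic tokens of topic ``k``.

    score(k, w) = beta[k, w] / (mean over other topics of beta[., w] + eps);
    ties break lexicographically.  Requires at least two topics.
    """
    if result.K < 2:
        raise ValueError("characteristic tokens require K >= 2")
    beta = result.topic_term
    others = (beta.sum(axis=0) - beta[k]) / (result.K - 1)
    scores = beta[k] / (others + _EPS)
    order = sorted(range(len(result.vocabulary)), key=lambda j: (-scores[j], result.vocabulary[j]))
    top = order[: min(n, len(result.vocabulary))]
    return [(result.vocabulary[j], float(scores[j])) for j in top]


def all_characteristic_tokens(
    result: TopicModelResult, n: int = 15
) -> list[list[tuple[str, float]]]:
    return [characteristic_tokens(result, k, n) for k in range(result.K)]
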