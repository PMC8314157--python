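"""Monthly post-volume series, seasonality correction and activity segmentation.

Forum activity about a drug is seasonal (winter peaks) and shifts regime
when external events hit (product withdrawals, prescription mandates).  The
monitoring stage builds the monthly count series, removes the seasonal
component with a LOESS fit on each of the 12 seasonal subseries (all
Januaries, all Februaries, ...), and segments the corrected series into
weak / moderate / high activity: a 3-state Gaussian hidden Markov model is
fitted by EM on the (log1p-transformed) deseasonalized values, K-means then
clusters the per-month feature vectors (trend value, deseasonalized value,
HMM posterior state probabilities), clusters are relabelled by ascending
mean volume, clusters whose mean volumes are not meaningfully distinct are
merged, and short runs are smoothed into their flanking states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from hmmlearn.hmm import GaussianHMM
from sklearn.cluster import KMeans
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.tsa.seasonal import STL

from forumvigil.corpus import CleanPost

WEAK, MODERATE, HIGH = "weak", "moderate", "high"
_LABEL_SETS = {1: (MODERATE,), 2: (WEAK, HIGH), 3: (WEAK, MODERATE, HIGH)}


class ConvergenceError(RuntimeError):
    """EM failed to converge; carries iteration diagnostics."""


@dataclass
class MonthlySeries:
    months: pd.PeriodIndex  # contiguous calendar months
    counts: np.ndarray
    deseasonalized: np.ndarray | None = None
    trend: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.months)


@dataclass
class ActivitySegmentation:
    states: list[str]  # per-month label
    segments: list[tuple[int, int, str]]  # (start, end) half-open month indices
    hmm_means: np.ndarray
    hmm_transmat: np.ndarray
    hmm_startprob: np.ndarray
    state_means: dict[str, float]  # mean monthly count per final label


def build_monthly_series(posts: Sequence[CleanPost]) -> MonthlySeries:
    """Counts of non-discarded posts per calendar month, zero months included."""
    stamps = [p.timestamp for p in posts if not p.discarded]
    if not stamps:
        return MonthlySeries(pd.PeriodIndex([], freq="M"), np.array([], dtype=int))
    periods = pd.PeriodIndex([pd.Period(ts, freq="M") for ts in stamps])
    full = pd.period_range(periods.min(), periods.max(), freq="M")
    counts = periods.value_counts().reindex(full, fill_value=0).sort_index()
    return MonthlySeries(full, counts.to_numpy())


def _lowess_fit(y: np.ndarray, frac: float) -> np.ndarray:
    x = np.arange(len(y), dtype=float)
    if len(y) < 3:
        return np.full(len(y), float(np.mean(y)))
    return lowess(y, x, frac=min(1.0, frac), return_sorted=False)


def deseasonalize(
    series: MonthlySeries, seasonal_window: int = 7, trend_window: int = 13
) -> MonthlySeries:
    """Remove the monthly seasonal component via seasonal-trend decomposition.

    Each of the 12 seasonal subseries (all Januaries, all Februaries, ...)
    is LOESS-smoothed and centred within the iterated seasonal-trend
    procedure (STL, period 12); the deseasonalized series is the counts
    minus the seasonal component and the LOESS trend is retained.  The
    trend window (13 months) is kept deliberately short so that abrupt
    regime shifts go to the trend rather than leaking into the seasonal
    component.  Requires at least two full periods (24 months).
    """
    n = len(series)
    if n < 24:
        raise ValueError("insufficient periods: need >= 24 months")
    counts = series.counts.astype(float)
    stl = STL(
        pd.Series(counts, index=series.months.to_timestamp()),
        period=12,
        seasonal=seasonal_window,
        trend=trend_window,
        robust=False,
    ).fit()
    seasonal = np.asarray(stl.seasonal)
    deseason = counts - seasonal
    trend = np.asarray(stl.trend)
    return MonthlySeries(series.months, series.counts, deseason, trend)


def _fit_hmm(
    obs: np.ndarray, n_states: int, seed: int, restarts: int, max_iter: int, tol: float
) -> GaussianHMM:
    best, best_score = None, -np.inf
    diagnostics = []
    X = obs.reshape(-1, 1)
    # individual restarts may oscillate; only a global failure is reported
    logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)
    for r in range(restarts):
        model = GaussianHMM(
            n_components=n_states,
            covariance_type="diag",
            n_iter=max_iter,
            tol=tol,
            random_state=seed + r,
            min_covar=1e-3,
        )
        try:
            model.fit(X)
            diagnostics.append((r, model.monitor_.converged, model.monitor_.iter))
            if not model.monitor_.converged:
                continue
            score = model.score(X)
        except (ValueError, np.linalg.LinAlgError):
            # degenerate restart (collapsed state / NaN parameters)
            diagnostics.append((r, "degenerate", None))
            continue
        if np.isfinite(score) and score > best_score:
            best, best_score = model, score
    if best is None:
        raise ConvergenceError(
            f"HMM EM failed to converge in {max_iter} iterations "
            f"across {restarts} restarts; diagnostics (restart, converged, iters): {diagnostics}"
        )
    return best


def _smooth_runs(states: list[int], values: np.ndarray, means: dict[int, float], min_run: int) -> list[int]:
    states = list(states)
    changed = True
    while changed:
        changed = False
        runs = _runs(states)
        if len(runs) <= 1:
            break
        for i, (start, end, s) in enumerate(runs):
            if end - start >= min_run:
                continue
            run_mean = values[start:end].mean()
            neighbors = []
            if i > 0:
                neighbors.append(runs[i - 1][2])
            if i + 1 < len(runs):
                neighbors.append(runs[i + 1][2])
            target = min(neighbors, key=lambda t: abs(means[t] - run_mean))
            for j in range(start, end):
                states[j] = target
            changed = True
            break
    return states


def _runs(states: Sequence) -> list[tuple[int, int, object]]:
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append((start, i, states[start]))
            start = i
    return runs


def segment_activity(
    series: MonthlySeries,
    seed: int = 0,
    n_states: int = 3,
    min_run: int = 2,
    restarts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-6,
    log_transform: bool = True,
    merge_noise_factor: float = 3.5,
) -> ActivitySegmentation:
    """Segment the deseasonalized series into weak/moderate/high activity.

    Pipeline: 3-state Gaussian HMM by EM (multiple seeded restarts, best
    likelihood kept) → K-means (k=3) on per-month features (trend,
    deseasonalized value, HMM posteriors) → relabel by ascending mean volume
    → merge clusters that interleave in time or whose mean volumes differ
    by less than ``merge_noise_factor`` robust noise standard deviations → absorb
    runs shorter than ``min_run`` into the flanking state with the nearer
    mean.  Deterministic given the seed.
    """
    if series.deseasonalized is None:
        series = deseasonalize(series)
    x = np.asarray(series.deseasonalized, dtype=float)
    trend = np.asarray(series.trend, dtype=float)
    counts = series.counts.astype(float)
    n = len(x)
    obs = np.log1p(np.clip(x, 0.0, None)) if log_transform else x

    if n == 0:
        return ActivitySegmentation([], [], np.array([]), np.array([]), np.array([]), {})
    if float(np.std(obs)) < 1e-9:  # constant series: one state, one segment
        label = _LABEL_SETS[1][0]
        return ActivitySegmentation(
            [label] * n,
            [(0, n, label)],
            np.array([obs.mean()]),
            np.array([[1.0]]),
            np.array([1.0]),
            {label: float(counts.mean())},
        )

    hmm = _fit_hmm(obs, n_states, seed, restarts, max_iter, tol)
    posteriors = hmm.predict_proba(obs.reshape(-1, 1))
    # canonicalize posterior column order by ascending emission mean, so an
    # index permutation of HMM states never changes the downstream labels
    order = np.argsort(hmm.means_.ravel())
    posteriors = posteriors[:, order]

    def _std(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    trend_feat = np.log1p(np.clip(trend, 0.0, None)) if log_transform else trend
    features = np.column_stack([_std(trend_feat), _std(obs), posteriors])
    km = KMeans(n_clusters=min(n_states, n), n_init=10, random_state=seed)
    cluster = km.fit_predict(features)

    # Merge clusters that do not correspond to distinct activity regimes.
    # see _merge_indistinct: interleaved or noise-level-close clusters are
    # one regime; merging proceeds over adjacent pairs in ascending-mean order
    cluster = _merge_indistinct(cluster, obs, merge_noise_factor)

    ids = sorted(set(cluster), key=lambda c: counts[cluster == c].mean())
    labels = _LABEL_SETS[min(len(ids), 3)]
    if len(ids) > 3:  # cannot happen with k<=3, defensive
        labels = labels + tuple(f"state{i}" for i in range(3, len(ids)))
    id_to_rank = {c: i for i, c in enumerate(ids)}
    rank_means = {i: float(obs[cluster == c].mean()) for i, c in enumerate(ids)}
    ranks = [id_to_rank[c] for c in cluster]
    ranks = _smooth_runs(ranks, obs, rank_means, min_run)

    # ranks present after smoothing keep their ascending-mean label order
    present = sorted(set(ranks))
    labels_present = _LABEL_SETS[min(len(present), 3)]
    rank_to_label = {r: labels_present[i] for i, r in enumerate(present)}
    states = [rank_to_label[r] for r in ranks]
    segs = [(s, e, lab) for s, e, lab in _runs(states)]
    state_means = {
        lab: float(counts[[st == lab for st in states]].mean()) for lab in set(states)
    }
    return ActivitySegmentation(
        states=states,
        segments=segs,
        hmm_means=hmm.means_.ravel()[order],
        hmm_transmat=hmm.transmat_[np.ix_(order, order)],
        hmm_startprob=hmm.startprob_[order],
        state_means=state_means,
    )


def _merge_indistinct(
    cluster: np.ndarray, obs: np.ndarray, noise_factor: float, max_runs: int = 3
) -> np.ndarray:
    """Merge clusters that are one noisy regime rather than two.

    Two signatures: the pair's members interleave in time (more than
    ``max_runs`` alternating runs — real regimes are temporal blocks), or
    the mean gap is within ``noise_factor`` noise standard deviations, the
    noise scale estimated robustly from successive differences (which a
    cluster split cannot deflate the way within-cluster s.d. can).
    """
    cluster = np.asarray(cluster).copy()
    diffs = np.abs(np.diff(obs))
    noise_sd = float(np.median(diffs)) / 0.954 if len(diffs) else 0.0
    while True:
        ids = sorted(set(cluster), key=lambda c: obs[cluster == c].mean())
        if len(ids) <= 1:
            return cluster
        candidates = []
        for a, b in zip(ids, ids[1:]):
            gap = abs(obs[cluster == b].mean() - obs[cluster == a].mean())
            pair_seq = cluster[np.isin(cluster, [a, b])]
            runs = 1 + int(np.sum(pair_seq[1:] != pair_seq[:-1]))
            if runs > max_runs or gap < noise_factor * noise_sd:
                candidates.append((gap, a, b))
        if not candidates:
            return cluster
        _gap, a, b = min(candidates)
        cluster[cluster == b] = a
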