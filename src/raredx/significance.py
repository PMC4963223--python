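"""Monte Carlo significance of the diagnostic score.

Null model: a query of m symptoms drawn uniformly at random, without
replacement, from the knowledge-base vocabulary. For each random query
the statistic recorded is the *best* DS over all diseases — the quantity
a user sees on their top prediction. The empirical tail probability of
that statistic calibrates the conventional significance cutoff (DS >=
0.5, which random queries essentially never reach on a realistic
knowledge base), and the top-two score gap under the same null gives a
minimum significant difference between two reported scores.

Empirical p-values are raw exceedance fractions; a Clopper–Pearson 95%
upper confidence bound accompanies each so that "< 1e-4" claims remain
honest at finite trial counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.stats import beta

from .knowledgebase import KnowledgeBase
from .scoring import DiseaseRanker, Query

__all__ = [
    "NullDistribution",
    "SignificanceEstimate",
    "sample_random_query",
    "null_distribution",
    "score_pvalue",
    "min_significant_difference",
]


@dataclass(frozen=True)
class NullDistribution:
    """Empirical sample of best-DS values under random queries of one size."""

    query_size: int
    n_trials: int
    best_scores: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        scores = np.asarray(self.best_scores, dtype=float)
        object.__setattr__(self, "best_scores", scores)
        if len(scores) != self.n_trials:
            raise ValueError("n_trials must equal len(best_scores)")
        if len(scores) and (scores.min() < -1 or scores.max() > 1):
            raise ValueError("best scores must lie in [-1, 1]")


@dataclass(frozen=True)
class SignificanceEstimate:
    threshold: float
    empirical_p: float
    upper_95: float  # Clopper–Pearson one-sided 95% upper bound
    n_exceeding: int
    n_trials: int
    alpha: float = 1e-4


def sample_random_query(kb: KnowledgeBase, m: int, rng: np.random.Generator) -> Query:
    """Draw m distinct symptom ids uniformly from the vocabulary."""
    vocab = sorted(kb.symptom_ids)
    if not 1 <= m <= len(vocab):
        raise ValueError(f"query size m={m} out of range [1, {len(vocab)}]")
    picks = rng.choice(len(vocab), size=m, replace=False)
    return Query(frozenset(vocab[i] for i in picks))


def _random_query_matrix(
    n: int, vocab_size: int, m: int, rng: np.random.Generator
) -> sp.csr_matrix:
    """Sparse indicator of n uniform random m-subsets of the vocabulary.

    The m smallest of iid uniform keys per row form a uniform random
    m-subset; argpartition vectorises this across trials.
    """
    if m == vocab_size:
        cols = np.tile(np.arange(vocab_size), n)
    else:
        keys = rng.random((n, vocab_size))
        cols = np.argpartition(keys, m, axis=1)[:, :m].ravel()
    indptr = np.arange(n + 1, dtype=np.int64) * m
    return sp.csr_matrix(
        (np.ones(n * m, dtype=np.int64), cols.astype(np.int64), indptr),
        shape=(n, vocab_size),
    )


def null_distribution(
    kb: KnowledgeBase,
    m: int,
    n_trials: int,
    seed: int,
    *,
    chunk_size: int = 2048,
    ranker: DiseaseRanker | None = None,
) -> NullDistribution:
    """Best DS over all diseases for each of ``n_trials`` random queries."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if ranker is None:
        ranker = DiseaseRanker().fit(kb)
    vocab_size = len(ranker.vocabulary_)
    if not 1 <= m <= vocab_size:
        raise ValueError(f"query size m={m} out of range [1, {vocab_size}]")
    rng = np.random.default_rng(seed)
    best = np.empty(n_trials, dtype=float)
    done = 0
    while done < n_trials:
        n = min(chunk_size, n_trials - done)
        Q = _random_query_matrix(n, vocab_size, m, rng)
        ds = ranker.decision_function(Q)
        best[done : done + n] = ds.max(axis=1)
        done += n
    return NullDistribution(query_size=m, n_trials=n_trials, best_scores=best, seed=seed)


def score_pvalue(
    null: NullDistribution, score: float, alpha: float = 1e-4
) -> SignificanceEstimate:
    """Empirical P(best DS >= score) under the null, with CP upper bound."""
    n = null.n_trials
    if n < 1:
        raise ValueError("null distribution is empty")
    k = int((null.best_scores >= score).sum())
    upper = 1.0 if k == n else float(beta.ppf(0.95, k + 1, n - k))
    return SignificanceEstimate(
        threshold=float(score),
        empirical_p=k / n,
        upper_95=upper,
        n_exceeding=k,
        n_trials=n,
        alpha=alpha,
    )


def min_significant_difference(
    kb: KnowledgeBase,
    m: int,
    n_trials: int,
    alpha: float = 0.001,
    seed: int = 0,
    *,
    chunk_size: int = 2048,
    ranker: DiseaseRanker | None = None,
) -> float:
    """(1 - alpha) quantile of the top-two DS gap under random queries.

    Two reported scores whose difference exceeds this value are unlikely
    (at level alpha) to be a chance fluctuation of the null ranking. A
    query for which every disease ties contributes a gap of 0.
    """
    if ranker is None:
        ranker = DiseaseRanker().fit(kb)
    if len(ranker.disease_ids_) < 2:
        raise ValueError("need at least two diseases to define a score gap")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    vocab_size = len(ranker.vocabulary_)
    if not 1 <= m <= vocab_size:
        raise ValueError(f"query size m={m} out of range [1, {vocab_size}]")
    rng = np.random.default_rng(seed)
    gaps = np.empty(n_trials, dtype=float)
    done = 0
    while done < n_trials:
        n = min(chunk_size, n_trials - done)
        Q = _random_query_matrix(n, vocab_size, m, rng)
        ds = ranker.decision_function(Q)
        top = ds.max(axis=1)
        runner = np.where(ds == top[:, None], -np.inf, ds).max(axis=1)
        gap = top - runner
        gap[~np.isfinite(gap)] = 0.0  # all diseases tied
        gaps[done : done + n] = gap
        done += n
    return float(np.quantile(gaps, 1.0 - alpha))
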