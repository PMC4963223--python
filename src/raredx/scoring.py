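"""Diagnostic score and disease ranking.

The ranking statistic is a normalised Hamming-like set distance turned
into a similarity. For a user query Q (a set of symptom ids) and a
disease D with stored symptom set S_D,

    DS = 1 - n / max(|Q|, |S_D|),        n = |Q xor S_D|,

where ``xor`` is the set symmetric difference: symptoms present in one
set but not the other. DS is 1 exactly when the two sets coincide, -1
when two equal-sized sets are disjoint, and lies in [-1, 1] always. A
differential diagnosis ranks every disease in the knowledge base by
decreasing DS; a score of at least 0.5 is conventionally significant
because random symptom sets essentially never reach it (see
:mod:`raredx.significance`).

The engine is exposed as a scikit-learn style estimator,
:class:`DiseaseRanker`: ``fit`` ingests the knowledge base, and queries
are scored with ``decision_function`` / ``predict`` / ``rank``. The
module-level functions (:func:`score_breakdown`, :func:`rank_diseases`,
:func:`min_symptoms_for_significance`) are thin wrappers for one-shot
use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from .knowledgebase import DiseaseEntry, KnowledgeBase, Symptom

__all__ = [
    "Query",
    "ScoreBreakdown",
    "ScoredDisease",
    "DiagnosisResult",
    "DiseaseRanker",
    "UnknownSymptomError",
    "score_breakdown",
    "rank_diseases",
    "min_symptoms_for_significance",
    "DEFAULT_THRESHOLD",
]

#: Score at or above which a diagnosis is flagged statistically significant.
DEFAULT_THRESHOLD = 0.5


class UnknownSymptomError(ValueError):
    """A query contains symptom ids absent from the knowledge base."""

    def __init__(self, unknown: Iterable[str]):
        self.unknown = tuple(sorted(unknown))
        super().__init__(
            f"symptoms not in the knowledge base vocabulary: {list(self.unknown)}"
        )


@dataclass(frozen=True)
class Query:
    """A user-submitted symptom set; duplicates collapse (set semantics)."""

    symptoms: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "symptoms", frozenset(self.symptoms))
        if not self.symptoms:
            raise ValueError("query must contain at least one symptom")

    @classmethod
    def coerce(cls, symptoms: "Query | Iterable[str]") -> "Query":
        if isinstance(symptoms, Query):
            return symptoms
        return cls(frozenset(symptoms))

    @property
    def size(self) -> int:
        return len(self.symptoms)


@dataclass(frozen=True)
class ScoreBreakdown:
    """DS score of one query against one disease, with its ingredients."""

    n: int
    max_size: int
    ds: float


@dataclass(frozen=True)
class ScoredDisease:
    disease_id: str
    disease_name: str
    ds: float
    n: int
    max_size: int
    rank: int
    significant: bool


@dataclass(frozen=True)
class DiagnosisResult:
    """Full ranked differential diagnosis for one query.

    ``ranked`` covers every disease in the knowledge base, sorted by
    non-increasing DS with ties broken by ascending disease id.
    ``top_set`` is the tie group at the maximum score — the unit used for
    true/false-positive counting in the benchmark.
    """

    ranked: tuple[ScoredDisease, ...]
    top_set: frozenset[str]
    threshold: float

    @property
    def top(self) -> ScoredDisease:
        return self.ranked[0]


def score_breakdown(
    query: Query | Iterable[str], disease: DiseaseEntry | Iterable[str]
) -> ScoreBreakdown:
    """Score one query against one disease symptom set."""
    q = Query.coerce(query).symptoms
    d = disease.symptoms if isinstance(disease, DiseaseEntry) else frozenset(disease)
    if not d:
        raise ValueError("disease symptom set must be non-empty")
    n = len(q ^ d)
    max_size = max(len(q), len(d))
    return ScoreBreakdown(n=n, max_size=max_size, ds=1.0 - n / max_size)


def min_symptoms_for_significance(
    disease_size: int, threshold: float = DEFAULT_THRESHOLD
) -> int:
    """Smallest number of matching symptoms giving a significant score.

    For a disease with S stored symptoms, submitting k of them (and
    nothing else, with k <= S) yields DS = k/S; the smallest k with
    k/S >= threshold is ceil(threshold * S).
    """
    if disease_size < 1:
        raise ValueError(f"disease_size must be >= 1, got {disease_size}")
    k = math.ceil(threshold * disease_size)
    if k > disease_size:
        raise ValueError(
            f"threshold {threshold} unreachable for disease of size {disease_size}"
        )
    return int(k)


class DiseaseRanker(BaseEstimator):
    """Differential-diagnosis engine over a disease–symptom knowledge base.

    Parameters
    ----------
    threshold : float, default 0.5
        DS score at or above which a prediction is flagged significant.

    Attributes (after ``fit``)
    --------------------------
    disease_ids_ : ndarray of str, sorted ascending
    disease_names_ : ndarray of str, aligned with ``disease_ids_``
    vocabulary_ : ndarray of str, sorted symptom ids
    sizes_ : ndarray of int, stored symptom count per disease
    indicator_ : scipy.sparse.csr_matrix, (n_diseases, n_symptoms) binary

    Examples
    --------
    >>> ranker = DiseaseRanker().fit(kb)
    >>> ranker.predict([{"HP:1", "HP:2"}])
    array(['D0042'], dtype=...)
    """

    def __init__(self, threshold: float = DEFAULT_THRESHOLD):
        self.threshold = threshold

    # -- fitting ---------------------------------------------------------

    def fit(self, X, y=None) -> "DiseaseRanker":
        """Ingest the knowledge base.

        ``X`` is either a :class:`KnowledgeBase` or a sequence of symptom-id
        collections (one per disease) with ``y`` the disease ids.
        """
        if isinstance(X, KnowledgeBase):
            kb = X
        else:
            sets = [frozenset(s) for s in X]
            if y is None:
                y = [f"D{i}" for i in range(len(sets))]
            vocab = sorted(set().union(*sets)) if sets else []
            kb = KnowledgeBase(
                diseases=tuple(
                    DiseaseEntry(str(label), str(label), s)
                    for label, s in zip(y, sets)
                ),
                vocabulary=tuple(Symptom(v) for v in vocab),
            )
        if kb.n_diseases == 0:
            raise ValueError("knowledge base has no diseases")
        self.kb_ = kb
        self.disease_ids_ = np.array([d.id for d in kb.diseases], dtype=object)
        self.disease_names_ = np.array([d.name for d in kb.diseases], dtype=object)
        self.vocabulary_ = np.array([s.id for s in kb.vocabulary], dtype=object)
        self._symptom_pos = {sid: i for i, sid in enumerate(self.vocabulary_)}
        self.sizes_ = np.array([d.size for d in kb.diseases], dtype=np.int64)
        indptr = np.zeros(kb.n_diseases + 1, dtype=np.int64)
        cols: list[int] = []
        for i, d in enumerate(kb.diseases):
            idx = sorted(self._symptom_pos[s] for s in d.symptoms)
            cols.extend(idx)
            indptr[i + 1] = len(cols)
        self.indicator_ = sp.csr_matrix(
            (np.ones(len(cols), dtype=np.int64), np.array(cols, dtype=np.int64), indptr),
            shape=(kb.n_diseases, kb.n_symptoms),
        )
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "indicator_"):
            raise RuntimeError("DiseaseRanker is not fitted; call fit(kb) first")

    # -- query conversion ------------------------------------------------

    def _as_query_matrix(self, X) -> tuple[sp.csr_matrix, np.ndarray]:
        """Coerce queries to a sparse (n_queries, n_symptoms) indicator.

        Accepts a single Query/set of ids, an iterable of such, or an
        already-built binary matrix aligned to ``vocabulary_``.
        """
        self._check_fitted()
        if sp.issparse(X):
            Q = X.tocsr().astype(np.int64)
        elif isinstance(X, np.ndarray) and X.ndim == 2:
            Q = sp.csr_matrix(X.astype(np.int64))
        else:
            if isinstance(X, (Query, set, frozenset)):
                X = [X]
            sets = [Query.coerce(q).symptoms for q in X]
            unknown = set().union(*sets) - self._symptom_pos.keys()
            if unknown:
                raise UnknownSymptomError(unknown)
            indptr = np.zeros(len(sets) + 1, dtype=np.int64)
            cols: list[int] = []
            for i, s in enumerate(sets):
                cols.extend(sorted(self._symptom_pos[x] for x in s))
                indptr[i + 1] = len(cols)
            Q = sp.csr_matrix(
                (
                    np.ones(len(cols), dtype=np.int64),
                    np.array(cols, dtype=np.int64),
                    indptr,
                ),
                shape=(len(sets), len(self.vocabulary_)),
            )
        if Q.shape[1] != len(self.vocabulary_):
            raise ValueError(
                f"query matrix has {Q.shape[1]} columns; vocabulary has "
                f"{len(self.vocabulary_)}"
            )
        sizes = np.asarray(Q.sum(axis=1)).ravel().astype(np.int64)
        if (sizes == 0).any():
            raise ValueError("query must contain at least one symptom")
        return Q, sizes

    # -- scoring ---------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """Dense (n_queries, n_diseases) matrix of DS scores."""
        Q, q_sizes = self._as_query_matrix(X)
        inter = np.asarray((Q @ self.indicator_.T).todense(), dtype=np.int64)
        su = q_sizes[:, None]
        sd = self.sizes_[None, :]
        n = su + sd - 2 * inter
        return 1.0 - n / np.maximum(su, sd)

    def predict(self, X) -> np.ndarray:
        """Most likely disease id per query (ties -> smallest disease id)."""
        ds = self.decision_function(X)
        # disease order is id-sorted, so argmax's first-hit rule is the tie-break
        return self.disease_ids_[np.argmax(ds, axis=1)]

    def rank(self, query: Query | Iterable[str]) -> DiagnosisResult:
        """Full ranked differential diagnosis for a single query."""
        q = Query.coerce(query)
        ds = self.decision_function([q])[0]
        su = q.size
        max_size = np.maximum(su, self.sizes_)
        n_int = np.rint((1.0 - ds) * max_size).astype(np.int64)
        order = np.argsort(-ds, kind="stable")  # stable keeps ascending-id ties
        best = ds[order[0]]
        ranked = tuple(
            ScoredDisease(
                disease_id=str(self.disease_ids_[j]),
                disease_name=str(self.disease_names_[j]),
                ds=float(ds[j]),
                n=int(n_int[j]),
                max_size=int(max_size[j]),
                rank=r,
                significant=bool(ds[j] >= self.threshold),
            )
            for r, j in enumerate(order, start=1)
        )
        top_set = frozenset(str(self.disease_ids_[j]) for j in np.nonzero(ds == best)[0])
        return DiagnosisResult(ranked=ranked, top_set=top_set, threshold=self.threshold)


def rank_diseases(
    query: Query | Iterable[str],
    kb: KnowledgeBase,
    threshold: float = DEFAULT_THRESHOLD,
) -> DiagnosisResult:
    """One-shot ranked differential diagnosis (fits a ranker internally)."""
    return DiseaseRanker(threshold=threshold).fit(kb).rank(query)
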