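"""Independent brute-force oracles, kept free of the package's numpy path.

Everything here works on plain Python sets and dicts so that agreement
with the sparse-matrix engine is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

from itertools import combinations


def brute_ds(query: set, disease: set) -> float:
    n = len(set(query) ^ set(disease))
    return 1.0 - n / max(len(set(query)), len(set(disease)))


def brute_rank(query: set, diseases: dict[str, frozenset]) -> list[tuple[str, float]]:
    """(disease id, ds) sorted by decreasing ds, ties by ascending id."""
    scored = [(did, brute_ds(query, sym)) for did, sym in diseases.items()]
    return sorted(scored, key=lambda t: (-t[1], t[0]))


def brute_top_set(query: set, diseases: dict[str, frozenset]) -> set[str]:
    ranking = brute_rank(query, diseases)
    best = ranking[0][1]
    return {did for did, ds in ranking if ds == best}


def brute_metrics(
    cohort: list[tuple[str, set]], diseases: dict[str, frozenset]
) -> tuple[float, float, float]:
    """(precision, sensitivity, f1) with top-score-set tie semantics."""
    tp = fp = 0
    for true_disease, observed in cohort:
        top = brute_top_set(observed, diseases)
        hit = true_disease in top
        tp += hit
        fp += len(top) - hit
    p = tp / (tp + fp) if tp + fp else 0.0
    s = tp / len(cohort)
    f1 = 2 * p * s / (p + s) if p + s else 0.0
    return p, s, f1


def brute_best_score_population(
    diseases: dict[str, frozenset], vocabulary: list[str], m: int
) -> list[float]:
    """Best ds for every possible m-symptom query (exhaustive null)."""
    return [
        max(brute_ds(set(q), sym) for sym in diseases.values())
        for q in combinations(sorted(vocabulary), m)
    ]


def brute_gap_population(
    diseases: dict[str, frozenset], vocabulary: list[str], m: int
) -> list[float]:
    """Top-two distinct-score gap for every possible m-symptom query."""
    gaps = []
    for q in combinations(sorted(vocabulary), m):
        scores = sorted((brute_ds(set(q), sym) for sym in diseases.values()), reverse=True)
        best = scores[0]
        below = [s for s in scores if s < best]
        gaps.append(best - below[0] if below else 0.0)
    return gaps
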