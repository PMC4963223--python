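"""Noise-injection benchmarking of the diagnostic engine.

Synthetic patients are generated one per disease, each initially
carrying the disease's full stored symptom set — the only design under
which the noise-free benchmark is perfect by construction (precision =
sensitivity = F1 = 1 on any knowledge base with pairwise-distinct
symptom sets). Two perturbation operators stress the engine:

* **add/delete noise** — k sequential edits; each edit is, with
  probability ``p_add`` (default 1/2), the addition of a uniformly
  chosen vocabulary symptom not yet observed, otherwise the deletion of
  a uniformly chosen observed symptom. A deletion that would empty the
  set becomes an addition, so queries stay non-empty.
* **fraction deletion** — floor(fraction * set size) observed symptoms
  removed uniformly at random, always retaining at least one.

Evaluation uses top-score-set tie semantics: for each patient the set T
of diseases tied at the maximum DS is computed; the patient contributes
one true positive if the true disease is in T, and |T| minus that as
false positives. Then

    precision   p = TP / (TP + FP)
    sensitivity s = TP / n_patients
    F1          = 2 p s / (p + s)

so precision degrades through top-score ties and overtakes while
sensitivity only falls when the true disease leaves the top set — the
behaviour characteristic of this engine under noise.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .knowledgebase import KnowledgeBase, validate_kb
from .scoring import DEFAULT_THRESHOLD, DiseaseRanker

__all__ = [
    "SyntheticPatient",
    "NoiseSpec",
    "BenchmarkMetrics",
    "make_baseline_cohort",
    "apply_add_delete_noise",
    "apply_fraction_deletion",
    "evaluate_cohort",
    "run_noise_grid",
    "fig_mix_grid",
    "fig_deletion_grid",
    "load_noise_grid",
    "DEFAULT_PATIENT_FRACTIONS",
]

#: Default fraction-of-patients-perturbed axis: 0% to 100% in steps of 10.
DEFAULT_PATIENT_FRACTIONS: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass(frozen=True)
class SyntheticPatient:
    """A simulated case: the true disease and the observed symptom set."""

    true_disease: str
    observed: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed", frozenset(self.observed))
        if not self.observed:
            raise ValueError("patient must have at least one observed symptom")


@dataclass(frozen=True)
class NoiseSpec:
    """One cell of the noise grid.

    ``mode`` is ``add_delete_count`` (k random edits per perturbed
    patient) or ``delete_fraction`` (a fixed fraction of each perturbed
    patient's symptoms deleted); ``patient_fraction`` is the share of the
    cohort perturbed.
    """

    mode: str
    k: int | None = None
    fraction_deleted: float | None = None
    patient_fraction: float = 1.0
    p_add: float = 0.5

    def __post_init__(self) -> None:
        if self.mode == "add_delete_count":
            if self.k is None or self.k < 1:
                raise ValueError("mode add_delete_count requires k >= 1")
        elif self.mode == "delete_fraction":
            if self.fraction_deleted is None or not 0.0 < self.fraction_deleted < 1.0:
                raise ValueError("mode delete_fraction requires 0 < fraction < 1")
        else:
            raise ValueError(f"unknown noise mode {self.mode!r}")
        if not 0.0 <= self.patient_fraction <= 1.0:
            raise ValueError("patient_fraction must be in [0, 1]")
        if not 0.0 <= self.p_add <= 1.0:
            raise ValueError("p_add must be in [0, 1]")

    @property
    def level(self) -> float:
        """The noise magnitude: k (mode 1) or fraction deleted (mode 2)."""
        return float(self.k if self.mode == "add_delete_count" else self.fraction_deleted)


@dataclass(frozen=True)
class BenchmarkMetrics:
    precision: float
    sensitivity: float
    f1: float
    top1_rate: float
    top10_rate: float
    top50_rate: float
    n_patients: int
    replicate: int = 0


def make_baseline_cohort(kb: KnowledgeBase) -> tuple[SyntheticPatient, ...]:
    """One noise-free patient per disease, carrying its full symptom set."""
    report = validate_kb(kb)
    if report.duplicate_set_pairs:
        raise ValueError(
            "knowledge base has duplicate symptom sets; noise-free recovery is "
            f"not guaranteed: {report.duplicate_set_pairs[:5]}"
        )
    if report.empty_symptom_sets:
        raise ValueError(f"diseases with no symptoms: {report.empty_symptom_sets[:5]}")
    return tuple(
        SyntheticPatient(true_disease=d.id, observed=d.symptoms) for d in kb.diseases
    )


def apply_add_delete_noise(
    patient: SyntheticPatient,
    kb: KnowledgeBase,
    k: int,
    rng: np.random.Generator,
    p_add: float = 0.5,
) -> SyntheticPatient:
    """Apply k sequential random symptom edits to one patient."""
    if k < 0:
        raise ValueError("k must be >= 0")
    vocab = kb.sorted_symptom_ids
    observed = sorted(patient.observed)
    member = set(observed)
    for _ in range(k):
        add = rng.random() < p_add
        if not add and len(observed) == 1:
            add = True  # deletion would empty the query
        if add:
            if len(member) == len(vocab):
                warnings.warn("vocabulary exhausted; addition edit skipped", stacklevel=2)
                continue
            while True:
                pick = vocab[int(rng.integers(len(vocab)))]
                if pick not in member:
                    break
            bisect.insort(observed, pick)
            member.add(pick)
        else:
            j = int(rng.integers(len(observed)))
            member.remove(observed.pop(j))
    return replace(patient, observed=frozenset(observed))


def apply_fraction_deletion(
    patient: SyntheticPatient, fraction: float, rng: np.random.Generator
) -> SyntheticPatient:
    """Delete floor(fraction * set size) symptoms, retaining at least one."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    observed = sorted(patient.observed)
    n_delete = min(int(fraction * len(observed)), len(observed) - 1)
    if n_delete > 0:
        drop = set(rng.choice(len(observed), size=n_delete, replace=False).tolist())
        observed = [s for i, s in enumerate(observed) if i not in drop]
    return replace(patient, observed=frozenset(observed))


def evaluate_cohort(
    cohort: Sequence[SyntheticPatient],
    kb: KnowledgeBase,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    ranker: DiseaseRanker | None = None,
    replicate: int = 0,
) -> BenchmarkMetrics:
    """Score every patient and aggregate tie-aware diagnostic metrics."""
    if not cohort:
        raise ValueError("cohort must be non-empty")
    if ranker is None:
        ranker = DiseaseRanker(threshold=threshold).fit(kb)
    id_pos = {sid: i for i, sid in enumerate(ranker.disease_ids_)}
    try:
        true_idx = np.array([id_pos[p.true_disease] for p in cohort], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"patient's true disease {exc} not in knowledge base") from exc
    ds = ranker.decision_function([p.observed for p in cohort])
    n_pat = len(cohort)
    rows = np.arange(n_pat)
    ds_true = ds[rows, true_idx]
    row_max = ds.max(axis=1)
    tie_counts = (ds == row_max[:, None]).sum(axis=1)
    tp_flags = ds_true == row_max
    tp = int(tp_flags.sum())
    fp = int(tie_counts.sum()) - tp
    precision = tp / (tp + fp) if tp + fp else 0.0
    sensitivity = tp / n_pat
    f1 = (
        2.0 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    # deterministic tie-broken rank of the true disease (ascending id on ties)
    beats = (ds > ds_true[:, None]).sum(axis=1)
    col = np.arange(ds.shape[1])
    tie_before = ((ds == ds_true[:, None]) & (col[None, :] < true_idx[:, None])).sum(axis=1)
    rank_true = 1 + beats + tie_before
    return BenchmarkMetrics(
        precision=float(precision),
        sensitivity=float(sensitivity),
        f1=float(f1),
        top1_rate=float(tp_flags.mean()),
        top10_rate=float((rank_true <= 10).mean()),
        top50_rate=float((rank_true <= 50).mean()),
        n_patients=n_pat,
        replicate=replicate,
    )


def _perturb_cohort(
    cohort: Sequence[SyntheticPatient],
    kb: KnowledgeBase,
    spec: NoiseSpec,
    rng: np.random.Generator,
) -> list[SyntheticPatient]:
    n = len(cohort)
    n_perturb = int(round(spec.patient_fraction * n))
    chosen = set(rng.choice(n, size=n_perturb, replace=False).tolist())
    out = []
    for i, patient in enumerate(cohort):
        if i not in chosen:
            out.append(patient)
        elif spec.mode == "add_delete_count":
            out.append(apply_add_delete_noise(patient, kb, spec.k, rng, spec.p_add))
        else:
            out.append(apply_fraction_deletion(patient, spec.fraction_deleted, rng))
    return out


def run_noise_grid(
    kb: KnowledgeBase,
    grid: Sequence[NoiseSpec],
    replicates: int = 10,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Evaluate every (noise spec, replicate) cell; one metrics row each.

    Fully reproducible: per-cell RNG streams are spawned deterministically
    from ``seed``, so identical inputs give identical tables.
    """
    if not grid:
        raise ValueError("noise grid must be non-empty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ranker = DiseaseRanker(threshold=threshold).fit(kb)
    baseline = make_baseline_cohort(kb)
    streams = np.random.SeedSequence(seed).spawn(len(grid) * replicates)
    records = []
    for gi, spec in enumerate(grid):
        for rep in range(replicates):
            rng = np.random.default_rng(streams[gi * replicates + rep])
            cohort = _perturb_cohort(baseline, kb, spec, rng)
            metrics = evaluate_cohort(cohort, kb, ranker=ranker, replicate=rep)
            records.append(
                {
                    "experiment": "noise-mix"
                    if spec.mode == "add_delete_count"
                    else "deletion",
                    "mode": spec.mode,
                    "k_or_fraction": spec.level,
                    "patient_fraction": spec.patient_fraction,
                    "replicate": rep,
                    "seed": seed,
                    "n_patients": metrics.n_patients,
                    "precision": metrics.precision,
                    "sensitivity": metrics.sensitivity,
                    "f1": metrics.f1,
                    "top1_rate": metrics.top1_rate,
                    "top10_rate": metrics.top10_rate,
                    "top50_rate": metrics.top50_rate,
                }
            )
    return pd.DataFrame.from_records(records)


def fig_mix_grid(
    ks: Iterable[int] = (1, 2, 3, 4, 5, 10, 20),
    patient_fractions: Iterable[float] = DEFAULT_PATIENT_FRACTIONS,
    p_add: float = 0.5,
) -> list[NoiseSpec]:
    """The joint added/deleted-symptom experiment grid."""
    return [
        NoiseSpec(mode="add_delete_count", k=k, patient_fraction=pf, p_add=p_add)
        for k in ks
        for pf in patient_fractions
    ]


def fig_deletion_grid(
    fractions: Iterable[float] = (0.25, 0.50, 0.75),
    patient_fractions: Iterable[float] = DEFAULT_PATIENT_FRACTIONS,
) -> list[NoiseSpec]:
    """The deleted-symptoms-only experiment grid."""
    return [
        NoiseSpec(mode="delete_fraction", fraction_deleted=f, patient_fraction=pf)
        for f in fractions
        for pf in patient_fractions
    ]


def load_noise_grid(path: str | Path) -> list[NoiseSpec]:
    """Read a YAML noise-grid config.

    Format: a mapping with an optional ``patient_fractions`` list and a
    ``cells`` list of mappings with keys ``mode`` plus ``k`` or
    ``fraction_deleted`` (and optionally ``patient_fraction``, ``p_add``).
    Cells without an explicit ``patient_fraction`` are expanded over the
    ``patient_fractions`` axis.
    """
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "cells" not in cfg:
        raise ValueError(f"{path}: expected a mapping with a 'cells' list")
    fractions = cfg.get("patient_fractions", list(DEFAULT_PATIENT_FRACTIONS))
    grid: list[NoiseSpec] = []
    for cell in cfg["cells"]:
        cell = dict(cell)
        if "patient_fraction" in cell:
            grid.append(NoiseSpec(**cell))
        else:
            grid.extend(NoiseSpec(**cell, patient_fraction=pf) for pf in fractions)
    return grid
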