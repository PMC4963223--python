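"""Noise operators, tie-aware metrics, and the experiment grid."""

import numpy as np
import pytest

from raredx import (
    NoiseSpec,
    SyntheticPatient,
    apply_add_delete_noise,
    apply_fraction_deletion,
    evaluate_cohort,
    fig_deletion_grid,
    fig_mix_grid,
    load_noise_grid,
    make_baseline_cohort,
    run_noise_grid,
)
from conftest import make_kb
from oracles import brute_metrics


@pytest.fixture(scope="module")
def medium_kb():
    rng = np.random.default_rng(42)
    pool = [f"s{i:02d}" for i in range(40)]
    diseases, seen = {}, set()
    for i in range(30):
        while True:
            size = int(rng.integers(2, 9))
            sym = frozenset(rng.choice(pool, size=size, replace=False).tolist())
            if sym not in seen:
                seen.add(sym)
                break
        diseases[f"D{i:02d}"] = set(sym)
    return make_kb(diseases)


def test_baseline_cohort_construction(toy_kb):
    cohort = make_baseline_cohort(toy_kb)
    assert len(cohort) == toy_kb.n_diseases
    for patient in cohort:
        assert patient.observed == toy_kb.disease(patient.true_disease).symptoms


def test_baseline_cohort_refuses_duplicate_sets():
    kb = make_kb({"D1": {"a", "b"}, "D2": {"a", "b"}})
    with pytest.raises(ValueError, match="duplicate symptom sets"):
        make_baseline_cohort(kb)


def test_baseline_cohort_is_perfect(toy_kb):
    metrics = evaluate_cohort(make_baseline_cohort(toy_kb), toy_kb)
    assert (metrics.precision, metrics.sensitivity, metrics.f1) == (1.0, 1.0, 1.0)


def test_tie_semantics_hand_example(toy_kb):
    """Single patient with true disease D1 observing {b}: top set {D1, D2},
    so TP = 1, FP = 1, p = 1/2, s = 1, F1 = 2/3."""
    cohort = [SyntheticPatient("D1", frozenset({"b"}))]
    metrics = evaluate_cohort(cohort, toy_kb)
    assert metrics.precision == pytest.approx(0.5)
    assert metrics.sensitivity == 1.0
    assert metrics.f1 == pytest.approx(2 / 3)
    assert metrics.top1_rate == 1.0


def test_all_wrong_cohort_scores_zero(toy_kb):
    cohort = [SyntheticPatient("D3", frozenset({"a", "b"}))]  # D1 matches exactly
    metrics = evaluate_cohort(cohort, toy_kb)
    assert (metrics.precision, metrics.sensitivity, metrics.f1) == (0.0, 0.0, 0.0)


def test_metrics_match_brute_force(medium_kb):
    rng = np.random.default_rng(3)
    diseases = {d.id: d.symptoms for d in medium_kb.diseases}
    cohort = []
    for d in medium_kb.diseases[:15]:
        observed = set(d.symptoms)
        observed = set(
            apply_add_delete_noise(
                SyntheticPatient(d.id, frozenset(observed)), medium_kb, 3, rng
            ).observed
        )
        cohort.append((d.id, observed))
    metrics = evaluate_cohort(
        [SyntheticPatient(t, frozenset(o)) for t, o in cohort], medium_kb
    )
    p, s, f1 = brute_metrics(cohort, diseases)
    assert metrics.precision == pytest.approx(p)
    assert metrics.sensitivity == pytest.approx(s)
    assert metrics.f1 == pytest.approx(f1)


def test_add_delete_noise_properties(toy_kb):
    patient = SyntheticPatient("D3", frozenset({"d"}))
    # zero edits: unchanged
    rng = np.random.default_rng(0)
    assert apply_add_delete_noise(patient, toy_kb, 0, rng) == patient
    # forced deletion on a singleton becomes an addition
    grown = apply_add_delete_noise(patient, toy_kb, 1, np.random.default_rng(1), p_add=0.0)
    assert len(grown.observed) == 2 and "d" in grown.observed
    # determinism
    a = apply_add_delete_noise(patient, toy_kb, 3, np.random.default_rng(5))
    b = apply_add_delete_noise(patient, toy_kb, 3, np.random.default_rng(5))
    assert a == b
    assert a.true_disease == "D3"


def test_add_noise_exhausted_vocabulary_warns(toy_kb):
    patient = SyntheticPatient("D1", frozenset({"a", "b", "c", "d"}))
    with pytest.warns(UserWarning, match="vocabulary exhausted"):
        out = apply_add_delete_noise(patient, toy_kb, 1, np.random.default_rng(0), p_add=1.0)
    assert out.observed == patient.observed


def test_fraction_deletion_arithmetic():
    patient = SyntheticPatient("D", frozenset(f"x{i}" for i in range(48)))
    out = apply_fraction_deletion(patient, 0.5, np.random.default_rng(0))
    assert len(out.observed) == 24
    assert out.observed <= patient.observed
    # floor + retention rule on a 2-symptom patient
    tiny = SyntheticPatient("D", frozenset({"a", "b"}))
    out = apply_fraction_deletion(tiny, 0.75, np.random.default_rng(0))
    assert len(out.observed) == 1
    # determinism
    a = apply_fraction_deletion(patient, 0.25, np.random.default_rng(9))
    b = apply_fraction_deletion(patient, 0.25, np.random.default_rng(9))
    assert a == b
    with pytest.raises(ValueError):
        apply_fraction_deletion(patient, 0.0, np.random.default_rng(0))


def test_noise_spec_validation():
    with pytest.raises(ValueError):
        NoiseSpec(mode="add_delete_count")
    with pytest.raises(ValueError):
        NoiseSpec(mode="delete_fraction", fraction_deleted=1.0)
    with pytest.raises(ValueError):
        NoiseSpec(mode="bogus", k=1)
    with pytest.raises(ValueError):
        NoiseSpec(mode="add_delete_count", k=1, patient_fraction=1.5)


def test_grid_zero_patient_fraction_is_perfect(medium_kb):
    grid = [NoiseSpec(mode="add_delete_count", k=20, patient_fraction=0.0)]
    table = run_noise_grid(medium_kb, grid, replicates=3, seed=5)
    assert (table[["precision", "sensitivity", "f1"]] == 1.0).all().all()


def test_grid_determinism_and_invariants(medium_kb):
    grid = fig_mix_grid(ks=(2, 5), patient_fractions=(0.0, 0.5, 1.0))
    a = run_noise_grid(medium_kb, grid, replicates=2, seed=7)
    b = run_noise_grid(medium_kb, grid, replicates=2, seed=7)
    assert a.equals(b)
    assert (a["precision"] <= a["sensitivity"] + 1e-12).all()
    assert (a["top1_rate"] <= a["top10_rate"]).all()
    assert (a["top10_rate"] <= a["top50_rate"]).all()
    assert a.columns.tolist()[:7] == [
        "experiment", "mode", "k_or_fraction", "patient_fraction",
        "replicate", "seed", "n_patients",
    ]


def test_deletion_keeps_true_score_positive(medium_kb):
    """Deletion-only noise keeps the true disease's score at k/S > 0."""
    rng = np.random.default_rng(1)
    for patient in make_baseline_cohort(medium_kb)[:10]:
        noisy = apply_fraction_deletion(patient, 0.5, rng)
        disease = medium_kb.disease(patient.true_disease)
        k, s = len(noisy.observed), disease.size
        from raredx import score_breakdown

        assert score_breakdown(noisy.observed, disease).ds == pytest.approx(k / s)


def test_yaml_grid_config(tmp_path):
    cfg = tmp_path / "grid.yaml"
    cfg.write_text(
        "patient_fractions: [0.0, 1.0]\n"
        "cells:\n"
        "  - {mode: add_delete_count, k: 3}\n"
        "  - {mode: delete_fraction, fraction_deleted: 0.5, patient_fraction: 0.3}\n"
    )
    grid = load_noise_grid(cfg)
    assert len(grid) == 3
    assert grid[0].patient_fraction == 0.0 and grid[1].patient_fraction == 1.0
    assert grid[2].fraction_deleted == 0.5


def test_default_grids_shape():
    assert len(fig_mix_grid()) == 7 * 11
    assert len(fig_deletion_grid()) == 3 * 11
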