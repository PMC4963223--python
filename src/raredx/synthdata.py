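"""Seeded synthetic disease–symptom knowledge bases and patient cohorts.

The generator emulates the structural features of a curated rare-disease
phenotype resource that the scoring, significance, and benchmark modules
depend on: thousands of diseases, right-skewed per-disease symptom
counts (a truncated log-normal spanning roughly 5–180, matching the
observed spread of stored symptom counts from a handful to nearly two
hundred), a shared vocabulary in which popular symptoms recur across
many diseases, and pairwise-distinct symptom sets. It makes no claim to
reproduce any real resource's exact dimensions or co-occurrence
statistics — it is a stand-in dataset for desk-scale experiments.

Symptom popularity is a Dirichlet-weighted categorical distribution: a
single ``sharing_concentration`` knob interpolates from exactly uniform
symptom choice (0) to heavy reuse of a few popular symptoms (larger
values), which is what drives top-score ties in the benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .benchmark import SyntheticPatient
from .knowledgebase import DiseaseEntry, KnowledgeBase, Symptom

__all__ = ["SyntheticKBSpec", "generate_kb", "generate_cohort", "DEFAULT_KB_SEED"]

#: Seed of the default stand-in dataset; fixed so "the default synthetic KB"
#: names one reproducible object, the way a frozen download would.
DEFAULT_KB_SEED = 20150901


@dataclass(frozen=True)
class SyntheticKBSpec:
    """Parameters of the synthetic knowledge-base generator.

    ``size_log_mean``/``size_log_sd`` are the log-scale location and
    spread of the truncated log-normal for per-disease symptom counts;
    the defaults put the median near 25 symptoms inside [5, 180].
    """

    n_diseases: int = 2000
    vocab_size: int = 3000
    size_min: int = 5
    size_max: int = 180
    size_log_mean: float = 3.2
    size_log_sd: float = 0.9
    sharing_concentration: float = 2.0
    seed: int = DEFAULT_KB_SEED

    def __post_init__(self) -> None:
        if self.n_diseases < 1:
            raise ValueError("n_diseases must be >= 1")
        if not 1 <= self.size_min <= self.size_max <= self.vocab_size:
            raise ValueError(
                "need 1 <= size_min <= size_max <= vocab_size, got "
                f"{self.size_min}, {self.size_max}, {self.vocab_size}"
            )
        if self.size_log_sd <= 0:
            raise ValueError("size_log_sd must be > 0")
        if self.sharing_concentration < 0:
            raise ValueError("sharing_concentration must be >= 0")

    def truncated_size_median(self) -> float:
        """Median of the continuous truncated log-normal (oracle quantity)."""
        dist = stats.lognorm(s=self.size_log_sd, scale=np.exp(self.size_log_mean))
        lo, hi = dist.cdf(self.size_min), dist.cdf(self.size_max)
        return float(dist.ppf(lo + 0.5 * (hi - lo)))


def _sample_sizes(spec: SyntheticKBSpec, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample integer set sizes from the truncated log-normal."""
    out = np.empty(spec.n_diseases, dtype=np.int64)
    filled = 0
    while filled < spec.n_diseases:
        draw = rng.lognormal(spec.size_log_mean, spec.size_log_sd, 2 * spec.n_diseases)
        keep = draw[(draw >= spec.size_min) & (draw <= spec.size_max)]
        take = min(len(keep), spec.n_diseases - filled)
        out[filled : filled + take] = np.rint(keep[:take]).astype(np.int64)
        filled += take
    return np.clip(out, spec.size_min, spec.size_max)


def generate_kb(spec: SyntheticKBSpec | None = None, max_retries: int = 100) -> KnowledgeBase:
    """Generate a validated knowledge base, deterministic per seed.

    Pairwise-distinct symptom sets are enforced by resampling a colliding
    disease up to ``max_retries`` times; exhaustion raises with the
    colliding set sizes (only plausible for tiny vocabularies).
    """
    if spec is None:
        spec = SyntheticKBSpec()
    rng = np.random.default_rng(spec.seed)
    width_s = len(str(spec.vocab_size))
    width_d = len(str(spec.n_diseases))
    symptom_ids = [f"S{i + 1:0{width_s}d}" for i in range(spec.vocab_size)]
    if spec.sharing_concentration == 0.0:
        weights = None  # exactly uniform
    else:
        alpha = 1.0 / spec.sharing_concentration
        weights = rng.dirichlet(np.full(spec.vocab_size, alpha))
    sizes = _sample_sizes(spec, rng)
    seen: set[frozenset[int]] = set()
    diseases: list[DiseaseEntry] = []
    for i in range(spec.n_diseases):
        size = int(sizes[i])
        for attempt in range(max_retries):
            picks = frozenset(
                rng.choice(spec.vocab_size, size=size, replace=False, p=weights).tolist()
            )
            if picks not in seen:
                break
        else:
            raise RuntimeError(
                f"could not generate a distinct symptom set of size {size} for "
                f"disease {i + 1} within {max_retries} retries"
            )
        seen.add(picks)
        diseases.append(
            DiseaseEntry(
                id=f"D{i + 1:0{width_d}d}",
                name=f"synthetic disease {i + 1}",
                symptoms=frozenset(symptom_ids[j] for j in picks),
            )
        )
    return KnowledgeBase(
        diseases=tuple(diseases),
        vocabulary=tuple(
            Symptom(sid, f"synthetic symptom {i + 1}")
            for i, sid in enumerate(symptom_ids)
        ),
    )


def generate_cohort(
    kb: KnowledgeBase,
    patients_per_disease: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[SyntheticPatient, ...]:
    """Noise-free patients carrying full symptom sets, ready for the
    benchmark noise operators.

    With one patient per disease this equals the benchmark's baseline
    cohort; ``rng`` is accepted for interface symmetry with the noise
    operators (the noiseless construction itself draws nothing).
    """
    if patients_per_disease < 1:
        raise ValueError("patients_per_disease must be >= 1")
    return tuple(
        SyntheticPatient(true_disease=d.id, observed=d.symptoms)
        for d in kb.diseases
        for _ in range(patients_per_disease)
    )
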