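"""Synthetic labeled cohorts with syndrome-conditional binary symptom
profiles.

Each syndrome is characterized by a set of signature findings that occur
with high probability in its patients, on top of low-probability background
findings shared by everyone. Feature presence is conditionally independent
given the syndrome — the simplest model under which the estimated
syndrome-conditional probability is exactly the generating parameter, which
makes parameter-recovery tests sharp. Real records correlate symptoms
within a patient; that structure is deliberately not modeled.

The default configuration mirrors the published cohort: 1265 patients with
class sizes KED 339, LFBU 307, PFSI 194, QDSS 270, WFAI 155, and each
syndrome's 10 published signature entities as its high-probability
vocabulary. Signature names shared between syndromes (fine pulse and
duration under both QDSS and KED, for example) reproduce the overlap that
makes those two patterns confusable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ingest import PatientRecord, SYNDROMES
from .weighting import load_reference_weights

#: Published per-syndrome cohort sizes (sum 1265).
DEFAULT_CLASS_SIZES = {"KED": 339, "LFBU": 307, "PFSI": 194, "QDSS": 270, "WFAI": 155}

#: Presence probability of a signature entity under a syndrome it does not
#: characterize: at the top of the background band, since real signature
#: findings are common complaints, not syndrome-exclusive.
NONSIGNATURE_PROB = 0.10


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic cohort.

    ``signature_probs`` maps (entity, syndrome) to the Bernoulli presence
    probability of that entity in that syndrome's patients; entities absent
    from the map for a syndrome fall back to ``background_probs`` (for
    background entities) or ``nonsignature_prob``.
    """

    class_sizes: dict[str, int] = field(default_factory=dict)
    signature_probs: dict[tuple[str, str], float] = field(default_factory=dict)
    background_probs: dict[str, float] = field(default_factory=dict)
    nonsignature_prob: float = NONSIGNATURE_PROB
    seed: int = 0

    def validate(self) -> None:
        if not self.class_sizes:
            raise ValueError("class_sizes must be non-empty")
        for s, n in self.class_sizes.items():
            if n < 1:
                raise ValueError(f"class size for {s!r} must be >= 1, got {n}")
        probs = (
            list(self.signature_probs.values())
            + list(self.background_probs.values())
            + [self.nonsignature_prob]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for s in self.class_sizes:
            if not any(syn == s for _, syn in self.signature_probs):
                raise ValueError(f"syndrome {s!r} has no signature entity")

    @property
    def syndromes(self) -> tuple[str, ...]:
        return tuple(sorted(self.class_sizes))

    @property
    def entities(self) -> tuple[str, ...]:
        names = {e for e, _ in self.signature_probs} | set(self.background_probs)
        return tuple(sorted(names))

    def presence_prob(self, entity: str, syndrome: str) -> float:
        if (entity, syndrome) in self.signature_probs:
            return self.signature_probs[(entity, syndrome)]
        if entity in self.background_probs:
            return self.background_probs[entity]
        return self.nonsignature_prob


def default_config(seed: int = 0) -> CohortConfig:
    """The study-scale default: published class sizes; each syndrome's 10
    published signature entities with presence probabilities linearly spaced
    0.9 → 0.6 in descending published-weight order; 10 generic background
    findings at probabilities 0.05 → 0.2 identical across syndromes."""
    ref = load_reference_weights()
    signature_probs: dict[tuple[str, str], float] = {}
    for syndrome in SYNDROMES:
        entities = sorted(
            (e for (e, s) in ref.combined if s == syndrome),
            key=lambda e: -ref.combined[(e, syndrome)],
        )
        for p, entity in zip(np.linspace(0.9, 0.6, len(entities)), entities):
            signature_probs[(entity, syndrome)] = float(p)
    background_probs = {
        f"Background finding {i + 1:02d}": float(p)
        for i, p in enumerate(np.linspace(0.05, 0.2, 10))
    }
    cfg = CohortConfig(
        class_sizes=dict(DEFAULT_CLASS_SIZES),
        signature_probs=signature_probs,
        background_probs=background_probs,
        seed=seed,
    )
    cfg.validate()
    return cfg


def generate_cohort(config: CohortConfig, seed: int | None = None) -> list[PatientRecord]:
    """Draw the cohort: for each syndrome, ``class_sizes[s]`` patients whose
    features are independent Bernoulli draws at the configured presence
    probabilities. Patients who draw no feature at all are resampled, so
    every record is non-empty. Deterministic per seed."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    entities = list(config.entities)
    records: list[PatientRecord] = []
    idx = 0
    for syndrome in config.syndromes:
        p = np.array([config.presence_prob(e, syndrome) for e in entities])
        n = config.class_sizes[syndrome]
        draws = rng.random((n, len(entities))) < p
        for row in draws:
            while not row.any():  # resample empty profiles
                row = rng.random(len(entities)) < p
            records.append(
                PatientRecord(
                    patient_id=f"S{idx:04d}",
                    features=frozenset(e for e, present in zip(entities, row) if present),
                    syndrome=syndrome,
                )
            )
            idx += 1
    return records


def corrupt_labels(
    records: list[PatientRecord], rate: float, seed: int = 0
) -> list[PatientRecord]:
    """Reassign exactly round(rate·n) labels, chosen at random, to a
    uniformly drawn *different* syndrome. Robustness-testing utility."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    n_corrupt = int(round(rate * len(records)))
    targets = set(rng.choice(len(records), size=n_corrupt, replace=False)) if n_corrupt else set()
    out = []
    for i, rec in enumerate(records):
        if i in targets:
            others = [s for s in SYNDROMES if s != rec.syndrome]
            new = others[rng.integers(len(others))]
            out.append(PatientRecord(rec.patient_id, rec.features, new))
        else:
            out.append(rec)
    return out
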