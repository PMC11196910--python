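"""Edge-weight computation for symptom→syndrome relations.

Each feature entity's weight toward a syndrome combines two terms estimated
from the labeled cohort:

* ``w_if`` — the information gain (mutual information, in bits) between the
  feature's presence/absence and the syndrome label:
  ``w_if = Gain(Y, X) = H(Y) − H(Y|X)``. It measures how much diagnostic
  information the entity carries overall, regardless of direction.
* ``w_sd`` — the syndrome-conditional presence probability
  ``p(symptom | syndrome)``, optionally add-α smoothed:
  ``(count + α) / (n_syndrome + 2α)``.

The combined edge weight is their sum, ``Weight = w_if + w_sd``, so for a
5-class label it is bounded by ``log2(5) + 1``. The same entity gets the
same ``w_if`` under every syndrome but a different ``w_sd``, which is what
lets a shared pulse finding count more toward one syndrome than another.
"""

from __future__ import annotations

import importlib.resources

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .ingest import PatientRecord

_TOL = 1e-9


def shannon_entropy(probabilities: Sequence[float]) -> float:
    """Shannon entropy in bits, with the 0·log0 = 0 convention.
    ``probabilities`` must sum to 1."""
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("distribution must be a non-empty 1-D sequence")
    if np.any(p < -_TOL) or np.any(p > 1 + _TOL):
        raise ValueError("probabilities must lie in [0, 1]")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"probabilities sum to {p.sum()}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _counts(values: Sequence) -> tuple[np.ndarray, list]:
    levels = sorted(set(values), key=repr)
    index = {v: i for i, v in enumerate(levels)}
    out = np.zeros(len(levels), dtype=float)
    for v in values:
        out[index[v]] += 1
    return out, levels


def conditional_entropy(feature: Sequence, labels: Sequence) -> float:
    """H(Y|X) in bits from paired observations: the expected label entropy
    within each feature state, weighted by the state's frequency."""
    if len(feature) != len(labels):
        raise ValueError(
            f"length mismatch: {len(feature)} feature values vs {len(labels)} labels"
        )
    if len(labels) == 0:
        raise ValueError("empty sample")
    n = len(labels)
    by_state: dict = {}
    for x, y in zip(feature, labels):
        by_state.setdefault(x, []).append(y)
    h = 0.0
    for ys in by_state.values():
        counts, _ = _counts(ys)
        h += (len(ys) / n) * shannon_entropy(counts / counts.sum())
    return h


def information_gain(feature: Sequence, labels: Sequence) -> float:
    """Mutual information H(Y) − H(Y|X) in bits between a feature (binary
    presence/absence in this package's use) and the syndrome labels."""
    counts, _ = _counts(labels)
    h_y = shannon_entropy(counts / counts.sum())
    gain = h_y - conditional_entropy(feature, labels)
    # exact-arithmetic gain is >= 0; floating error can leave a tiny negative
    return max(gain, 0.0)


def syndrome_conditional_prob(
    records: Sequence[PatientRecord],
    syndromes: Sequence[str] | None = None,
    alpha: float = 0.0,
) -> dict[tuple[str, str], float]:
    """Estimate p(entity present | syndrome) for every entity seen in the
    cohort under every syndrome, add-α smoothed: (k + α) / (n_s + 2α)."""
    if not records:
        raise ValueError("empty cohort")
    unlabeled = [r.patient_id for r in records if r.syndrome is None]
    if unlabeled:
        raise ValueError(f"unlabeled records: {unlabeled[:5]}")
    class_sizes = Counter(r.syndrome for r in records)
    if syndromes is None:
        syndromes = sorted(class_sizes)
    for s in syndromes:
        if class_sizes.get(s, 0) == 0:
            raise ValueError(f"syndrome {s!r} has zero patients")
    entities = sorted(set().union(*(r.features for r in records)))
    present: Counter = Counter()
    for r in records:
        for e in r.features:
            present[(e, r.syndrome)] += 1
    return {
        (e, s): (present[(e, s)] + alpha) / (class_sizes[s] + 2 * alpha)
        for e in entities
        for s in syndromes
    }


@dataclass
class WeightTable:
    """Combined symptom→syndrome edge weights, with the per-term breakdown
    when computed from a cohort (a transcribed reference table may carry the
    combined column only)."""

    combined: dict[tuple[str, str], float]
    w_if: dict[str, float] = field(default_factory=dict)
    w_sd: dict[tuple[str, str], float] = field(default_factory=dict)
    syndromes: tuple[str, ...] = ()
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not self.syndromes:
            self.syndromes = tuple(sorted({s for _, s in self.combined}))
        for (e, s), c in self.combined.items():
            if e in self.w_if and (e, s) in self.w_sd:
                if abs(self.w_if[e] + self.w_sd[(e, s)] - c) > _TOL:
                    raise ValueError(
                        f"combined weight for ({e!r}, {s!r}) is not w_if + w_sd"
                    )

    @property
    def entities(self) -> list[str]:
        return sorted({e for e, _ in self.combined})

    def lookup(self, entity: str, syndrome: str) -> float:
        try:
            return self.combined[(entity, syndrome)]
        except KeyError:
            raise KeyError(
                f"no weight for entity {entity!r} under syndrome {syndrome!r}"
            ) from None

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("entity\tsyndrome\tw_if\tw_sd\tcombined\n")
            for (e, s), c in sorted(self.combined.items()):
                wif = repr(self.w_if[e]) if e in self.w_if else ""
                wsd = repr(self.w_sd[(e, s)]) if (e, s) in self.w_sd else ""
                fh.write(f"{e}\t{s}\t{wif}\t{wsd}\t{c!r}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "WeightTable":
        combined: dict[tuple[str, str], float] = {}
        w_if: dict[str, float] = {}
        w_sd: dict[tuple[str, str], float] = {}
        with Path(path).open(encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header != ["entity", "syndrome", "w_if", "w_sd", "combined"]:
                raise ValueError(f"{path}:1: bad weight-table header {header!r}")
            for lineno, line in enumerate(fh, start=2):
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 columns")
                e, s, wif, wsd, c = parts
                combined[(e, s)] = float(c)
                if wif:
                    w_if[e] = float(wif)
                if wsd:
                    w_sd[(e, s)] = float(wsd)
        return cls(combined=combined, w_if=w_if, w_sd=w_sd)


def compute_weight_table(
    records: Sequence[PatientRecord],
    alpha: float = 0.0,
    syndromes: Sequence[str] | None = None,
) -> WeightTable:
    """Estimate the full weight table from a labeled cohort: one ``w_if``
    per entity, one ``w_sd`` per (entity, syndrome) pair over the observed
    feature universe, combined by summation."""
    if not records:
        raise ValueError("empty cohort")
    w_sd = syndrome_conditional_prob(records, syndromes=syndromes, alpha=alpha)
    labels = [r.syndrome for r in records]
    entities = sorted({e for e, _ in w_sd})
    syn = tuple(sorted({s for _, s in w_sd}))
    w_if: dict[str, float] = {}
    for e in entities:
        presence = [e in r.features for r in records]
        w_if[e] = information_gain(presence, labels)
    combined = {(e, s): w_if[e] + w_sd[(e, s)] for e in entities for s in syn}
    return WeightTable(combined=combined, w_if=w_if, w_sd=w_sd, syndromes=syn, alpha=alpha)


def lookup_weight(table: WeightTable, entity: str, syndrome: str) -> float:
    return table.lookup(entity, syndrome)


def load_reference_weights() -> WeightTable:
    """The packaged reference table of 50 published symptom→syndrome combined
    weights (10 entities for each of the 5 syndromes), usable for lookups and
    as a realistic signature vocabulary for simulation."""
    ref = importlib.resources.files("kgdiag.data") / "table2_weights.tsv"
    with importlib.resources.as_file(ref) as path:
        return WeightTable.from_tsv(path)
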