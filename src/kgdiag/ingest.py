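"""Ingest structured patient records and curated knowledge triples, align
near-duplicate entity names by string similarity, and assemble the fused
knowledge graph.

Free-text extraction is out of scope: records arrive already structured
(one row per patient with the set of present symptom/attribute labels and
an optional syndrome diagnosis). Continuous findings must arrive pre-binned
as categorical labels (e.g. ``"duration:>1y"``) — every feature is a
discrete graph entity.
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

from .graph import Entity, KnowledgeGraph, Relation

#: The five syndrome-pattern labels: wind fire attacking internally,
#: liver fire bearing upward, phlegm fire stagnation internally,
#: Qi deficiency of the spleen and stomach, kidney essence deficiency.
SYNDROMES = ("KED", "LFBU", "PFSI", "QDSS", "WFAI")

#: Default auto-alignment threshold: short clinical entity strings warrant a
#: permissive cutoff, and near-duplicate syndrome names in the source
#: vocabulary typically differ in one or two characters out of five.
DEFAULT_THRESHOLD = 0.6


@dataclass(frozen=True)
class PatientRecord:
    """One patient row: id, the set of present feature labels (symptoms,
    tongue/pulse findings, pre-binned attributes), and the syndrome
    diagnosis when known (``None`` for a query patient)."""

    patient_id: str
    features: frozenset[str]
    syndrome: str | None = None

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError(f"patient {self.patient_id!r} has no features")
        if self.syndrome is not None and self.syndrome not in SYNDROMES:
            raise ValueError(
                f"patient {self.patient_id!r}: unknown syndrome "
                f"{self.syndrome!r}; expected one of {SYNDROMES}"
            )


def read_records(path: str | Path) -> list[PatientRecord]:
    """Read patient records from JSONL (``{"patient_id":…, "features":[…],
    "syndrome":…}``) or CSV (``patient_id,features,syndrome`` with features
    ``|``-joined). Duplicate patient ids are rejected."""
    path = Path(path)
    rows: list[tuple[str, list[str], str | None]] = []
    if path.suffix.lower() in (".jsonl", ".json", ".ndjson"):
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: invalid JSON: {exc}") from None
                if "patient_id" not in obj or "features" not in obj:
                    raise ValueError(
                        f"{path}:{lineno}: missing required key "
                        "'patient_id' or 'features'"
                    )
                rows.append(
                    (str(obj["patient_id"]), list(obj["features"]), obj.get("syndrome"))
                )
    elif path.suffix.lower() in (".csv", ".tsv"):
        delim = "\t" if path.suffix.lower() == ".tsv" else ","
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            required = {"patient_id", "features"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise ValueError(
                    f"{path}: missing required column(s) "
                    f"{sorted(required - set(reader.fieldnames or ()))}"
                )
            for row in reader:
                feats = [f for f in (row["features"] or "").split("|")]
                rows.append((row["patient_id"], feats, row.get("syndrome") or None))
    else:
        raise ValueError(f"unrecognized records format {path.suffix!r} for {path}")

    records: list[PatientRecord] = []
    seen: set[str] = set()
    for i, (pid, feats, syndrome) in enumerate(rows, start=1):
        if pid in seen:
            raise ValueError(f"{path}: duplicate patient_id {pid!r} (row {i})")
        seen.add(pid)
        cleaned = frozenset(f.strip() for f in feats if f.strip())
        if not cleaned:
            raise ValueError(f"{path}: row {i} (patient {pid!r}) has no features")
        records.append(PatientRecord(pid, cleaned, syndrome))
    return records


def write_records(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records as JSONL, the format ``read_records`` ingests."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "patient_id": r.patient_id,
                        "features": sorted(r.features),
                        "syndrome": r.syndrome,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# -- string similarity -------------------------------------------------------


def _lcs_length(a: str, b: str) -> int:
    # small DP; entity strings are a handful of characters
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0]
        for j, cb in enumerate(b, start=1):
            cur.append(prev[j - 1] + 1 if ca == cb else max(prev[j], cur[j - 1]))
        prev = cur
    return prev[-1]


def string_similarity(a: str, b: str, metric: str = "levenshtein") -> float:
    """Similarity in [0, 1] between two entity names, computed on Unicode
    code points so Chinese strings behave per-character.

    ``levenshtein`` (default): 1 − editdistance / max(len).
    ``lcs``: 2·LCS / (len(a) + len(b)).
    """
    if not a or not b:
        raise ValueError("string_similarity requires non-empty strings")
    if metric == "levenshtein":
        dist = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
        return 1.0 - dist / max(len(a), len(b))
    if metric == "lcs":
        return 2.0 * _lcs_length(a, b) / (len(a) + len(b))
    raise ValueError(f"unknown similarity metric {metric!r}")


@dataclass
class AlignmentMap:
    """Raw label -> canonical label mapping produced by ``align_entities``.

    Canonical labels map to themselves (the map is idempotent); every
    auto-mapped pair records the similarity that justified it; manual
    overrides win over automatic matches.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    similarity: dict[str, float] = field(default_factory=dict)
    manual_overrides: dict[str, str] = field(default_factory=dict)

    def apply(self, label: str) -> str:
        return self.mapping.get(label, label)

    def apply_record(self, record: PatientRecord) -> PatientRecord:
        return PatientRecord(
            record.patient_id,
            frozenset(self.apply(f) for f in record.features),
            record.syndrome,
        )


def align_entities(
    labels: Iterable[str],
    canonical: Sequence[str],
    threshold: float = DEFAULT_THRESHOLD,
    overrides: Mapping[str, str] | None = None,
    metric: str = "levenshtein",
) -> AlignmentMap:
    """Map each raw label to its highest-similarity canonical label when that
    similarity reaches ``threshold``; otherwise the label passes through
    unchanged. Explicit ``overrides`` (raw -> canonical) always win."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    amap = AlignmentMap(manual_overrides=dict(overrides or {}))
    canonical = list(canonical)
    canonical_set = set(canonical)
    for label in labels:
        if label in amap.manual_overrides:
            amap.mapping[label] = amap.manual_overrides[label]
            amap.similarity[label] = 1.0
            continue
        if label in canonical_set:
            amap.mapping[label] = label
            amap.similarity[label] = 1.0
            continue
        best, best_sim = label, 0.0
        for cand in canonical:
            sim = string_similarity(label, cand, metric=metric)
            if sim > best_sim:
                best, best_sim = cand, sim
        if best_sim >= threshold:
            amap.mapping[label] = best
            amap.similarity[label] = best_sim
        else:
            amap.mapping[label] = label
    for cand in canonical:
        amap.mapping.setdefault(cand, cand)
        amap.similarity.setdefault(cand, 1.0)
    return amap


def read_overrides(path: str | Path) -> dict[str, str]:
    """Read a two-column ``raw<TAB>canonical`` override file (the auditable
    stand-in for manual curation of the fused vocabulary)."""
    out: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out[parts[0]] = parts[1]
    return out


def read_triples(path: str | Path) -> list[tuple[str, str, str]]:
    """Read curated knowledge triples from TSV ``source<TAB>rtype<TAB>target``."""
    triples: list[tuple[str, str, str]] = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["source", "rtype", "target"]:
            raise ValueError(f"{path}:1: bad triple header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            triples.append((parts[0], parts[1], parts[2]))
    return triples


# -- graph assembly ----------------------------------------------------------


def slugify(label: str) -> str:
    """ASCII-safe id for a display label. Non-ASCII labels (e.g. Chinese)
    get a short stable hash; the display label is kept on the node."""
    if label.isascii():
        slug = re.sub(r"[^a-z0-9]+", "-", label.lower()).strip("-")
        if slug:
            return slug
    digest = hashlib.blake2b(label.encode("utf-8"), digest_size=4).hexdigest()
    return f"x{digest}"


def build_graph(
    records: Sequence[PatientRecord],
    knowledge_triples: Iterable[tuple[str, str, str]] = (),
    alignment: AlignmentMap | None = None,
) -> KnowledgeGraph:
    """Assemble the fused graph: one patient node per record, an edge from
    each patient to every feature entity, an edge to the syndrome node when
    the record is labeled, then the curated triples on the aligned
    vocabulary."""
    if not records:
        raise ValueError("build_graph requires at least one record")
    alignment = alignment or AlignmentMap()
    graph = KnowledgeGraph()
    label_to_id: dict[str, str] = {}
    taken: set[str] = set()

    def feature_node(label: str, etype: str = "symptom") -> str:
        label = alignment.apply(label)
        if label in label_to_id:
            return label_to_id[label]
        node_id = slugify(label)
        if node_id in taken:  # same slug from a different label
            node_id = f"{node_id}-{hashlib.blake2b(label.encode(), digest_size=3).hexdigest()}"
        label_to_id[label] = node_id
        taken.add(node_id)
        graph.upsert_entity(Entity(node_id, label, etype))
        return node_id

    for s in SYNDROMES:
        graph.upsert_entity(Entity(s, s, "syndrome"))
        label_to_id[s] = s
        taken.add(s)

    for rec in records:
        pid = rec.patient_id
        if pid in taken and (pid not in graph or graph.entity(pid).etype != "patient"):
            raise ValueError(f"patient id {pid!r} collides with an entity id")
        graph.upsert_entity(Entity(pid, pid, "patient"))
        taken.add(pid)
        for feat in sorted(rec.features):
            graph.upsert_relation(Relation(pid, feature_node(feat), "has_finding"))
        if rec.syndrome is not None:
            graph.upsert_relation(Relation(pid, rec.syndrome, "diagnosed_as"))

    for source, rtype, target in knowledge_triples:
        src_label = alignment.apply(source)
        tgt_label = alignment.apply(target)
        ids = []
        for lab in (src_label, tgt_label):
            node_id = label_to_id.get(lab, lab if lab in graph else None)
            if node_id is not None and graph.entity(node_id).etype == "patient":
                raise ValueError(
                    f"knowledge triple ({source!r}, {rtype!r}, {target!r}) "
                    f"references patient node {node_id!r}"
                )
            ids.append(node_id if node_id is not None else feature_node(lab))
        graph.upsert_relation(Relation(ids[0], ids[1], rtype))
    return graph
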