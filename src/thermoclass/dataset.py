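"""Dataset construction: threshold labelling, cluster-disjoint splitting,
class balancing, and a self-contained greedy sequence clusterer.

Labels derive from one scalar per organism — its optimal growth temperature
(OGT) — so per-threshold labels are monotone by construction: a protein
labelled stable at 65 degrees C is also labelled stable at every lower
threshold.  Splits are made at the granularity of whole identity clusters
so that no two homologous sequences (same cluster) land in different
subsets, preventing leakage between train, validation and test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import ClusterTable, SequenceRecord

__all__ = [
    "OrganismAnnotation",
    "LabeledExample",
    "DatasetSplit",
    "assign_threshold_labels",
    "build_examples",
    "cluster_disjoint_split",
    "balanced_subsample",
    "greedy_cluster",
    "write_split_manifest",
    "read_split_manifest",
]

# Plausibility window for growth temperatures in degrees Celsius.
MIN_PLAUSIBLE_OGT = -20.0
MAX_PLAUSIBLE_OGT = 150.0


@dataclass(frozen=True)
class OrganismAnnotation:
    organism_key: str
    growth_temperature: float  # degrees Celsius

    def __post_init__(self) -> None:
        t = self.growth_temperature
        if not math.isfinite(t):
            raise ValueError(f"growth temperature of {self.organism_key!r} not finite")
        if not MIN_PLAUSIBLE_OGT <= t <= MAX_PLAUSIBLE_OGT:
            raise ValueError(
                f"growth temperature {t} of {self.organism_key!r} outside the "
                f"plausible range [{MIN_PLAUSIBLE_OGT}, {MAX_PLAUSIBLE_OGT}]"
            )


@dataclass
class LabeledExample:
    """One training/evaluation item: mean embedding plus per-threshold labels."""

    sequence_id: str
    embedding: np.ndarray
    labels: dict[float, int]
    growth_temperature: float

    def __post_init__(self) -> None:
        self.embedding = np.asarray(self.embedding, dtype=np.float64)
        ts = sorted(self.labels)
        # monotone by construction from one scalar OGT
        for lo, hi in zip(ts, ts[1:]):
            if self.labels[hi] > self.labels[lo]:
                raise ValueError(
                    f"non-monotone labels for {self.sequence_id!r}: "
                    f"label[{hi}]={self.labels[hi]} > label[{lo}]={self.labels[lo]}"
                )


@dataclass
class DatasetSplit:
    train: list[LabeledExample]
    validation: list[LabeledExample]
    test: list[LabeledExample]
    cluster_ids: dict[str, set[int]] = field(default_factory=dict)

    def subset(self, name: str) -> list[LabeledExample]:
        return getattr(self, name)


def assign_threshold_labels(
    growth_temperature: float, thresholds: Sequence[float]
) -> dict[float, int]:
    """Per-threshold binary labels: 1 iff OGT >= threshold.

    The OGT is a lower bound on protein melting temperature, so an organism
    growing at the threshold temperature counts as class 1 ("stable at T
    and higher").
    """
    if not math.isfinite(growth_temperature):
        raise ValueError(f"growth temperature {growth_temperature} not finite")
    ts = [float(t) for t in thresholds]
    if not ts:
        raise ValueError("threshold list must be non-empty")
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError(f"thresholds must be strictly ascending, got {ts}")
    return {t: int(growth_temperature >= t) for t in ts}


def build_examples(
    records: Iterable[SequenceRecord],
    annotations: Mapping[str, float],
    embeddings: Mapping[str, np.ndarray],
    thresholds: Sequence[float],
) -> list[LabeledExample]:
    """Join sequences, organism temperatures and embeddings into examples."""
    examples = []
    missing_ann: list[str] = []
    for rec in records:
        if rec.organism_key is None or rec.organism_key not in annotations:
            missing_ann.append(rec.id)
            continue
        ogt = OrganismAnnotation(rec.organism_key, annotations[rec.organism_key])
        examples.append(
            LabeledExample(
                sequence_id=rec.id,
                embedding=embeddings[rec.id],
                labels=assign_threshold_labels(ogt.growth_temperature, thresholds),
                growth_temperature=ogt.growth_temperature,
            )
        )
    if missing_ann:
        raise ValueError(
            f"{len(missing_ann)} sequences without organism annotation, "
            f"e.g. {missing_ann[:5]}"
        )
    return examples


def cluster_disjoint_split(
    examples: Sequence[LabeledExample],
    clusters: ClusterTable,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> DatasetSplit:
    """Assign whole clusters to train/validation/test.

    Cluster ids are shuffled with the given seed, then each cluster goes to
    the subset with the largest remaining deficit against its target
    sequence count (ties broken in train > validation > test order).  The
    same inputs and seed always produce the same split.  A warning is
    emitted when cluster atomicity forces realized fractions more than 10
    percentage points away from the targets.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    by_cluster: dict[int, list[LabeledExample]] = {}
    for ex in examples:
        cid = clusters.assignments.get(ex.sequence_id)
        if cid is None:
            raise ValueError(f"example {ex.sequence_id!r} missing from cluster table")
        by_cluster.setdefault(cid, []).append(ex)

    rng = np.random.Generator(np.random.PCG64(seed))
    cluster_ids = sorted(by_cluster)
    rng.shuffle(cluster_ids)

    total = sum(len(v) for v in by_cluster.values())
    names = ("train", "validation", "test")
    targets = {name: frac * total for name, frac in zip(names, fractions)}
    counts = {name: 0 for name in names}
    assigned: dict[str, set[int]] = {name: set() for name in names}
    subsets: dict[str, list[LabeledExample]] = {name: [] for name in names}

    for cid in cluster_ids:
        deficits = [(targets[name] - counts[name], -i) for i, name in enumerate(names)]
        pick = names[max(range(3), key=lambda i: deficits[i])]
        assigned[pick].add(cid)
        subsets[pick].extend(by_cluster[cid])
        counts[pick] += len(by_cluster[cid])

    for name, frac in zip(names, fractions):
        if total and abs(counts[name] / total - frac) > 0.10:
            warnings.warn(
                f"cluster atomicity: realized {name} fraction "
                f"{counts[name] / total:.2f} deviates from target {frac:.2f}",
                stacklevel=2,
            )
    return DatasetSplit(
        train=subsets["train"],
        validation=subsets["validation"],
        test=subsets["test"],
        cluster_ids=assigned,
    )


def balanced_subsample(
    examples: Sequence[LabeledExample], threshold: float, n: int, seed: int = 0
) -> list[LabeledExample]:
    """Sample n/2 examples of each class at the given threshold, without
    replacement, deterministically under the seed."""
    if n % 2:
        raise ValueError(f"n must be even, got {n}")
    half = n // 2
    pos = [ex for ex in examples if ex.labels[threshold] == 1]
    neg = [ex for ex in examples if ex.labels[threshold] == 0]
    if len(pos) < half or len(neg) < half:
        raise ValueError(
            f"insufficient class members at threshold {threshold:g}: "
            f"{len(pos)} positives / {len(neg)} negatives, need {half} each"
        )
    rng = np.random.Generator(np.random.PCG64(seed))
    picked_pos = [pos[i] for i in rng.choice(len(pos), size=half, replace=False)]
    picked_neg = [neg[i] for i in rng.choice(len(neg), size=half, replace=False)]
    return picked_pos + picked_neg


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_identity(a: str, b: str, k: int = 5) -> float:
    """Shared-k-mer fraction of the shorter sequence (ungapped containment)."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    ks = _kmers(short, k)
    if not ks:
        return 0.0
    return len(ks & _kmers(long_, k)) / len(ks)


def greedy_cluster(
    records: Sequence[SequenceRecord], identity_threshold: float = 0.3, k: int = 5
) -> ClusterTable:
    """Length-sorted greedy clustering on k-mer containment identity.

    A stand-in for an external identity clusterer so the pipeline runs
    self-contained: records are visited in order of decreasing length
    (ties by id); each joins the first cluster whose representative shares
    at least ``identity_threshold`` k-mer identity, else founds a new
    cluster and becomes its representative.
    """
    if not records:
        raise ValueError("cannot cluster an empty record list")
    if not 0.0 < identity_threshold < 1.0:
        raise ValueError(f"identity threshold must be in (0,1), got {identity_threshold}")
    order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[SequenceRecord] = []
    assignments: dict[str, int] = {}
    representatives: dict[int, str] = {}
    for rec in order:
        placed = False
        for cid, rep in enumerate(reps):
            if kmer_identity(rec.sequence, rep.sequence, k) >= identity_threshold:
                assignments[rec.id] = cid
                placed = True
                break
        if not placed:
            cid = len(reps)
            reps.append(rec)
            assignments[rec.id] = cid
            representatives[cid] = rec.id
    return ClusterTable(assignments=assignments, representatives=representatives)


# ---------------------------------------------------------------------------
# Split manifest TSV

def write_split_manifest(
    split: DatasetSplit,
    clusters: ClusterTable,
    thresholds: Sequence[float],
    path: str | Path,
) -> None:
    path = Path(path)
    ts = [float(t) for t in thresholds]
    header = ["sequence_id", "subset", "cluster_id", "growth_temperature"]
    header += [f"label_{t:g}C" for t in ts]
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for subset in ("train", "validation", "test"):
            for ex in split.subset(subset):
                row = [
                    ex.sequence_id,
                    subset,
                    str(clusters.assignments[ex.sequence_id]),
                    f"{ex.growth_temperature:g}",
                ]
                row += [str(ex.labels[t]) for t in ts]
                fh.write("\t".join(row) + "\n")


def read_split_manifest(path: str | Path) -> dict[str, dict]:
    """Read a split manifest back as {sequence_id: row dict}."""
    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    label_cols = [h for h in header if h.startswith("label_")]
    thresholds = [float(h[len("label_") : -1]) for h in label_cols]
    rows: dict[str, dict] = {}
    for line in lines[1:]:
        parts = dict(zip(header, line.split("\t")))
        rows[parts["sequence_id"]] = {
            "subset": parts["subset"],
            "cluster_id": int(parts["cluster_id"]),
            "growth_temperature": float(parts["growth_temperature"]),
            "labels": {t: int(parts[f"label_{t:g}C"]) for t in thresholds},
        }
    return rows
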