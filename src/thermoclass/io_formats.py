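"""Readers and writers for the formats the toolkit touches.

FASTA (sequences in, via Biopython), CD-HIT ``.clstr`` cluster files,
two-column organism-annotation tables, the prediction TSV, and a portable
checkpoint container (a directory of named arrays plus a JSON metadata
sidecar).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AMINO_ACID_ALPHABET",
    "SequenceRecord",
    "ClusterTable",
    "CheckpointBundle",
    "read_fasta",
    "write_fasta",
    "read_clstr",
    "write_clstr",
    "read_annotations",
    "write_annotations",
    "write_predictions",
    "read_predictions",
    "save_checkpoint",
    "load_checkpoint",
]

# 20 standard residues plus ambiguity/rare codes real proteomes contain.
AMINO_ACID_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZUO")

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class SequenceRecord:
    """One amino-acid sequence with its identifier and source organism."""

    id: str
    sequence: str
    organism_key: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence for record {self.id!r} is empty")
        self.sequence = self.sequence.upper()
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in AMINO_ACID_ALPHABET:
                raise ValueError(
                    f"illegal residue character {ch!r} at position {pos} "
                    f"in record {self.id!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ClusterTable:
    """Assignment of sequence ids to identity clusters.

    Every id maps to exactly one cluster and each cluster has exactly one
    representative sequence.
    """

    assignments: dict[str, int] = field(default_factory=dict)
    representatives: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clusters = set(self.assignments.values())
        for cid in clusters:
            rep = self.representatives.get(cid)
            if rep is None:
                raise ValueError(f"cluster {cid} has no representative")
            if self.assignments.get(rep) != cid:
                raise ValueError(
                    f"representative {rep!r} of cluster {cid} is not a member"
                )
        for cid in self.representatives:
            if cid not in clusters:
                raise ValueError(f"representative given for empty cluster {cid}")

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)

    def members(self, cluster_id: int) -> list[str]:
        return [s for s, c in self.assignments.items() if c == cluster_id]

    def is_representative(self, seq_id: str) -> bool:
        return self.representatives.get(self.assignments[seq_id]) == seq_id


@dataclass
class CheckpointBundle:
    """Weights plus architecture descriptor and training metadata."""

    arrays: dict[str, np.ndarray]
    layer_sizes: list[int]            # e.g. [1024, 256, 128, 1]
    activations: list[str]            # e.g. ["relu", "relu", "sigmoid"]
    threshold: float                  # degrees Celsius
    seed: int
    selected_epoch: int
    validation_mcc: float

    def __post_init__(self) -> None:
        if len(self.activations) != len(self.layer_sizes) - 1:
            raise ValueError("one activation required per weight layer")
        for i in range(len(self.layer_sizes) - 1):
            w = self.arrays.get(f"W{i}")
            b = self.arrays.get(f"b{i}")
            if w is None or b is None:
                raise ValueError(f"missing arrays W{i}/b{i}")
            expected_w = (self.layer_sizes[i], self.layer_sizes[i + 1])
            if w.shape != expected_w or b.shape != (self.layer_sizes[i + 1],):
                raise ValueError(
                    f"layer {i} array shapes {w.shape}/{b.shape} inconsistent "
                    f"with architecture {self.layer_sizes}"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects.

    The record id is the header token up to the first whitespace; the full
    header is kept as the description.  Case is normalised to upper.
    Duplicate ids and illegal residue characters raise ``ValueError``.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, sequence=str(rec.seq), description=rec.description)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.description if rec.description.startswith(rec.id) else rec.id
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# CD-HIT .clstr

_CLSTR_HEADER = re.compile(r"^>Cluster\s+(\d+)")
_CLSTR_MEMBER = re.compile(r"^\d+\s+\d+(?:aa|nt),\s+>(.+?)\.\.\.\s+(.*)$")


def read_clstr(path: str | Path) -> ClusterTable:
    """Parse a CD-HIT ``.clstr`` file into a :class:`ClusterTable`.

    Member lines ending in ``*`` mark the cluster representative; all other
    members carry an ``at XX%`` identity note.  A member line appearing
    before any ``>Cluster`` header, an empty cluster, or a cluster without
    a starred representative is a parse error.
    """
    path = Path(path)
    assignments: dict[str, int] = {}
    representatives: dict[int, str] = {}
    current: int | None = None
    members_in_current = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            header = _CLSTR_HEADER.match(line)
            if header:
                if current is not None and members_in_current == 0:
                    raise ValueError(f"cluster {current} has zero members ({path})")
                current = int(header.group(1))
                members_in_current = 0
                continue
            member = _CLSTR_MEMBER.match(line)
            if not member:
                raise ValueError(f"{path}:{lineno}: unparseable .clstr line: {line!r}")
            if current is None:
                raise ValueError(
                    f"{path}:{lineno}: member line before any '>Cluster' header"
                )
            seq_id, tail = member.group(1), member.group(2)
            if seq_id in assignments:
                raise ValueError(f"{path}:{lineno}: id {seq_id!r} listed twice")
            assignments[seq_id] = current
            members_in_current += 1
            if tail.strip() == "*":
                if current in representatives:
                    raise ValueError(
                        f"{path}:{lineno}: cluster {current} has two representatives"
                    )
                representatives[current] = seq_id
    if current is None:
        raise ValueError(f"no clusters found in {path}")
    if members_in_current == 0:
        raise ValueError(f"cluster {current} has zero members ({path})")
    return ClusterTable(assignments=assignments, representatives=representatives)


def write_clstr(table: ClusterTable, path: str | Path) -> None:
    """Write a cluster table in the CD-HIT ``.clstr`` dialect."""
    path = Path(path)
    by_cluster: dict[int, list[str]] = {}
    for seq_id, cid in table.assignments.items():
        by_cluster.setdefault(cid, []).append(seq_id)
    with path.open("w") as fh:
        for cid in sorted(by_cluster):
            fh.write(f">Cluster {cid}\n")
            rep = table.representatives[cid]
            members = sorted(by_cluster[cid], key=lambda s: (s != rep, s))
            for i, seq_id in enumerate(members):
                tail = "*" if seq_id == rep else "at 90.00%"
                fh.write(f"{i}\t100aa, >{seq_id}... {tail}\n")


# ---------------------------------------------------------------------------
# Annotation table: organism_key<TAB>growth_temperature_celsius

def read_annotations(path: str | Path) -> dict[str, float]:
    path = Path(path)
    out: dict[str, float] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            key, temp = parts
            if key in out:
                raise ValueError(f"{path}:{lineno}: duplicate organism key {key!r}")
            out[key] = float(temp)
    if not out:
        raise ValueError(f"no annotations found in {path}")
    return out


def write_annotations(annotations: dict[str, float], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, temp in annotations.items():
            fh.write(f"{key}\t{temp:g}\n")


# ---------------------------------------------------------------------------
# Prediction TSV

def _format_temp(t: float) -> str:
    return f"{t:g}"


def write_predictions(profiles: Sequence, path: str | Path, decimals: int = 4) -> None:
    """Write prediction profiles as a TSV table.

    Columns: ``sequence_id``, one probability and one binary-call column per
    threshold in ascending temperature order, ``left_label``, ``right_label``
    and ``clash`` (literal ``true``/``false``).  All profiles must share one
    threshold set.  An empty profile list is allowed only with an explicit
    threshold set on the caller side; it produces a header-only file using
    the default six thresholds.
    """
    from .thermo_labels import DEFAULT_THRESHOLDS  # avoid import cycle

    path = Path(path)
    if profiles:
        thresholds = list(profiles[0].thresholds)
        for p in profiles:
            if list(p.thresholds) != thresholds:
                raise ValueError(
                    f"profile {p.sequence_id!r} has threshold set {list(p.thresholds)}, "
                    f"expected {thresholds}"
                )
    else:
        thresholds = list(DEFAULT_THRESHOLDS)
    header = ["sequence_id"]
    header += [f"prob_{_format_temp(t)}C" for t in thresholds]
    header += [f"call_{_format_temp(t)}C" for t in thresholds]
    header += ["left_label", "right_label", "clash"]
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for p in profiles:
            row = [p.sequence_id]
            row += [f"{prob:.{decimals}f}" for prob in p.probabilities]
            row += [str(int(c)) for c in p.binary_calls]
            row += [p.left_label.name, p.right_label.name, "true" if p.clash else "false"]
            fh.write("\t".join(row) + "\n")


def read_predictions(path: str | Path):
    """Read a prediction TSV written by :func:`write_predictions`."""
    from .thermo_labels import PredictionProfile, left_right_labels

    path = Path(path)
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty prediction file {path}")
    header = lines[0].split("\t")
    prob_cols = [h for h in header if h.startswith("prob_")]
    thresholds = [float(h[len("prob_") : -1]) for h in prob_cols]
    n = len(thresholds)
    profiles = []
    for line in lines[1:]:
        parts = line.split("\t")
        seq_id = parts[0]
        probs = [float(x) for x in parts[1 : 1 + n]]
        calls = [int(x) for x in parts[1 + n : 1 + 2 * n]]
        left, right, clash = left_right_labels(calls, thresholds)
        profiles.append(
            PredictionProfile(
                sequence_id=seq_id,
                thresholds=thresholds,
                probabilities=probs,
                binary_calls=calls,
                left_label=left,
                right_label=right,
                clash=clash,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Checkpoint container

def save_checkpoint(bundle: CheckpointBundle, path: str | Path) -> None:
    """Persist a checkpoint as ``<path>/meta.json`` + ``<path>/arrays.npz``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "layer_sizes": bundle.layer_sizes,
        "activations": bundle.activations,
        "threshold": bundle.threshold,
        "seed": bundle.seed,
        "selected_epoch": bundle.selected_epoch,
        "validation_mcc": bundle.validation_mcc,
    }
    with (path / "meta.json").open("w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    np.savez(path / "arrays.npz", **bundle.arrays)


def load_checkpoint(path: str | Path) -> CheckpointBundle:
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no checkpoint metadata at {meta_path}")
    with meta_path.open() as fh:
        meta = json.load(fh)
    version = meta.get("format_version")
    if version != CHECKPOINT_FORMAT_VERSION:
        raise ValueError(f"unknown checkpoint format version {version!r}")
    with np.load(path / "arrays.npz") as npz:
        arrays = {k: npz[k] for k in npz.files}
    return CheckpointBundle(
        arrays=arrays,
        layer_sizes=list(meta["layer_sizes"]),
        activations=list(meta["activations"]),
        threshold=float(meta["threshold"]),
        seed=int(meta["seed"]),
        selected_epoch=int(meta["selected_epoch"]),
        validation_mcc=float(meta["validation_mcc"]),
    )
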