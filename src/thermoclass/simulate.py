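"""Synthetic fixture generator.

Emulates an OGT-annotated proteome collection plus mean embeddings whose
class signal is a monotone (linear) function of the organism's growth
temperature: the mean embedding of a protein from an organism with OGT t is

    mu + beta * (t - 50) / 50 * u + eps,

with mu a fixed seeded base vector, u a fixed seeded unit direction, and
eps elementwise Gaussian noise of standard deviation sigma.  All the
information about thermostability therefore lives in a single direction of
embedding space, which is the simplest model under which independently
trained per-threshold classifiers should agree with each other — making
the clash rate of the inference layer a meaningful test statistic.

Sequence content is decoupled from the embedding signal (random residue
strings), so tests of the classifier stack are independent of any embedder.

Two named OGT distributions mirror the temperature coverage of typical
growth-temperature compilations: ``bimodal`` draws organisms from
20-40 or 60-80 degrees C (mesophile/thermophile peaks), ``uniform`` covers
0-100 degrees C.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .embedding import EmbeddingCache, MeanEmbedding, ResidueEmbedding
from .io_formats import (
    ClusterTable,
    SequenceRecord,
    write_annotations,
    write_clstr,
    write_fasta,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_dataset",
    "make_cluster_structure",
    "write_fixture",
    "SignalEmbedder",
]

STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimulationConfig:
    n_organisms: int = 3000
    ogt_distribution: str | Sequence[float] = "uniform"  # or "bimodal" or fixed list
    proteins_per_organism: int = 1
    seq_length_range: tuple[int, int] = (50, 300)
    dim: int = 1024
    beta: float = 3.0   # effect size along the signal direction
    sigma: float = 1.0  # elementwise noise sd
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_organisms < 1 or self.proteins_per_organism < 1 or self.dim < 1:
            raise ValueError("counts and dimension must be positive")
        lo, hi = self.seq_length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad sequence length range {self.seq_length_range}")
        if self.beta < 0 or self.sigma <= 0:
            raise ValueError("beta must be >= 0 and sigma > 0")
        if isinstance(self.ogt_distribution, str):
            if self.ogt_distribution not in ("uniform", "bimodal"):
                raise ValueError(
                    f"unknown OGT distribution {self.ogt_distribution!r}"
                )
        elif len(self.ogt_distribution) != self.n_organisms:
            raise ValueError("fixed OGT list length must equal n_organisms")


@dataclass
class SyntheticDataset:
    records: list[SequenceRecord]
    annotations: dict[str, float]
    embeddings: dict[str, np.ndarray]  # sequence_id -> mean embedding
    signal_direction: np.ndarray       # the true unit vector u
    base_vector: np.ndarray            # mu
    config: SimulationConfig = field(repr=False, default=None)

    def mean_embeddings(self) -> list[MeanEmbedding]:
        return [MeanEmbedding(sid, vec) for sid, vec in self.embeddings.items()]


def _draw_ogts(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(cfg.ogt_distribution, str):
        if cfg.ogt_distribution == "uniform":
            return rng.uniform(0.0, 100.0, cfg.n_organisms)
        # bimodal: mesophile 20-40 or thermophile 60-80, equal mass
        hot = rng.random(cfg.n_organisms) < 0.5
        lows = rng.uniform(20.0, 40.0, cfg.n_organisms)
        highs = rng.uniform(60.0, 80.0, cfg.n_organisms)
        return np.where(hot, highs, lows)
    return np.asarray(cfg.ogt_distribution, dtype=float)


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate organisms, sequences and signal-bearing mean embeddings.

    Fully deterministic per seed: all draws come from one seeded generator
    in a fixed order (base vector, signal direction, OGTs, then per-protein
    lengths, sequences and noise).
    """
    rng = np.random.Generator(np.random.PCG64(cfg.seed))
    mu = rng.standard_normal(cfg.dim)
    u = rng.standard_normal(cfg.dim)
    u = u / np.linalg.norm(u)
    ogts = _draw_ogts(cfg, rng)

    width = len(str(cfg.n_organisms))
    records: list[SequenceRecord] = []
    annotations: dict[str, float] = {}
    embeddings: dict[str, np.ndarray] = {}
    lo, hi = cfg.seq_length_range
    for i, t in enumerate(ogts):
        org = f"org{i:0{width}d}"
        annotations[org] = float(t)
        for p in range(cfg.proteins_per_organism):
            seq_id = f"{org}_p{p + 1}"
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(
                STANDARD_RESIDUES[j]
                for j in rng.integers(0, len(STANDARD_RESIDUES), length)
            )
            records.append(
                SequenceRecord(id=seq_id, sequence=seq, organism_key=org)
            )
            noise = rng.normal(0.0, cfg.sigma, cfg.dim)
            embeddings[seq_id] = mu + cfg.beta * ((t - 50.0) / 50.0) * u + noise
    return SyntheticDataset(
        records=records,
        annotations=annotations,
        embeddings=embeddings,
        signal_direction=u,
        base_vector=mu,
        config=cfg,
    )


def make_cluster_structure(
    dataset: SyntheticDataset,
    n_families: int,
    copies_per_family: int,
    mutation_rate: float,
    seed: int = 0,
) -> tuple[SyntheticDataset, ClusterTable]:
    """Expand the first ``n_families`` records into point-mutated families.

    Each family keeps its founder and adds ``copies_per_family - 1`` copies
    whose residues are independently substituted at ``mutation_rate``.
    Copies inherit the founder's organism (hence OGT) and get a fresh noise
    draw around the same signal mean.  Returns the enlarged dataset plus
    the ground-truth cluster table (one cluster per family; founder is the
    representative).
    """
    if not 0.0 <= mutation_rate < 0.7:
        raise ValueError(f"mutation rate must be in [0, 0.7), got {mutation_rate}")
    if n_families > len(dataset.records):
        raise ValueError("more families requested than records available")
    if copies_per_family < 1:
        raise ValueError("copies_per_family must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    cfg = dataset.config
    founders = dataset.records[:n_families]
    records: list[SequenceRecord] = []
    embeddings: dict[str, np.ndarray] = {}
    assignments: dict[str, int] = {}
    representatives: dict[int, str] = {}
    for fam, founder in enumerate(founders):
        records.append(founder)
        embeddings[founder.id] = dataset.embeddings[founder.id]
        assignments[founder.id] = fam
        representatives[fam] = founder.id
        t = dataset.annotations[founder.organism_key]
        for c in range(1, copies_per_family):
            seq = list(founder.sequence)
            for pos in range(len(seq)):
                if rng.random() < mutation_rate:
                    seq[pos] = STANDARD_RESIDUES[rng.integers(0, len(STANDARD_RESIDUES))]
            copy_id = f"{founder.id}_c{c}"
            records.append(
                SequenceRecord(
                    id=copy_id, sequence="".join(seq), organism_key=founder.organism_key
                )
            )
            noise = rng.normal(0.0, cfg.sigma, cfg.dim)
            embeddings[copy_id] = (
                dataset.base_vector
                + cfg.beta * ((t - 50.0) / 50.0) * dataset.signal_direction
                + noise
            )
            assignments[copy_id] = fam
    table = ClusterTable(assignments=assignments, representatives=representatives)
    out = SyntheticDataset(
        records=records,
        annotations=dataset.annotations,
        embeddings=embeddings,
        signal_direction=dataset.signal_direction,
        base_vector=dataset.base_vector,
        config=cfg,
    )
    return out, table


def singleton_clusters(dataset: SyntheticDataset) -> ClusterTable:
    """Ground-truth table when every sequence is its own cluster."""
    assignments = {rec.id: i for i, rec in enumerate(dataset.records)}
    representatives = {i: rec.id for i, rec in enumerate(dataset.records)}
    return ClusterTable(assignments=assignments, representatives=representatives)


def write_fixture(
    dataset: SyntheticDataset, out_dir: str | Path, clusters: ClusterTable | None = None
) -> dict[str, Path]:
    """Write FASTA + annotation TSV + embedding cache + cluster table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "sequences.fasta",
        "annotations": out / "annotations.tsv",
        "embeddings": out / "embeddings.npz",
        "clstr": out / "clusters.clstr",
    }
    write_fasta(dataset.records, paths["fasta"])
    write_annotations(dataset.annotations, paths["annotations"])
    cache = EmbeddingCache(fingerprint=_fixture_fingerprint(dataset.config))
    for sid, vec in dataset.embeddings.items():
        cache.put(MeanEmbedding(sid, vec))
    cache.save(paths["embeddings"])
    if clusters is None:
        clusters = singleton_clusters(dataset)
    write_clstr(clusters, paths["clstr"])
    return paths


def _fixture_fingerprint(cfg: SimulationConfig) -> str:
    return (
        f"mock-signal:d{cfg.dim}:b{cfg.beta:g}:s{cfg.sigma:g}:seed{cfg.seed}"
    )


class SignalEmbedder:
    """Embedder whose output carries the simulated OGT signal.

    Residue matrices are the signal mean tiled over sequence length (so
    mean pooling recovers the stored mean embedding exactly); requires the
    organism annotation map used at simulation time.
    """

    key = "mock-signal"

    def __init__(self, dataset: SyntheticDataset):
        self._dataset = dataset

    def fingerprint(self) -> str:
        return _fixture_fingerprint(self._dataset.config)

    def embed_mean(self, record: SequenceRecord) -> MeanEmbedding:
        return MeanEmbedding(record.id, self._dataset.embeddings[record.id])

    def embed_residues(self, record: SequenceRecord) -> ResidueEmbedding:
        vec = self._dataset.embeddings[record.id]
        return ResidueEmbedding(
            sequence_id=record.id,
            matrix=np.tile(vec, (len(record.sequence), 1)),
        )
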