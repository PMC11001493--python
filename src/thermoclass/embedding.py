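"""Embedder contract, pooling operators, mock embedders and a cache.

An embedder maps a sequence record to a per-residue matrix (L x D); the
classifier consumes the column-wise mean (the "mean embedding").  Pooling
over sliding windows of size k yields per-segment embeddings, one per full
window (stride 1, no partial windows at the edges).

The deterministic hash embedder stands in for a pretrained protein language
model during development and testing; the ``plm`` adapter slot isolates a
real encoder behind the same contract.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import SequenceRecord

__all__ = [
    "ResidueEmbedding",
    "MeanEmbedding",
    "mean_pool",
    "segment_pool",
    "HashEmbedder",
    "hash_embed",
    "plm_embed",
    "PLMUnavailableError",
    "EmbeddingCache",
    "get_embedder",
]

DEFAULT_DIM = 1024


@dataclass
class ResidueEmbedding:
    """Per-residue embedding matrix for one sequence (rows = residues)."""

    sequence_id: str
    matrix: np.ndarray  # shape (L, D)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 1:
            raise ValueError("residue embedding must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"non-finite entries in embedding of {self.sequence_id!r}")


@dataclass
class MeanEmbedding:
    """Column-wise mean of a residue embedding matrix."""

    sequence_id: str
    vector: np.ndarray  # shape (D,)

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if self.vector.ndim != 1:
            raise ValueError("mean embedding must be a 1-D vector")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError(f"non-finite entries in embedding of {self.sequence_id!r}")


def mean_pool(residue: ResidueEmbedding) -> MeanEmbedding:
    """Arithmetic mean over residues: vector[d] = (1/L) sum_i matrix[i, d]."""
    return MeanEmbedding(
        sequence_id=residue.sequence_id, vector=residue.matrix.mean(axis=0)
    )


def segment_pool(residue: ResidueEmbedding, k: int) -> list[MeanEmbedding]:
    """Mean embeddings of all L-k+1 sliding windows of size k (stride 1).

    Window i (1-based) averages rows i..i+k-1.  Only full windows are
    produced; k = L collapses to :func:`mean_pool`, k = 1 returns the rows.
    """
    L = residue.matrix.shape[0]
    if k < 1:
        raise ValueError(f"window size k must be >= 1, got {k}")
    if k > L:
        raise ValueError(f"window size k={k} exceeds sequence length L={L}")
    return [
        MeanEmbedding(
            sequence_id=residue.sequence_id,
            vector=residue.matrix[i : i + k].mean(axis=0),
        )
        for i in range(L - k + 1)
    ]


class HashEmbedder:
    """Deterministic mock embedder.

    Row i of the output is a pseudo-random standard-normal vector seeded by
    (residue identity, position, seed): a pure function of the inputs, with
    single-residue locality — editing one residue changes only its own row.
    """

    key = "mock-hash"

    def __init__(self, dim: int = DEFAULT_DIM, seed: int = 0) -> None:
        if dim < 1:
            raise ValueError("embedding dimension must be >= 1")
        self.dim = int(dim)
        self.seed = int(seed)
        self._row_cache: dict[tuple[str, int], np.ndarray] = {}

    def fingerprint(self) -> str:
        return f"mock-hash:d{self.dim}:s{self.seed}"

    def _row(self, aa: str, position: int) -> np.ndarray:
        cache_key = (aa, position)
        row = self._row_cache.get(cache_key)
        if row is None:
            ss = np.random.SeedSequence([self.seed, position, ord(aa)])
            row = np.random.Generator(np.random.PCG64(ss)).standard_normal(self.dim)
            self._row_cache[cache_key] = row
        return row

    def embed_residues(self, record: SequenceRecord) -> ResidueEmbedding:
        matrix = np.vstack(
            [self._row(aa, i) for i, aa in enumerate(record.sequence)]
        )
        return ResidueEmbedding(sequence_id=record.id, matrix=matrix)

    def embed_mean(self, record: SequenceRecord) -> MeanEmbedding:
        return mean_pool(self.embed_residues(record))


def hash_embed(record: SequenceRecord, D: int = DEFAULT_DIM, seed: int = 0) -> ResidueEmbedding:
    """Functional form of :class:`HashEmbedder`."""
    return HashEmbedder(dim=D, seed=seed).embed_residues(record)


class PLMUnavailableError(RuntimeError):
    pass


def plm_embed(record: SequenceRecord) -> ResidueEmbedding:
    """Adapter to a real pretrained protein language model encoder.

    Requires ``torch`` and ``transformers`` with a local ProtT5-class model;
    when they are absent the toolkit keeps working through the mock
    embedders, so this adapter only ever raises or delegates.
    """
    try:
        import torch  # noqa: F401
        from transformers import T5EncoderModel, T5Tokenizer  # noqa: F401
    except ImportError as exc:
        raise PLMUnavailableError(
            "no protein language model backend available (torch/transformers "
            "not installed); use the 'mock-hash' embedder for offline work"
        ) from exc
    tokenizer = T5Tokenizer.from_pretrained("Rostlab/prot_t5_xl_half_uniref50-enc")
    model = T5EncoderModel.from_pretrained("Rostlab/prot_t5_xl_half_uniref50-enc")
    spaced = " ".join(record.sequence)
    inputs = tokenizer(spaced, return_tensors="pt")
    with torch.no_grad():
        hidden = model(**inputs).last_hidden_state[0, : len(record.sequence)]
    return ResidueEmbedding(sequence_id=record.id, matrix=hidden.numpy().astype(np.float64))


class EmbeddingCache:
    """Content-addressed store of mean embeddings keyed by sequence id.

    Backed by an ``.npz`` of named arrays plus a JSON sidecar holding the
    embedder fingerprint; loading under a different fingerprint fails, so a
    stale cache can never be silently reused.
    """

    def __init__(self, fingerprint: str, vectors: dict[str, np.ndarray] | None = None):
        self.fingerprint = fingerprint
        self.vectors: dict[str, np.ndarray] = dict(vectors or {})

    def put(self, emb: MeanEmbedding) -> None:
        self.vectors[emb.sequence_id] = np.asarray(emb.vector, dtype=np.float64)

    def get(self, sequence_id: str) -> MeanEmbedding:
        return MeanEmbedding(sequence_id=sequence_id, vector=self.vectors[sequence_id])

    def __contains__(self, sequence_id: str) -> bool:
        return sequence_id in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **self.vectors)
        sidecar = path.with_suffix(path.suffix + ".json")
        digest = hashlib.sha256(self.fingerprint.encode()).hexdigest()
        with sidecar.open("w") as fh:
            json.dump({"fingerprint": self.fingerprint, "digest": digest}, fh)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path, expected_fingerprint: str | None = None) -> "EmbeddingCache":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        with sidecar.open() as fh:
            meta = json.load(fh)
        fingerprint = meta["fingerprint"]
        if hashlib.sha256(fingerprint.encode()).hexdigest() != meta["digest"]:
            raise ValueError(f"embedding cache sidecar {sidecar} is corrupted")
        if expected_fingerprint is not None and fingerprint != expected_fingerprint:
            raise ValueError(
                f"embedding cache fingerprint {fingerprint!r} does not match "
                f"expected {expected_fingerprint!r}"
            )
        with np.load(path) as npz:
            vectors = {k: npz[k] for k in npz.files}
        return cls(fingerprint=fingerprint, vectors=vectors)


def get_embedder(key: str, dim: int = DEFAULT_DIM, seed: int = 0):
    """Look up an embedder by config key: ``mock-hash`` or ``plm``.

    The OGT-signal embedder lives in :mod:`thermoclass.simulate` because it
    needs organism annotations; it satisfies the same contract.
    """
    if key == "mock-hash":
        return HashEmbedder(dim=dim, seed=seed)
    if key == "plm":
        class _PLMAdapter:
            key = "plm"

            def fingerprint(self) -> str:
                return "plm:prot-t5-xl"

            def embed_residues(self, record: SequenceRecord) -> ResidueEmbedding:
                return plm_embed(record)

            def embed_mean(self, record: SequenceRecord) -> MeanEmbedding:
                return mean_pool(plm_embed(record))

        return _PLMAdapter()
    raise KeyError(f"unknown embedder key {key!r} (expected 'mock-hash' or 'plm')")
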