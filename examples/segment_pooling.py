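"""Pooling per-residue embeddings: global mean and sliding windows.

A protein-language-model embedder yields one vector per residue (an L x D
matrix).  The classifier consumes the column-wise mean; per-segment
predictions instead average each length-k sliding window, giving one
prediction per window.  This example uses the deterministic hash embedder,
so it runs without any pretrained model.
"""

import numpy as np

from thermoclass import HashEmbedder, SequenceRecord, mean_pool, segment_pool

record = SequenceRecord(id="demo", sequence="MKVLAWTFEHGIKDSPQNRYC" * 4)  # L = 84
embedder = HashEmbedder(dim=64, seed=0)
residues = embedder.embed_residues(record)
print(f"sequence length L = {residues.matrix.shape[0]}, "
      f"embedding dim D = {residues.matrix.shape[1]}")

mean = mean_pool(residues)
print(f"mean embedding: first 4 of {mean.vector.size} features -> "
      f"{np.round(mean.vector[:4], 3)}")

k = 41
segments = segment_pool(residues, k)
print(f"\nper-segment pooling with window k={k}: {len(segments)} windows "
      f"(L - k + 1 = {residues.matrix.shape[0] - k + 1})")
print(f"window 1 covers residues 1..{k}; last window covers "
      f"{len(segments)}..{residues.matrix.shape[0]}")

# identities that pin the semantics down
(whole,) = segment_pool(residues, residues.matrix.shape[0])
assert np.array_equal(whole.vector, mean.vector)
assert np.array_equal(segment_pool(residues, 1)[0].vector, residues.matrix[0])
print("\nchecks: k=L window equals the global mean; k=1 windows are the rows.")
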