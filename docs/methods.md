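# Methods

## Model and assumptions

The predictor is a panel of independent binary classifiers, one per
temperature threshold T ∈ {40, 45, 50, 55, 60, 65} °C (extended mode adds
70, 75, 80 °C).  Each answers "stable at ≥ T °C?" from the mean of a
protein's per-residue embedding matrix.  The key data assumption is that
an organism's optimal growth temperature (OGT) is a *lower bound* on the
melting temperature of its proteins: labels are y = 1(OGT ≥ T), with the
boundary OGT = T counted as class 1, consistent with lower-bound
semantics.  Because a protein from a 45 °C organism may or may not be
stable at 60 °C, single thresholds are not interchangeable and regression
on OGT would conflate the bound with the quantity of interest; the
threshold ladder is the honest formulation.

Labels derived from one scalar OGT are monotone across thresholds by
construction.  Trained classifiers, however, are independent, so their
call vectors can be non-monotone; the inference layer makes that
observable rather than hiding it (see below).

## Classifier and training

Architecture: D → 256 → 128 → 1 fully connected, ReLU after each hidden
layer, logistic output.  Training: mini-batches of 24 sampled *with
replacement* under per-example weights 1/(count of its class) — expected
batch composition is 1:1 regardless of raw imbalance — Adam with learning
rate 10⁻⁴ and weight decay 10⁻⁴ (L2 added to gradients), binary
cross-entropy computed from logits (softplus form) for numerical
stability.  One epoch is ⌈N/24⌉ batches.  After each epoch the model is
scored on the full, unweighted validation set and the snapshot with the
highest validation MCC is kept (earliest epoch on ties); default budget is
30 epochs with no other early stopping.  Validation MCC is deliberately
computed without resampling: a metric under a class-rebalancing sampler
estimates a different population than the one reported at test time.

The network, backpropagation and Adam are implemented directly in numpy
with one explicitly seeded PCG64 generator per run, which makes training
bit-reproducible on a single thread — a property the test suite asserts
file-by-file across full pipeline runs.  Weight initialisation is the
uniform fan-in scheme U(±1/√fan_in) for weights and biases, recorded in
each checkpoint's metadata.

Ensembles: five members per threshold differing only in training seed;
the ensemble probability is the arithmetic mean of member probabilities.
Member seeds derive deterministically from the base seed and the
threshold index, and stay below 2³¹.

MCC uses the convention MCC = 0 whenever a confusion-matrix margin is
zero (routinely needed in early epochs).  ROC AUC is the rank statistic
(ties count ½ — exact under ties); PR AUC is step-wise summation over
descending score cut-points with tied scores grouped (the
average-precision estimator), not trapezoidal — the two differ, so the
choice is stated.  PCA for embedding QC delegates to scikit-learn.

## Dataset construction

Splits operate on whole identity clusters: cluster ids are shuffled under
the split seed and each cluster is assigned greedily to the subset with
the largest remaining deficit against its target *sequence* count
(targets default to 70/15/15; deficit ties resolve train > validation >
test).  Sequence-count granularity was chosen over cluster-count because
subset sizes are naturally quoted in sequences.  With many small clusters
realized fractions converge to the targets (±2% at 1000 singletons,
asserted); a single dominant cluster is kept atomic and triggers a
warning instead of being split.  CD-HIT `.clstr` files are parsed
directly; when no external clustering is available, a greedy stand-in
clusters by ungapped k-mer containment (k = 5, identity = shared-5-mer
fraction of the shorter sequence, representatives visited in decreasing
length order).  This is not a replacement for alignment-based identity —
it exists so the pipeline is testable end-to-end offline, and at 10%
point mutation it recovers ≥ 95% of ground-truth co-memberships on the
synthetic families.

Balanced evaluation subsets (n/2 per class, without replacement,
seed-deterministic) support imbalance-free comparisons; an optional
maximum-length filter (e.g. 1022 residues for length-limited encoders) is
off by default.

## Multi-threshold inference

The n thresholds tile the line into n+1 half-open ranges (−∞, T₁),
[T₁, T₂), …, [Tₙ, ∞), printed as `<40`, `[50,55)`, `65+`.  The left-hand
label is the range opened by the last positive call of the *leading* run
of 1s; the right-hand label is the range opened by the highest positive
call anywhere; all-negative vectors map to the first range under both
rules.  The leading-run reading of the left-hand rule is the only
internally consistent one: if the left scan instead took the last 1
anywhere, the two labels could never differ, and conflicting classifier
outputs are precisely what the clash flag must surface.  For monotone
vectors the labels coincide and name the highest range still predicted
stable; exactly n+1 of the 2ⁿ call vectors are clash-free (exhaustively
verified for n ≤ 9).  The probability-to-call cutoff is 0.5, inclusive.

## Embedding layer

The embedder contract is sequence → L×D residue matrix; mean pooling and
sliding-window (per-segment) pooling with stride 1 and no partial edge
windows sit on top, with the identities segment(k=L) ≡ mean and
segment(k=1) ≡ identity asserted exactly.  The default window for
per-segment scans is k = 41.  Per-residue prediction feeds residue
vectors to models trained on means; its output is marked exploratory in
the file header because train and test representations differ.  The
deterministic hash embedder (a pure function of residue identity,
position and seed, unit-variance entries, single-residue locality) serves
development and testing; a real pretrained encoder plugs in behind the
same contract and the toolkit never depends on it.  Embedding caches are
fingerprinted by embedder configuration so a stale cache cannot be
silently reused.

## Synthetic data generator

The generator emulates an OGT-annotated proteome collection: organism
OGTs are drawn uniformly on 0–100 °C (or from a bimodal 20–40/60–80 °C
mesophile/thermophile mixture, or a fixed list); each protein's mean
embedding is μ + β·((t−50)/50)·u + ε with μ a seeded base vector, u a
seeded unit direction, and ε elementwise Gaussian with sd σ.  Defaults:
3000 organisms, one protein each, D = 1024 (128 in the benchmark
workflows, for speed), β = 3, σ = 1.  Sequences are random residue
strings decoupled from the embedding signal, isolating classifier tests
from embedder behaviour.  The single-direction signal is the simplest
model under which the per-threshold classifiers *should* agree, which is
what makes the held-out clash rate a meaningful statistic.  Family
structure for split testing comes from point-mutated copies of founder
sequences with a known ground-truth cluster table.

What the generator does not emulate: any real sequence–stability
coupling, compositional biases, length effects, phylogenetic correlation
between organisms, or per-residue signal localisation.  Passing tests
therefore demonstrate that the training, selection, splitting and
inference machinery recovers a planted signal under controlled
conditions — not that any particular accuracy transfers to real
proteomes.

A quantitative consequence of the generator's geometry is worth stating:
the only informative statistic is the projection onto u, with signal
slope β/50 per °C against noise sd σ.  At β = 3, σ = 1, uniform OGT, the
optimal attainable held-out MCC is ≈ 0.72–0.74 per threshold (examples
near a threshold are inherently ambiguous), and the projection–OGT
Pearson correlation is exactly √3/2 ≈ 0.866.  The trained ensembles reach
this ceiling (held-out MCC 0.72–0.78, ROC AUC ≈ 0.95, clash rate ≈ 2%),
which is the relevant evidence that the pipeline works; at σ = 0.1 the
same pipeline exceeds MCC 0.95.  The zero-signal control (β = 0) stays at
chance.

## Problem sizes and numerical choices

The benchmark workflow trains 6 thresholds × 5 members on a 70/15/15
split of 3000 examples at D = 128, 30 epochs each — about two minutes on
one CPU — and the test suite uses smaller variants of the same
conditions.  Tolerances: metric-panel agreement with brute-force oracles
to 1e-10; pooling and checkpoint round-trips exact; Monte-Carlo
assertions carry explicit ±0.02–0.05 bands.  Checkpoints are a directory
of named arrays plus a versioned JSON metadata sidecar; loading validates
shapes against the architecture descriptor and rejects unknown format
versions.  Prediction tables print probabilities to 4 decimals and a
literal `true`/`false` clash column.

## Known limitations

* The greedy k-mer clusterer under-merges distant homologues relative to
  alignment-based 30%-identity clustering; use real CD-HIT output for
  production splits.
* Per-residue predictions are exploratory by construction (representation
  mismatch with training).
* Probabilities are not calibrated; the 0.5 cutoff is a convention, and
  clashes are reported, never resolved.
* The real-encoder adapter requires torch/transformers at runtime and is
  intentionally untested beyond its error path in this repository.
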