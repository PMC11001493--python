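# thermoclass

Multi-threshold protein thermostability classification from protein
language model (pLM) embeddings.

## The problem

Screening proteins for thermostability experimentally is slow and
expensive, so sequence-based predictors matter for enzyme engineering and
for picking candidates (e.g. CRISPR effectors) that must survive elevated
temperatures.  Per-protein melting-temperature data is scarce, but the
optimal growth temperature (OGT) of an organism is a reliable *lower bound*
on the melting temperature of its proteins — and OGT annotations exist for
thousands of sequenced prokaryotes, yielding millions of weakly labelled
sequences.

Because the OGT is only a lower bound, neither regression nor multi-class
classification over temperature intervals is well posed.  The workable
formulation is a panel of binary questions: *is this protein stable at
≥ T °C?* for an ascending ladder of thresholds
T ∈ {40, 45, 50, 55, 60, 65} °C (an extended mode adds 70, 75, 80 °C).

## The method

For each threshold T, sequences are labelled y = 1(OGT ≥ T) and a small
multilayer perceptron (D → 256 → 128 → 1, ReLU hidden activations,
logistic output) is trained on **mean pLM embeddings** — the column-wise
average of the per-residue embedding matrix (D = 1024 for ProtT5-class
encoders).  Training uses mini-batches of 24 drawn by a class-weighted
random sampler (weight 1/class-count, so batches are balanced in
expectation), Adam (lr = 10⁻⁴, weight decay = 10⁻⁴), binary cross-entropy,
and per-epoch model selection on the full validation set by Matthews
correlation coefficient (MCC).  Five seeds per threshold form an ensemble
whose prediction is the mean member probability.

Two structural safeguards come with the data construction:

* **Cluster-disjoint splits.** Sequences are clustered at 30% identity
  (CD-HIT `.clstr` files are parsed; a built-in greedy k-mer clusterer is
  the self-contained fallback) and whole clusters are assigned to
  train/validation/test, so no homologue of a training sequence ever lands
  in the test set.
* **Consistency labels.** The ordered per-threshold calls are condensed
  into a *left-hand* label (leading run of positives) and a *right-hand*
  label (highest positive anywhere).  They coincide exactly when the call
  vector is monotone; a disagreement is flagged as a **clash** — of the 2⁶
  possible call vectors only 7 (the monotone ones) are clash-free.

Everything runs offline: a deterministic hash embedder and a synthetic-data
generator (OGT-annotated organisms with a controllable linear
embedding-space signal) stand in for the pretrained encoder, which plugs in
behind the same embedder contract when available.

## Worked example

`examples/train_and_evaluate.py` runs the whole pipeline on a small
synthetic proteome (600 organisms, 32-dim embeddings, two-member
ensembles):

```
split sizes: train 420, validation 90, test 90 (whole clusters per subset)

threshold  held-out MCC  ROC AUC
    40 C       0.931      0.997
    45 C       0.956      0.998
    50 C       0.978      1.000
    55 C       0.870      0.993
    60 C       0.842      0.987
    65 C       0.862      0.995

clash rate on held-out profiles: 1.1%
```

MCC near 1 means each ensemble recovers the planted OGT signal at its
threshold; the low clash rate means the six independently trained
classifiers almost always yield mutually consistent temperature ranges.
`examples/label_logic.py` and `examples/segment_pooling.py` demonstrate the
inference layer and the per-segment (sliding-window) pooling used for
intra-sequence scans.

## Command line

The same workflow is scriptable from a shell:

```sh
thermoclass simulate --out fixture/ --n-organisms 600 --dim 32 --seed 42
thermoclass build-dataset --fasta fixture/sequences.fasta \
    --annotations fixture/annotations.tsv --embeddings fixture/embeddings.npz \
    --clstr fixture/clusters.clstr --out manifest.tsv
thermoclass train --manifest manifest.tsv --embeddings fixture/embeddings.npz \
    --out checkpoints/ --seed 42
thermoclass predict --fasta fixture/sequences.fasta --checkpoints checkpoints/ \
    --cache fixture/embeddings.npz --out predictions.tsv
thermoclass evaluate --manifest manifest.tsv --embeddings fixture/embeddings.npz \
    --checkpoints checkpoints/ --out metrics.tsv
```

`predict` writes one row per sequence: a probability and a binary call per
threshold, the left/right temperature-range labels and the clash flag
(`--per-segment k` instead yields one row per length-k window).

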