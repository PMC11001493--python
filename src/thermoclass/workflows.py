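"""End-to-end experiment workflows on synthetic data.

These functions wire the full pipeline — simulate, split, train per-threshold
ensembles, predict and evaluate — into single deterministic calls, used by
the examples and by the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classifier import (
    TrainConfig,
    ensemble_predict_batch,
    train_ensemble,
)
from .dataset import LabeledExample, assign_threshold_labels, cluster_disjoint_split
from .metrics import MetricsReport, confusion, mcc, metrics_report
from .simulate import SimulationConfig, simulate_dataset, singleton_clusters
from .thermo_labels import DEFAULT_THRESHOLDS, binarize, left_right_labels

__all__ = ["BenchmarkResult", "run_synthetic_benchmark", "imbalance_comparison"]


@dataclass
class BenchmarkResult:
    thresholds: list[float]
    heldout_mcc: dict[float, float]
    heldout_reports: dict[float, MetricsReport]
    clash_rate: float                      # fraction of held-out profiles with a clash
    n_train: int
    n_validation: int
    n_test: int
    validation_mcc: dict[float, list[float]] = field(default_factory=dict)


def _labelled_examples(dataset, thresholds) -> list[LabeledExample]:
    return [
        LabeledExample(
            sequence_id=rec.id,
            embedding=dataset.embeddings[rec.id],
            labels=assign_threshold_labels(
                dataset.annotations[rec.organism_key], thresholds
            ),
            growth_temperature=dataset.annotations[rec.organism_key],
        )
        for rec in dataset.records
    ]


def run_synthetic_benchmark(
    sim: SimulationConfig,
    thresholds=DEFAULT_THRESHOLDS,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    members: int = 5,
    train_cfg: TrainConfig | None = None,
    split_seed: int | None = None,
) -> BenchmarkResult:
    """Simulate, split cluster-disjointly, train one ensemble per threshold,
    and score everything on the held-out test subset.

    Each synthetic sequence is its own cluster (no engineered families), so
    the split granularity equals the sequence granularity.  Returns held-out
    MCC and the full metric panel per threshold plus the clash rate of the
    assembled multi-threshold profiles.
    """
    thresholds = [float(t) for t in thresholds]
    train_cfg = train_cfg or TrainConfig(seed=sim.seed)
    dataset = simulate_dataset(sim)
    examples = _labelled_examples(dataset, thresholds)
    split = cluster_disjoint_split(
        examples,
        singleton_clusters(dataset),
        fractions,
        seed=sim.seed if split_seed is None else split_seed,
    )

    X_test = np.vstack([ex.embedding for ex in split.test])
    prob_matrix = np.empty((len(split.test), len(thresholds)))
    heldout_mcc: dict[float, float] = {}
    heldout_reports: dict[float, MetricsReport] = {}
    val_mcc: dict[float, list[float]] = {}
    for ti, t in enumerate(thresholds):
        ensemble, trained = train_ensemble(
            split.train,
            split.validation,
            t,
            cfg=train_cfg,
            n_members=members,
            threshold_index=ti,
        )
        val_mcc[t] = [tc.validation_mcc for tc in trained]
        scores = ensemble_predict_batch(ensemble, X_test)
        prob_matrix[:, ti] = scores
        y = [ex.labels[t] for ex in split.test]
        calls = [int(s >= 0.5) for s in scores]
        heldout_mcc[t] = mcc(confusion(y, calls))
        heldout_reports[t] = metrics_report(y, calls, scores)

    clashes = 0
    for row in prob_matrix:
        calls = binarize(list(row))
        _, _, clash = left_right_labels(calls, thresholds)
        clashes += clash
    return BenchmarkResult(
        thresholds=thresholds,
        heldout_mcc=heldout_mcc,
        heldout_reports=heldout_reports,
        clash_rate=clashes / len(split.test),
        n_train=len(split.train),
        n_validation=len(split.validation),
        n_test=len(split.test),
        validation_mcc=val_mcc,
    )


def imbalance_comparison(
    seed: int,
    n_major: int = 900,
    n_minor: int = 100,
    beta: float = 2.0,
    sigma: float = 1.0,
    dim: int = 128,
    threshold: float = 50.0,
    max_epochs: int = 30,
) -> tuple[float, float]:
    """Held-out MCC with vs without the class-balancing sampler.

    Organisms are drawn 900:100 from mesophile (20-45 C) and thermophile
    (55-80 C) OGT ranges, labelled at the 50 C threshold, then one
    classifier is trained per sampling regime on identical data and seeds.
    Returns (mcc_weighted, mcc_unweighted) on the test subset.
    """
    from .classifier import train_classifier

    rng = np.random.Generator(np.random.PCG64(seed))
    ogts = np.concatenate([
        rng.uniform(20.0, 45.0, n_major),
        rng.uniform(55.0, 80.0, n_minor),
    ])
    rng.shuffle(ogts)
    sim = SimulationConfig(
        n_organisms=n_major + n_minor,
        ogt_distribution=list(ogts),
        dim=dim,
        beta=beta,
        sigma=sigma,
        seed=seed,
    )
    dataset = simulate_dataset(sim)
    examples = _labelled_examples(dataset, [threshold])
    split = cluster_disjoint_split(
        examples, singleton_clusters(dataset), (0.70, 0.15, 0.15), seed=seed
    )
    X = np.vstack([ex.embedding for ex in split.test])
    y = [ex.labels[threshold] for ex in split.test]
    out = []
    for weighted in (True, False):
        cfg = TrainConfig(seed=seed, max_epochs=max_epochs, weighted_sampling=weighted)
        tc = train_classifier(split.train, split.validation, threshold, cfg=cfg)
        calls = (tc.model.predict_proba(X) >= 0.5).astype(int)
        out.append(mcc(confusion(y, calls)))
    return out[0], out[1]
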