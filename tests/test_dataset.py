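import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermoclass.dataset import (
    LabeledExample,
    OrganismAnnotation,
    assign_threshold_labels,
    balanced_subsample,
    cluster_disjoint_split,
    greedy_cluster,
    kmer_identity,
    read_split_manifest,
    write_split_manifest,
)
from thermoclass.io_formats import ClusterTable, SequenceRecord

SIX = [40.0, 45.0, 50.0, 55.0, 60.0, 65.0]


def _example(i, ogt, cluster=None, dim=4):
    return LabeledExample(
        sequence_id=f"s{i}",
        embedding=np.full(dim, float(i)),
        labels=assign_threshold_labels(ogt, SIX),
        growth_temperature=ogt,
    )


# ------------------------------------------------------------------ labels

class TestThresholdLabels:
    @pytest.mark.parametrize(
        "ogt,expected",
        [
            (65.0, [1, 1, 1, 1, 1, 1]),
            (52.0, [1, 1, 1, 0, 0, 0]),
            (39.999, [0, 0, 0, 0, 0, 0]),
            (40.0, [1, 0, 0, 0, 0, 0]),  # boundary: OGT == threshold is class 1
        ],
    )
    def test_rule_application(self, ogt, expected):
        labels = assign_threshold_labels(ogt, SIX)
        assert [labels[t] for t in SIX] == expected

    def test_non_finite_temperature_rejected(self):
        with pytest.raises(ValueError):
            assign_threshold_labels(float("nan"), SIX)

    @given(st.floats(min_value=-20, max_value=150))
    @settings(max_examples=200, deadline=None)
    def test_monotonicity_over_random_ogts(self, ogt):
        labels = assign_threshold_labels(ogt, SIX)
        seq = [labels[t] for t in SIX]
        assert all(a >= b for a, b in zip(seq, seq[1:]))

    def test_unsorted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="ascending"):
            assign_threshold_labels(50.0, [45.0, 40.0])


def test_organism_annotation_plausibility_bounds():
    OrganismAnnotation("ok", 37.0)
    with pytest.raises(ValueError, match="plausible"):
        OrganismAnnotation("toohot", 200.0)
    with pytest.raises(ValueError):
        OrganismAnnotation("nan", float("nan"))


# ------------------------------------------------------------------- splits

def _singleton_table(n):
    return ClusterTable(
        assignments={f"s{i}": i for i in range(n)},
        representatives={i: f"s{i}" for i in range(n)},
    )


class TestClusterDisjointSplit:
    def test_ten_singletons(self):
        examples = [_example(i, 30.0 + i) for i in range(10)]
        split = cluster_disjoint_split(examples, _singleton_table(10), (0.8, 0.1, 0.1), seed=1)
        assert len(split.train) == 8 and len(split.validation) == 1 and len(split.test) == 1
        ids = {e.sequence_id for s in (split.train, split.validation, split.test) for e in s}
        assert len(ids) == 10

    def test_single_giant_cluster_is_atomic_and_warns(self):
        examples = [_example(i, 30.0) for i in range(100)]
        table = ClusterTable(
            assignments={f"s{i}": 0 for i in range(100)}, representatives={0: "s0"}
        )
        with pytest.warns(UserWarning, match="atomicity"):
            split = cluster_disjoint_split(examples, table, seed=0)
        sizes = sorted([len(split.train), len(split.validation), len(split.test)])
        assert sizes == [0, 0, 100]

    def test_missing_example_named_in_error(self):
        examples = [_example(0, 30.0)]
        table = _singleton_table(0)
        table.assignments = {}
        with pytest.raises(ValueError, match="s0"):
            cluster_disjoint_split(examples, table)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cluster_disjoint_split([_example(0, 30.0)], _singleton_table(1), (0.5, 0.2, 0.2))

    def test_determinism_same_seed_same_split(self):
        examples = [_example(i, 20.0 + i % 60) for i in range(50)]
        table = _singleton_table(50)
        a = cluster_disjoint_split(examples, table, seed=9)
        b = cluster_disjoint_split(examples, table, seed=9)
        assert [e.sequence_id for e in a.train] == [e.sequence_id for e in b.train]
        assert a.cluster_ids == b.cluster_ids

    def test_disjointness_and_conservation_over_random_instances(self, rng):
        """Whole clusters never span subsets; example multiset is conserved."""
        for trial in range(100):
            n_clusters = int(rng.integers(3, 20))
            sizes = rng.integers(1, 8, size=n_clusters)
            assignments, reps = {}, {}
            examples = []
            idx = 0
            for cid, size in enumerate(sizes):
                for j in range(size):
                    sid = f"s{idx}"
                    assignments[sid] = cid
                    examples.append(_example(idx, float(rng.uniform(0, 100))))
                    if j == 0:
                        reps[cid] = sid
                    idx += 1
            table = ClusterTable(assignments=assignments, representatives=reps)
            import warnings as w
            with w.catch_warnings():
                w.simplefilter("ignore")
                split = cluster_disjoint_split(examples, table, seed=trial)
            cids = split.cluster_ids
            assert not (cids["train"] & cids["validation"])
            assert not (cids["train"] & cids["test"])
            assert not (cids["validation"] & cids["test"])
            assert cids["train"] | cids["validation"] | cids["test"] == set(range(n_clusters))
            all_ids = sorted(
                e.sequence_id for s in (split.train, split.validation, split.test) for e in s
            )
            assert all_ids == sorted(e.sequence_id for e in examples)

    def test_fractions_converge_with_many_singletons(self):
        examples = [_example(i, 20.0 + (i % 80)) for i in range(1000)]
        split = cluster_disjoint_split(examples, _singleton_table(1000), (0.7, 0.15, 0.15), seed=4)
        assert abs(len(split.train) / 1000 - 0.70) <= 0.02
        assert abs(len(split.validation) / 1000 - 0.15) <= 0.02
        assert abs(len(split.test) / 1000 - 0.15) <= 0.02


# -------------------------------------------------------- balanced subsample

class TestBalancedSubsample:
    def _pool(self, n_pos, n_neg):
        pos = [_example(i, 70.0) for i in range(n_pos)]
        neg = [_example(n_pos + i, 20.0) for i in range(n_neg)]
        return pos + neg

    def test_exact_parity_at_2000(self):
        pool = self._pool(1500, 1500)
        sub = balanced_subsample(pool, 65.0, 2000, seed=0)
        labels = [e.labels[65.0] for e in sub]
        assert labels.count(1) == 1000 and labels.count(0) == 1000

    def test_insufficient_class_reports_counts(self):
        pool = self._pool(3, 100)
        with pytest.raises(ValueError, match="3 positives"):
            balanced_subsample(pool, 65.0, 10)

    def test_seed_determinism(self):
        pool = self._pool(50, 50)
        a = balanced_subsample(pool, 65.0, 40, seed=7)
        b = balanced_subsample(pool, 65.0, 40, seed=7)
        assert [e.sequence_id for e in a] == [e.sequence_id for e in b]

    def test_no_replacement(self):
        pool = self._pool(30, 30)
        sub = balanced_subsample(pool, 65.0, 60, seed=1)
        ids = [e.sequence_id for e in sub]
        assert len(set(ids)) == len(ids)

    def test_odd_n_rejected(self):
        with pytest.raises(ValueError, match="even"):
            balanced_subsample(self._pool(5, 5), 65.0, 7)


# ----------------------------------------------------------- greedy cluster

def _random_protein(rng, length):
    residues = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(residues[i] for i in rng.integers(0, 20, length))


class TestGreedyCluster:
    def test_identical_sequences_co_cluster(self, rng):
        seq = _random_protein(rng, 60)
        records = [SequenceRecord(id=f"s{i}", sequence=seq) for i in range(3)]
        table = greedy_cluster(records, 0.3)
        assert len(set(table.assignments.values())) == 1

    def test_disjoint_kmers_all_singletons(self):
        records = [
            SequenceRecord(id="a", sequence="AAAAAAAAAA"),
            SequenceRecord(id="b", sequence="CCCCCCCCCC"),
            SequenceRecord(id="c", sequence="DDDDDDDDDD"),
        ]
        table = greedy_cluster(records, 0.3)
        assert table.n_clusters == 3

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            greedy_cluster([], 0.3)

    def test_copies_co_cluster_with_originals(self, rng):
        """Exact copies land with their originals; cross-check against a
        brute-force pairwise k-mer identity oracle."""
        originals = [
            SequenceRecord(id=f"o{i}", sequence=_random_protein(rng, 80))
            for i in range(20)
        ]
        copies = [
            SequenceRecord(id=f"c{i}", sequence=originals[i].sequence)
            for i in range(5)
        ]
        table = greedy_cluster(originals + copies, 0.3)
        for i in range(5):
            assert table.assignments[f"c{i}"] == table.assignments[f"o{i}"]
        # oracle: any pair with identity >= 0.3 shares a cluster representative path
        for i in range(5):
            assert kmer_identity(copies[i].sequence, originals[i].sequence) == 1.0

    def test_each_cluster_has_one_representative(self, rng):
        records = [
            SequenceRecord(id=f"r{i}", sequence=_random_protein(rng, 50))
            for i in range(15)
        ]
        table = greedy_cluster(records, 0.3)
        assert set(table.representatives) == set(table.assignments.values())


# ------------------------------------------------------------ split manifest

def test_split_manifest_roundtrip(tmp_path):
    examples = [_example(i, 20.0 + i * 7 % 70) for i in range(12)]
    table = _singleton_table(12)
    split = cluster_disjoint_split(examples, table, seed=2)
    path = tmp_path / "manifest.tsv"
    write_split_manifest(split, table, SIX, path)
    rows = read_split_manifest(path)
    assert len(rows) == 12
    for ex in examples:
        row = rows[ex.sequence_id]
        assert row["labels"] == ex.labels
        assert row["growth_temperature"] == ex.growth_temperature
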