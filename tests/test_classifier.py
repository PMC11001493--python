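import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from thermoclass.classifier import (
    ClassifierSpec,
    MLPClassifier,
    ThresholdEnsemble,
    TrainConfig,
    ensemble_predict,
    sampler_weights,
    train_classifier,
)
from thermoclass.simulate import SimulationConfig, simulate_dataset
from tests.conftest import examples_from


def _zeroed(spec):
    model = MLPClassifier(spec, seed=0)
    model.weights = [np.zeros_like(w) for w in model.weights]
    model.biases = [np.zeros_like(b) for b in model.biases]
    return model


def _rigged_constant(prob, input_dim=4):
    """Model that outputs a fixed probability regardless of input."""
    model = _zeroed(ClassifierSpec(input_dim=input_dim, hidden=(2, 2)))
    model.biases[-1][:] = math.log(prob / (1 - prob))
    return model


class TestForward:
    def test_all_zero_weights_give_half(self):
        model = _zeroed(ClassifierSpec(input_dim=8, hidden=(4, 2)))
        assert model.forward(np.ones(8)) == 0.5

    def test_matches_pencil_and_paper_pass(self):
        """Hand-set weights on a 2 -> 2 -> 2 -> 1 net vs explicit arithmetic."""
        model = _zeroed(ClassifierSpec(input_dim=2, hidden=(2, 2)))
        model.weights[0] = np.array([[1.0, -1.0], [0.5, 2.0]])
        model.biases[0] = np.array([0.1, -0.2])
        model.weights[1] = np.array([[2.0, 0.0], [-1.0, 1.0]])
        model.biases[1] = np.array([0.0, 0.3])
        model.weights[2] = np.array([[1.5], [-0.5]])
        model.biases[2] = np.array([0.25])
        x = [1.0, 2.0]
        # layer 1
        h1 = [max(0.0, 1.0 * 1 + 0.5 * 2 + 0.1), max(0.0, -1.0 * 1 + 2.0 * 2 - 0.2)]
        # layer 2
        h2 = [max(0.0, 2.0 * h1[0] - 1.0 * h1[1]), max(0.0, 0.0 * h1[0] + 1.0 * h1[1] + 0.3)]
        z = 1.5 * h2[0] - 0.5 * h2[1] + 0.25
        expected = 1.0 / (1.0 + math.exp(-z))
        assert model.forward(np.array(x)) == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        model = _zeroed(ClassifierSpec(input_dim=8, hidden=(4, 2)))
        with pytest.raises(ValueError, match="dimension"):
            model.forward(np.ones(9))

    def test_probability_saturates_monotonically_with_logit_scale(self):
        model = _zeroed(ClassifierSpec(input_dim=2, hidden=(2, 2)))
        model.weights[0][:] = 1.0
        model.weights[1][:] = 1.0
        model.weights[2][:] = 1.0
        x = np.ones(2)
        probs = []
        for scale in (0.1, 1.0, 10.0, 100.0):
            model.biases[2][:] = 0.0
            model.weights[2] = np.full((2, 1), scale)
            probs.append(model.forward(x))
        assert probs == sorted(probs)
        assert probs[-1] > 0.999

    def test_output_in_open_unit_interval(self, rng):
        model = MLPClassifier(ClassifierSpec(input_dim=16, hidden=(8, 4)), seed=2)
        for _ in range(20):
            p = model.forward(rng.standard_normal(16))
            assert 0.0 < p < 1.0


class TestSamplerWeights:
    def test_reciprocal_class_counts(self):
        labels = [1] * 100 + [0] * 900
        w = sampler_weights(labels)
        assert w[0] / w[-1] == pytest.approx(9.0)

    def test_balanced_input_uniform(self):
        w = sampler_weights([0] * 50 + [1] * 50)
        assert np.allclose(w, w[0])

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            sampler_weights([1, 1, 1])

    def test_expected_balance_monte_carlo(self):
        labels = np.array([1] * 100 + [0] * 900)
        w = sampler_weights(labels)
        rng = np.random.default_rng(42)
        draws = rng.choice(len(labels), size=10_000, replace=True, p=w / w.sum())
        frac_pos = labels[draws].mean()
        assert abs(frac_pos - 0.5) <= 0.02


@pytest.fixture(scope="module")
def trained_t50(separable_examples):
    train, val = separable_examples[:2000], separable_examples[2000:]
    return train_classifier(train, val, 50.0, cfg=TrainConfig(seed=3))


class TestTraining:
    def test_separable_data_reaches_high_validation_mcc(self, trained_t50):
        assert trained_t50.validation_mcc >= 0.95

    def test_selection_is_a_maximum_over_epochs(self, trained_t50):
        mccs = [row["val_mcc"] for row in trained_t50.log]
        assert trained_t50.validation_mcc == max(mccs)
        assert trained_t50.validation_mcc >= mccs[0]
        # earliest epoch on ties
        assert trained_t50.selected_epoch == mccs.index(max(mccs)) + 1

    def test_loss_finite_every_epoch(self, trained_t50):
        assert all(math.isfinite(row["loss"]) for row in trained_t50.log)

    def test_zero_signal_yields_chance_level_mcc(self):
        cfg = SimulationConfig(n_organisms=900, dim=32, beta=0.0, sigma=1.0, seed=5)
        examples = examples_from(simulate_dataset(cfg))
        out = train_classifier(
            examples[:600], examples[600:], 50.0,
            cfg=TrainConfig(seed=1, max_epochs=10),
        )
        # max over 10 epochs of a noise MCC is biased up; stays near zero
        assert -0.15 <= out.validation_mcc <= 0.15

    def test_seed_determinism_bitwise(self, separable_examples):
        train, val = separable_examples[:300], separable_examples[300:500]
        cfg = TrainConfig(seed=21, max_epochs=3)
        a = train_classifier(train, val, 55.0, cfg=cfg)
        b = train_classifier(train, val, 55.0, cfg=cfg)
        assert a.selected_epoch == b.selected_epoch
        for wa, wb in zip(a.model.weights, b.model.weights):
            np.testing.assert_array_equal(wa, wb)
        for ba, bb in zip(a.model.biases, b.model.biases):
            np.testing.assert_array_equal(ba, bb)

    def test_single_class_sets_rejected(self, separable_examples):
        hot = [e for e in separable_examples if e.labels[40.0] == 1]
        with pytest.raises(ValueError, match="single class"):
            train_classifier(hot[:50], separable_examples[:50], 40.0,
                             cfg=TrainConfig(seed=0, max_epochs=1))

    def test_parameter_recovery_across_seeds(self, separable_examples):
        """Mean held-out MCC over 5 training seeds on separable data."""
        from thermoclass.metrics import confusion, mcc

        train, val, test = (
            separable_examples[:1600],
            separable_examples[1600:2000],
            separable_examples[2000:],
        )
        X = np.vstack([e.embedding for e in test])
        y = [e.labels[50.0] for e in test]
        scores = []
        for seed in range(5):
            out = train_classifier(train, val, 50.0,
                                   cfg=TrainConfig(seed=seed, max_epochs=15))
            calls = (out.model.predict_proba(X) >= 0.5).astype(int)
            scores.append(mcc(confusion(y, calls)))
        assert np.mean(scores) >= 0.9

    def test_monotone_response_in_ogt(self, trained_t50, separable_examples):
        """Mean predicted probability rises with OGT (binned Spearman)."""
        test = separable_examples[2000:]
        X = np.vstack([e.embedding for e in test])
        probs = trained_t50.model.predict_proba(X)
        ogts = np.array([e.growth_temperature for e in test])
        bins = np.linspace(0, 100, 11)
        binned = [
            probs[(ogts >= lo) & (ogts < hi)].mean()
            for lo, hi in zip(bins, bins[1:])
            if np.any((ogts >= lo) & (ogts < hi))
        ]
        rho, _ = spearmanr(range(len(binned)), binned)
        assert rho >= 0.95


class TestEnsemble:
    def test_mean_of_member_probabilities(self):
        members = [_rigged_constant(p) for p in (0.2, 0.4, 0.6, 0.8, 0.99)]
        ens = ThresholdEnsemble(threshold=50.0, members=members)
        got = ensemble_predict(ens, np.zeros(4))
        assert got == pytest.approx(np.mean([0.2, 0.4, 0.6, 0.8, 0.99]), abs=1e-9)

    def test_identical_members_equal_single(self):
        member = _rigged_constant(0.7)
        ens5 = ThresholdEnsemble(threshold=50.0, members=[member] * 5)
        assert ensemble_predict(ens5, np.zeros(4)) == pytest.approx(
            member.forward(np.zeros(4))
        )

    def test_order_invariance(self):
        members = [_rigged_constant(p) for p in (0.1, 0.5, 0.9)]
        a = ensemble_predict(ThresholdEnsemble(50.0, members), np.zeros(4))
        b = ensemble_predict(ThresholdEnsemble(50.0, members[::-1]), np.zeros(4))
        assert a == pytest.approx(b, abs=1e-12)

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            ThresholdEnsemble(threshold=50.0, members=[])
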