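"""Training contracts: corruption, balanced batching, pretraining,
fine-tuning, prediction determinism. Planted-rule performance bars live in
the acceptance suite; here the models are small and the checks structural.
"""

import numpy as np
import pytest
from scipy.stats import spearmanr

from guidenet import nets, synth
from guidenet.encoder import GUIDE_LEN
from guidenet.nets import (EnsembleModel, NetworkConfig, ParentEncoder,
                           balanced_batches, corrupt_batch, corrupt_input,
                           pretrain_parent, train_offtarget, train_ontarget)


@pytest.fixture(scope="module")
def ontarget_data():
    cfg = synth.SyntheticConfig(seed=101, n_guides=600)
    rule = synth.PlantedRule.random(101)
    return synth.ontarget_arrays(synth.gen_ontarget_set(rule, cfg))


@pytest.fixture(scope="module")
def pair_data():
    cfg = synth.SyntheticConfig(seed=102, n_pairs=3000, imbalance_ratio=50)
    return synth.gen_offtarget_set(config=cfg)


@pytest.fixture(scope="module")
def small_parent():
    X = synth.gen_unlabeled_set(640, seed=103)
    return pretrain_parent(X, NetworkConfig(seed=104, epochs=3))


@pytest.fixture(scope="module")
def small_ontarget_model(ontarget_data):
    X, y = ontarget_data
    return train_ontarget(None, X, y,
                          NetworkConfig.for_ontarget(seed=105, epochs=4,
                                                     ensemble=1))


@pytest.fixture(scope="module")
def small_pair_model(pair_data):
    ot = pair_data
    return train_offtarget(None, ot.Xg, ot.Xs, ot.detected,
                           NetworkConfig.for_offtarget(seed=106, epochs=4))


class TestCorruption:
    def test_zero_mask_probability_is_identity(self, ontarget_data):
        X, _ = ontarget_data
        out = corrupt_batch(X[:16], 0.0, 0.0, np.random.default_rng(0))
        assert np.array_equal(out, X[:16])

    def test_full_mask_preserves_one_hot(self, ontarget_data):
        X, _ = ontarget_data
        out = corrupt_batch(X[:16], 1.0, 0.1, np.random.default_rng(0))
        nuc = out[:, :, :4]
        assert np.array_equal(nuc.sum(axis=2), np.ones((16, GUIDE_LEN)))
        assert (out >= 0).all() and (out <= 1).all()

    def test_fixed_seed_reproduces_corruption(self, ontarget_data):
        X, _ = ontarget_data
        from guidenet.encoder import EncodedGuide
        g = EncodedGuide(X[0])
        config = NetworkConfig(seed=0, mask_prob=0.5, epi_noise=0.2)
        a = corrupt_input(g, config, seed=9)
        b = corrupt_input(g, config, seed=9)
        assert np.array_equal(a.values, b.values)


class TestBalancedBatches:
    def test_extreme_imbalance_exact_half_and_half(self):
        labels = np.array([1] * 4 + [0] * 1000)
        batches = list(balanced_batches(labels, 64, seed=0))
        assert len(batches) == 1000 // 32
        negatives_seen = []
        for b in batches:
            assert (labels[b] == 1).sum() == 32
            assert (labels[b] == 0).sum() == 32
            negs = b[labels[b] == 0]
            assert len(set(negs)) == 32           # majority chunk distinct
            negatives_seen += list(negs)
        assert len(set(negatives_seen)) == len(negatives_seen)  # partitioned

    def test_already_balanced_data_each_sample_once(self):
        labels = np.array([0, 1] * 96)
        seen = np.concatenate(list(balanced_batches(labels, 64, seed=1)))
        assert sorted(seen) == list(range(192))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            list(balanced_batches(np.ones(10), 4, seed=0))

    def test_odd_batch_size_rejected(self):
        with pytest.raises(ValueError):
            list(balanced_batches(np.array([0, 1]), 3, seed=0))


class TestPretraining:
    def test_reconstruction_loss_decreases(self, small_parent):
        trace = small_parent.loss_trace
        assert trace[-1] < trace[0]

    def test_same_seed_identical_loss_trace(self):
        X = synth.gen_unlabeled_set(320, seed=110)
        cfg = NetworkConfig(seed=111, epochs=2)
        a = pretrain_parent(X, cfg)
        b = pretrain_parent(X, cfg)
        assert a.loss_trace == b.loss_trace

    def test_denoising_beats_the_corruption_it_sees(self):
        # needs enough capacity/epochs to learn the corpus composition bias
        X = synth.gen_unlabeled_set(4000, seed=9)
        parent = pretrain_parent(X, NetworkConfig(seed=10, epochs=20,
                                                  mask_prob=0.2))
        rng = np.random.default_rng(114)
        corrupted = corrupt_batch(X[:300], 0.2, 0.1, rng)
        recon = nets.reconstruct(parent, corrupted)
        clean = X[:300, :, :4].argmax(2)
        agree_recon = (recon[:, :, :4].argmax(2) == clean).mean()
        agree_corrupted = (corrupted[:, :, :4].argmax(2) == clean).mean()
        assert agree_recon > agree_corrupted

    def test_too_few_inputs_rejected(self):
        with pytest.raises(ValueError):
            pretrain_parent(np.zeros((8, GUIDE_LEN, 8)),
                            NetworkConfig(seed=0, batch_size=64))


class TestOnTargetTraining:
    def test_frozen_parent_is_bit_identical_after_training(self, small_parent,
                                                           ontarget_data):
        X, y = ontarget_data
        before = [p.value.copy() for p in small_parent.net.params()]
        model = train_ontarget(small_parent, X[:300], y[:300],
                               NetworkConfig(seed=120, epochs=2, ensemble=1,
                                             finetune=False))
        inside = model.encoder.params()
        for b, p in zip(before, inside):
            assert np.array_equal(b, p.value)

    def test_finetuning_moves_the_parent_copy(self, small_parent,
                                              ontarget_data):
        X, y = ontarget_data
        model = train_ontarget(small_parent, X[:300], y[:300],
                               NetworkConfig(seed=121, epochs=2, ensemble=1,
                                             finetune=True))
        moved = any(not np.array_equal(a.value, b.value)
                    for a, b in zip(small_parent.net.params(),
                                    model.encoder.params()))
        assert moved

    def test_label_task_mismatch_rejected(self, ontarget_data):
        X, _ = ontarget_data
        with pytest.raises(ValueError, match="0/1"):
            train_ontarget(None, X[:64], np.full(64, 0.3),
                           NetworkConfig(seed=0, epochs=1, ensemble=1))

    def test_classification_scores_are_probabilities(self,
                                                     small_ontarget_model,
                                                     ontarget_data):
        X, _ = ontarget_data
        scores = small_ontarget_model.predict(X[:50])
        assert ((scores >= 0) & (scores <= 1)).all()
        out = small_ontarget_model._forward(X[:50], train=False)
        from guidenet.nn import softmax_probs
        assert np.allclose(softmax_probs(out).sum(axis=1), 1.0)

    def test_duplicate_inputs_get_identical_scores(self, small_ontarget_model,
                                                   ontarget_data):
        X, _ = ontarget_data
        dup = np.concatenate([X[:5], X[:5]])
        s = small_ontarget_model.predict(dup)
        assert np.array_equal(s[:5], s[5:])

    def test_batch_order_invariance(self, small_ontarget_model, ontarget_data):
        X, _ = ontarget_data
        perm = np.random.default_rng(1).permutation(60)
        assert np.allclose(small_ontarget_model.predict(X[:60])[perm],
                           small_ontarget_model.predict(X[:60][perm]))

    def test_shape_mismatch_rejected(self, small_ontarget_model):
        with pytest.raises(ValueError):
            small_ontarget_model.predict(np.zeros((4, 10, 8)))

    def test_regression_outputs_track_planted_labels(self):
        cfg = synth.SyntheticConfig(seed=130, n_guides=900, noise_sd=0.05)
        rule = synth.PlantedRule.random(130)
        X, y = synth.ontarget_arrays(synth.gen_ontarget_set(rule, cfg),
                                     "regression")
        m = train_ontarget(None, X[:700], y[:700],
                           NetworkConfig.for_ontarget(seed=131, epochs=15,
                                                      ensemble=1,
                                                      task="regression"))
        rho = spearmanr(m.predict(X[700:]), y[700:]).statistic
        assert rho > 0.5


class TestOffTargetTraining:
    def test_branch_encoders_differ_after_training(self, small_pair_model):
        pa = np.concatenate([p.value.ravel()
                             for p in small_pair_model.encoder_a.params()])
        pb = np.concatenate([p.value.ravel()
                             for p in small_pair_model.encoder_b.params()])
        assert not np.array_equal(pa, pb)

    def test_deterministic_repeat_predictions(self, small_pair_model,
                                              pair_data):
        ot = pair_data
        a = small_pair_model.predict(ot.Xg[:40], ot.Xs[:40])
        b = small_pair_model.predict(ot.Xg[:40], ot.Xs[:40])
        assert np.array_equal(a, b)

    def test_training_is_deterministic_given_config_seed(self, pair_data):
        ot = pair_data
        cfg = NetworkConfig.for_offtarget(seed=140, epochs=2)
        m1 = train_offtarget(None, ot.Xg[:800], ot.Xs[:800], ot.detected[:800],
                             cfg)
        m2 = train_offtarget(None, ot.Xg[:800], ot.Xs[:800], ot.detected[:800],
                             NetworkConfig.for_offtarget(seed=140, epochs=2))
        assert m1.log == m2.log
        assert np.array_equal(m1.predict(ot.Xg[:30], ot.Xs[:30]),
                              m2.predict(ot.Xg[:30], ot.Xs[:30]))

    def test_single_class_input_rejected(self, pair_data):
        ot = pair_data
        neg = ot.detected == 0
        with pytest.raises(ValueError):
            train_offtarget(None, ot.Xg[neg][:200], ot.Xs[neg][:200],
                            ot.detected[neg][:200],
                            NetworkConfig.for_offtarget(seed=0, epochs=1))


class TestEnsembles:
    def test_ensemble_prediction_is_member_mean(self, ontarget_data):
        X, y = ontarget_data
        model = train_ontarget(None, X[:200], y[:200],
                               NetworkConfig.for_ontarget(seed=150, epochs=2,
                                                          ensemble=2))
        assert isinstance(model, EnsembleModel)
        manual = np.mean([m.predict(X[:20]) for m in model.members], axis=0)
        assert np.allclose(model.predict(X[:20]), manual)
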