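"""Multi-task model: losses, aggregation, training behavior, persistence."""

import math

import numpy as np
import pytest

from cogdep import (
    GeneratorConfig,
    ModelConfig,
    MultiTaskModel,
    PostClassifier,
    distortion_loss,
    explanation_report,
    generate_corpus,
    joint_loss,
)
from cogdep.encoder import TinyEncoder, Vocabulary
from cogdep.model import TrainingError, _PreppedUser
from cogdep.taxonomy import N_CLASSES


def _tiny_model(users, **cfg_kwargs):
    defaults = dict(d_h=8, lstm_hidden=6, attention_dim=5, dep_hidden=4, seed=2)
    defaults.update(cfg_kwargs)
    cfg = ModelConfig(**defaults)
    texts = [p.text for u in users for p in u.posts]
    vocab = Vocabulary.build(texts)
    enc = TinyEncoder(vocab, dim=cfg.d_h, max_tokens=cfg.max_tokens,
                      seed=cfg.seed)
    return MultiTaskModel(cfg, enc)


@pytest.fixture(scope="module")
def tiny_users():
    cfg = GeneratorConfig(n_users=6, posts_per_user_mean=8, seed=11)
    return generate_corpus(cfg)


class TestDistortionLoss:
    def test_uniform_predictions_give_log_12(self):
        probs = np.full((40, N_CLASSES), 1 / N_CLASSES)
        labels = np.arange(40) % N_CLASSES
        l1 = distortion_loss(probs, labels, np.ones(40, dtype=bool))
        assert abs(l1 - math.log(12)) < 1e-6

    def test_perfect_predictions_give_zero(self):
        labels = np.arange(12)
        probs = np.eye(N_CLASSES)
        assert distortion_loss(probs, labels, np.ones(12, bool)) == pytest.approx(0.0, abs=1e-9)

    def test_all_masked_gives_zero(self):
        probs = np.full((5, N_CLASSES), 1 / N_CLASSES)
        assert distortion_loss(probs, np.zeros(5, int), np.zeros(5, bool)) == 0.0

    def test_masked_posts_contribute_nothing(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet(np.ones(N_CLASSES), size=10)
        labels = rng.integers(0, N_CLASSES, size=10)
        mask = np.array([True] * 5 + [False] * 5)
        scrambled = labels.copy()
        scrambled[5:] = (scrambled[5:] + 3) % N_CLASSES  # change masked golds
        assert distortion_loss(probs, labels, mask) == \
            distortion_loss(probs, scrambled, mask)


class TestJointLoss:
    def test_weighted_sum_arithmetic(self):
        assert joint_loss(2.0, 0.5) == 2.5
        assert joint_loss(0.0, 0.0) == 0.0

    def test_ablation_drops_auxiliary_term(self):
        assert joint_loss(7.3, 0.5, weights=(0.0, 1.0)) == 0.5

    def test_non_finite_raises(self):
        with pytest.raises(TrainingError):
            joint_loss(float("nan"), 0.1)


class TestForwardContracts:
    def test_post_distributions_normalized(self, tiny_users):
        m = _tiny_model(tiny_users)
        texts = [p.text for u in tiny_users for p in u.posts]
        P = m.predict_posts_proba(texts)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-6)
        assert (P >= 0).all()

    def test_single_post_attention_weight_one(self, tiny_users):
        m = _tiny_model(tiny_users)
        pu = _PreppedUser(tiny_users[0], m.encoder, 128)
        H = m.encode_posts(pu.seqs[:1])
        _, alpha, _ = m.aggregate_user(H)
        assert np.allclose(alpha, [1.0])

    def test_equal_logits_give_uniform_attention(self, tiny_users):
        m = _tiny_model(tiny_users)
        m.params["attn/v"][:] = 0.0  # all attention scores identical
        pu = _PreppedUser(tiny_users[0], m.encoder, 128)
        H = m.encode_posts(pu.seqs)
        _, alpha, _ = m.aggregate_user(H)
        assert np.allclose(alpha, 1.0 / len(alpha))

    def test_empty_sequence_rejected(self, tiny_users):
        m = _tiny_model(tiny_users)
        with pytest.raises(ValueError):
            m.aggregate_user(np.zeros((0, m.config.d_h)))

    def test_permuting_posts_changes_output(self, tiny_users):
        # the LSTM is order-sensitive by design
        m = _tiny_model(tiny_users)
        pu = _PreppedUser(tiny_users[0], m.encoder, 128)
        H = m.encode_posts(pu.seqs)
        u1, _, _ = m.aggregate_user(H)
        u2, _, _ = m.aggregate_user(H[::-1].copy())
        assert not np.allclose(u1, u2)

    def test_depression_probability_in_range(self, tiny_users):
        m = _tiny_model(tiny_users)
        rng = np.random.default_rng(5)
        for _ in range(20):
            u = rng.normal(size=m._s_dim)
            p, q, _ = m.classify_depression(u)
            assert 0.0 <= p <= 1.0
            assert np.isclose(q.sum(), 1.0)

    def test_untrained_probability_near_half(self, tiny_users):
        m = _tiny_model(tiny_users)
        rng = np.random.default_rng(6)
        ps = [m.classify_depression(rng.normal(size=m._s_dim))[0]
              for _ in range(200)]
        assert abs(np.mean(ps) - 0.5) < 0.2


class TestFullModelGradients:
    def test_backprop_matches_finite_differences(self, tiny_users):
        m = _tiny_model(tiny_users, lstm_bidirectional=True)
        prepped = [_PreppedUser(u, m.encoder, 128) for u in tiny_users[:3]]
        n_lab = sum(1 for pu in prepped for y in pu.labels if y is not None)

        def loss():
            l1 = l2 = 0.0
            for pu in prepped:
                fw = m._forward_user(pu)
                for t, y in enumerate(pu.labels):
                    if y is not None:
                        l1 += -np.log(fw["P"][t, y])
                l2 += -np.log(fw["q"][pu.y])
            return l1 / n_lab + l2 / len(prepped)

        grads = {k: np.zeros_like(v) for k, v in m.params.items()}
        for pu in prepped:
            fw = m._forward_user(pu)
            m._backward_user(pu, fw, 1.0 / n_lab, 1.0 / len(prepped), grads)

        rng = np.random.default_rng(0)
        eps = 1e-6
        for k, v in m.params.items():
            flat = v.ravel()
            for i in rng.choice(flat.size, size=min(6, flat.size),
                                replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[k].ravel()[i]
                assert abs(num - ana) <= 1e-6 + 1e-4 * (abs(num) + abs(ana)), \
                    f"param {k}[{i}]: numeric {num} vs analytic {ana}"

    def test_unlabeled_posts_never_affect_gradients(self, tiny_users):
        m = _tiny_model(tiny_users)
        pu = _PreppedUser(tiny_users[0], m.encoder, 128)
        pu.labels = [None] * len(pu.labels)  # mask everything

        def batch_grads():
            grads = {k: np.zeros_like(v) for k, v in m.params.items()}
            fw = m._forward_user(pu)
            m._backward_user(pu, fw, 1.0, 1.0, grads)
            return grads

        g1 = batch_grads()
        g2 = batch_grads()
        for k in g1:
            assert np.array_equal(g1[k], g2[k])
        assert not np.any(g1["W_post"])  # no post-level supervision flows


class TestTraining:
    def test_requires_labeled_users(self, tiny_users):
        unlabeled = [u.model_copy(update={"depression_label": None,
                                          "cohort": None})
                     for u in tiny_users]
        with pytest.raises(TrainingError):
            MultiTaskModel.fit(unlabeled, [], ModelConfig(epochs=1))

    def test_loss_decreases_on_separable_data(self):
        users = generate_corpus(GeneratorConfig(n_users=40,
                                                posts_per_user_mean=15,
                                                seed=21))
        m = MultiTaskModel.fit(users, [], ModelConfig(epochs=10, seed=3))
        losses = [e["l"] for e in m.training_log]
        assert np.mean(losses[-3:]) < np.mean(losses[:3])

    def test_training_deterministic_under_seed(self):
        users = generate_corpus(GeneratorConfig(n_users=12,
                                                posts_per_user_mean=8,
                                                seed=22))
        cfg = ModelConfig(epochs=3, seed=4)
        m1 = MultiTaskModel.fit(users, [], cfg)
        m2 = MultiTaskModel.fit(users, [], cfg)
        assert m1.training_log == m2.training_log
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_checkpoint_roundtrip(self, tmp_path, tiny_users):
        m = MultiTaskModel.fit(tiny_users, [],
                               ModelConfig(epochs=2, seed=5))
        m.save(tmp_path / "ckpt")
        m2 = MultiTaskModel.load(tmp_path / "ckpt")
        p1 = m.predict(tiny_users)
        p2 = m2.predict(tiny_users)
        for a, b in zip(p1, p2):
            assert a.depression_probability == pytest.approx(
                b.depression_probability, abs=1e-12)
            assert a.attention_weights == pytest.approx(b.attention_weights)


@pytest.fixture(scope="module")
def trained(tiny_users):
    return MultiTaskModel.fit(tiny_users, [], ModelConfig(epochs=3, seed=6))


class TestPredict:
    def test_one_prediction_per_user(self, trained, tiny_users):
        preds = trained.predict(tiny_users)
        assert len(preds) == len(tiny_users)
        assert [p.user_id for p in preds] == [u.user_id for u in tiny_users]

    def test_attention_weights_sum_to_one(self, trained, tiny_users):
        for pred in trained.predict(tiny_users):
            assert sum(pred.attention_weights) == pytest.approx(1.0, abs=1e-6)
            assert len(pred.attention_weights) == len(pred.post_predictions)

    def test_explanation_report_lists_top_posts(self, trained, tiny_users):
        preds = trained.predict(tiny_users)
        report = explanation_report(tiny_users, preds, top_k=3)
        assert f"User {tiny_users[0].user_id}" in report
        assert "attn" in report and "P(depression)" in report


class TestPostClassifier:
    def test_fits_separable_seed_to_high_accuracy(self, seed_pool):
        clf = PostClassifier(epochs=30, seed=0).fit(seed_pool.seed)
        preds = clf.predict([p.text for p in seed_pool.seed])
        acc = np.mean([a is b.label for a, b in zip(preds, seed_pool.seed)])
        assert acc >= 0.99

    def test_unfitted_raises(self):
        with pytest.raises(TrainingError):
            PostClassifier().predict_proba(["hello"])
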