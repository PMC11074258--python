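import dataclasses

import numpy as np
import pytest

from pcppn import (NetworkConfig, PCPPNet, PseudoLabelMap, TrainingConfig,
                   joint_loss, patch_distances, project_prototypes,
                   similarity_from_distance, train_head, train_joint)
from pcppn.nn import softmax

LN_1_OVER_EPS = np.log(1.0 / 1e-4)


def _mini_batch(n=2, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3, 64, 64)).astype(np.float32)
    y = np.arange(n) % 4
    return x, y


def _mini_ds(n=8, seed=0):
    """Tiny pseudo-labeled dataset of random 64px images."""
    from pcppn import LabeledImageSet
    rng = np.random.default_rng(seed)
    images = [rng.normal(size=(64, 64, 3)).astype(np.float32) for _ in range(n)]
    labels = np.arange(n) % 2
    pseudo = np.arange(n) % 4
    return LabeledImageSet(images=images, ids=[f"m{i}" for i in range(n)],
                           labels=labels, fold=np.zeros(n, dtype=int),
                           pseudo_labels=pseudo)


class TestJointLoss:
    def test_lambda_zero_reduces_to_cross_entropy(self, tiny_net):
        x, y = _mini_batch()
        cfg = TrainingConfig(lambda1=0.0, lambda2=0.0)
        loss, comps = joint_loss(tiny_net, x, y, cfg)
        assert loss == pytest.approx(comps["ce"])
        # independent CE recomputation from the forward pass
        _, scores, _, _ = tiny_net.forward(x)
        logits = scores @ tiny_net.head_w.T.astype(np.float64)
        p = softmax(logits)
        ce = -np.mean(np.log(p[np.arange(len(y)), y]))
        assert comps["ce"] == pytest.approx(ce, abs=1e-9)

    def test_zero_head_gives_log_c(self, tiny_net):
        tiny_net.head_w[:] = 0.0
        x, y = _mini_batch()
        _, comps = joint_loss(tiny_net, x, y, TrainingConfig())
        assert comps["ce"] == pytest.approx(np.log(4.0), abs=1e-9)

    def test_hand_set_distance_contribution(self):
        """Own-class min d2 = 4, other-class min d2 = 9 -> 0.8*4 - 0.08*9 = 2.48."""
        # 16px input on the stride-16 backbone -> a single 1x1 patch, so the
        # prototype-to-patch distances can be set exactly
        cfg_net = NetworkConfig(backbone="tiny", input_side=16, D=8,
                                M_per_class=1, C=2)
        net = PCPPNet(cfg_net, pseudo_map=PseudoLabelMap(q=2, K=1), seed=0)
        x = np.random.default_rng(0).normal(size=(1, 3, 16, 16)).astype(np.float32)
        v = net.forward_features(x)[0][:, 0, 0].astype(np.float64)
        offset = np.zeros(cfg_net.D)
        offset[0] = 1.0
        net.bank.vectors[0] = (v + 2.0 * offset).astype(np.float32)   # own, d2=4
        net.bank.vectors[1] = (v + 3.0 * offset).astype(np.float32)   # other, d2=9
        cfg = TrainingConfig(lambda1=0.8, lambda2=0.08)
        _, comps = joint_loss(net, x, np.array([0]), cfg)
        assert comps["cluster"] == pytest.approx(4.0, abs=1e-3)
        assert comps["separation"] == pytest.approx(9.0, abs=1e-3)
        contribution = cfg.lambda1 * comps["cluster"] - cfg.lambda2 * comps["separation"]
        assert contribution == pytest.approx(2.48, abs=1e-3)

    def test_matches_from_scratch_scalar_recomputation(self, tiny_net):
        """Eq-style objective vs an independent scalar loop (2 images, shared
        forward features only)."""
        x, y = _mini_batch(n=2, seed=4)
        cfg = TrainingConfig(lambda1=0.8, lambda2=0.08)
        loss, _ = joint_loss(tiny_net, x, y, cfg)

        total = 0.0
        for i in range(2):
            z = tiny_net.forward_features(x[i:i + 1])[0]
            m = tiny_net.bank.M
            dmin = []
            for j in range(m):
                best = min(
                    sum((float(z[d, r, c]) - float(tiny_net.bank.vectors[j, d])) ** 2
                        for d in range(tiny_net.cfg.D))
                    for r in range(4) for c in range(4))
                dmin.append(best)
            s = [np.log((dj + 1) / (dj + tiny_net.cfg.epsilon)) for dj in dmin]
            logits = [sum(tiny_net.head_w[cc, j] * s[j] for j in range(m))
                      for cc in range(4)]
            e = np.exp(np.array(logits) - max(logits))
            ce = -np.log(e[y[i]] / e.sum())
            own = [dmin[j] for j in range(m) if tiny_net.bank.owner[j] == y[i]]
            other = [dmin[j] for j in range(m) if tiny_net.bank.owner[j] != y[i]]
            total += ce + cfg.lambda1 * min(own) - cfg.lambda2 * min(other)
        assert loss == pytest.approx(total / 2, abs=1e-5)

    def test_unowned_pseudo_class_rejected(self, tiny_net):
        x, _ = _mini_batch(n=1)
        with pytest.raises(ValueError, match="own no prototype"):
            joint_loss(tiny_net, x, np.array([7]), TrainingConfig())


class TestTrainJoint:
    def test_head_frozen_bitwise_and_loss_decreases(self, tiny_net):
        ds = _mini_ds(n=8)
        before = tiny_net.checksum("head")
        history = train_joint(ds, tiny_net, TrainingConfig(batch_size=4, seed=0),
                              epochs=10)
        assert tiny_net.checksum("head") == before
        assert history[-1] < history[0]

    def test_default_learning_rate(self):
        assert TrainingConfig().lr == 0.001
        assert TrainingConfig().lambda1 == 0.8
        assert TrainingConfig().lambda2 == 0.08


class TestProjection:
    def test_provenance_distance_zero_and_similarity_cap(self, tiny_net):
        ds = _mini_ds(n=8)
        project_prototypes(ds, tiny_net)
        x = ds.as_tensor()
        for j in range(tiny_net.bank.M):
            img_id, r, c = tiny_net.bank.provenance[j]
            i = ds.ids.index(img_id)
            z = tiny_net.forward_features(x[i:i + 1])[0]
            d2 = float(((z[:, r, c] - tiny_net.bank.vectors[j]) ** 2).sum())
            assert d2 == pytest.approx(0.0, abs=1e-10)
            prof = tiny_net.similarity_profile(x[i])
            assert prof.scores[j] == pytest.approx(LN_1_OVER_EPS, abs=1e-4)

    def test_idempotent(self, tiny_net):
        ds = _mini_ds(n=8)
        project_prototypes(ds, tiny_net)
        first = tiny_net.bank.vectors.copy()
        prov = list(tiny_net.bank.provenance)
        project_prototypes(ds, tiny_net)
        np.testing.assert_array_equal(tiny_net.bank.vectors, first)
        assert tiny_net.bank.provenance == prov

    def test_matches_exhaustive_search_oracle(self, tiny_net):
        ds = _mini_ds(n=4, seed=9)
        expected = {}
        x = ds.as_tensor()
        for j in range(tiny_net.bank.M):
            best = (np.inf, None, None)
            for i in range(ds.n):
                if ds.pseudo_labels[i] != tiny_net.bank.owner[j]:
                    continue
                z = tiny_net.forward_features(x[i:i + 1])[0]
                for r in range(4):
                    for c in range(4):
                        d2 = float(((z[:, r, c] - tiny_net.bank.vectors[j]) ** 2).sum())
                        if d2 < best[0]:
                            best = (d2, (ds.ids[i], r, c), z[:, r, c].copy())
            expected[j] = best
        project_prototypes(ds, tiny_net)
        for j in range(tiny_net.bank.M):
            assert tiny_net.bank.provenance[j] == expected[j][1]
            np.testing.assert_allclose(tiny_net.bank.vectors[j], expected[j][2],
                                       atol=1e-6)

    def test_empty_pseudo_class_rejected(self, tiny_net):
        ds = _mini_ds(n=8).subset(np.arange(8) % 4 != 3)
        with pytest.raises(ValueError, match="3"):
            project_prototypes(ds, tiny_net)


class TestTrainHead:
    def test_conv_and_prototypes_frozen_bitwise(self, tiny_net):
        ds = _mini_ds(n=8)
        before = tiny_net.checksum("backbone+proto")
        train_head(ds, tiny_net, TrainingConfig(head_iters=5))
        assert tiny_net.checksum("backbone+proto") == before

    def test_large_l1_shrinks_wrong_class_weights(self, tiny_net):
        ds = _mini_ds(n=8)
        wrong = tiny_net.bank.owner[None, :] != np.arange(4)[:, None]
        maxima = []
        cfg = TrainingConfig(head_iters=1, head_l1=10.0, lr=0.05)
        for _ in range(20):
            train_head(ds, tiny_net, cfg)
            maxima.append(np.abs(tiny_net.head_w[wrong]).max())
        assert maxima[-1] < maxima[0]

    def test_l1_zero_is_plain_ce_refit(self, tiny_net):
        ds = _mini_ds(n=8)
        history = train_head(ds, tiny_net, TrainingConfig(head_iters=20, head_l1=0.0))
        assert history[-1] < history[0]


class TestFitSchedule:
    def test_provenance_set_after_fit(self, trained_model):
        model, _ = trained_model
        assert all(p is not None for p in model.bank.provenance)

    def test_training_never_alters_pseudo_map(self, trained_model,
                                              pseudo_labeled_train):
        model, _ = trained_model
        _, pmap = pseudo_labeled_train
        assert model.pseudo_map == pmap

    def test_k1_baseline_schedule_runs(self):
        ds = _mini_ds(n=8)
        ds = dataclasses.replace(ds, pseudo_labels=ds.labels.copy())
        net_cfg = NetworkConfig(backbone="tiny", input_side=64, D=8,
                                M_per_class=2, C=2)
        from pcppn import fit
        model, history = fit(ds, None, net_cfg,
                             TrainingConfig(total_epochs=2,
                                            joint_epochs_before_push=1,
                                            head_iters=2, batch_size=4, seed=0),
                             pseudo_map=PseudoLabelMap(q=2, K=1))
        assert len(history["joint_loss"]) == 2
        assert all(p is not None for p in model.bank.provenance)
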