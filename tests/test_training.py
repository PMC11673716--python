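import numpy as np
import pytest

from xmodnn.expression import LabelVector
from xmodnn.hierarchy import MODULE_LEVELS
from xmodnn.network import ModuleSpec, build_network, forward, predict
from xmodnn.synthetic import SyntheticSpec, simulate
from xmodnn.training import (
    Checkpoint,
    TrainingConfig,
    active_layers,
    class_weights,
    l1_penalty,
    module_losses,
    multi_loss,
    objective,
    select_best,
    train,
    weighted_cross_entropy,
)

from conftest import build_hierarchy


def labels_of(counts):
    sids, labs = [], []
    for cls, n in counts.items():
        for i in range(n):
            sids.append(f"{cls}{i}")
            labs.append(cls)
    return LabelVector(sids, labs)


class TestClassWeights:
    def test_balanced_two_class(self):
        w = class_weights(labels_of({"a": 50, "b": 50}))
        assert w == {"a": 1.0, "b": 1.0}

    def test_imbalanced_cohort(self):
        w = class_weights(labels_of({"male": 434, "female": 555}))
        assert w["male"] == pytest.approx(989 / (2 * 434))
        assert w["female"] == pytest.approx(989 / (2 * 555))

    def test_three_equal_classes(self):
        w = class_weights(labels_of({"a": 7, "b": 7, "c": 7}))
        assert all(v == pytest.approx(1.0) for v in w.values())


class TestWeightedCrossEntropy:
    def test_uniform_scores_give_log2(self):
        assert weighted_cross_entropy([0.0, 0.0], 0, [1.0, 1.0]) == \
            pytest.approx(np.log(2))

    def test_confident_correct_is_near_zero(self):
        loss = weighted_cross_entropy([10.0, -10.0], 0, [1.0, 1.0])
        assert loss == pytest.approx(np.log1p(np.exp(-20)), rel=1e-6)
        assert loss < 1e-8

    def test_linear_in_class_weight(self):
        scores = [0.3, -0.7, 1.2]
        base = weighted_cross_entropy(scores, 1, [1, 1, 1])
        doubled = weighted_cross_entropy(scores, 1, [1, 2, 1])
        assert doubled == pytest.approx(2 * base)

    def test_equals_unweighted_on_balanced_data(self):
        labels = labels_of({"a": 10, "b": 10})
        w = class_weights(labels)
        assert list(w.values()) == [1.0, 1.0]


class TestSchedule:
    @pytest.mark.parametrize("epoch, expected", [
        (1, {"C"}), (2, {"C", "B"}), (3, {"C", "B"}),
        (5, {"C", "B", "A"}), (6, {"C", "B", "A", "O"}),
        (30, {"C", "B", "A", "O"}),
    ])
    def test_default_inclusion(self, epoch, expected):
        assert active_layers(epoch, TrainingConfig()) == expected

    def test_decreasing_schedule_rejected(self):
        with pytest.raises(ValueError):
            TrainingConfig(inclusion_epochs={"C": 1, "B": 4, "A": 2, "O": 6})


class TestMultiLoss:
    H = None

    @pytest.fixture(autouse=True)
    def _hier(self):
        levels = {"g1": "D", "g2": "D", "c1": "C", "c2": "C", "b1": "B",
                  "a1": "A", "O": "O"}
        edges = [("g1", "c1"), ("g2", "c2"), ("c1", "b1"), ("c2", "b1"),
                 ("b1", "a1"), ("a1", "O")]
        self.h = build_hierarchy(edges, levels)

    def test_hand_arithmetic_all_active(self):
        losses = {"c1": 0.6, "c2": 0.4, "b1": 0.5, "a1": 0.3, "O": 0.2}
        total = multi_loss(losses, self.h, TrainingConfig(), epoch=6)
        assert total == pytest.approx(1.3 * 1.0 + 1.2 * 0.5 + 1.1 * 0.3 + 1.0 * 0.2)

    def test_hand_arithmetic_partial_schedule(self):
        losses = {"c1": 0.6, "c2": 0.4, "b1": 0.5, "a1": 0.3, "O": 0.2}
        total = multi_loss(losses, self.h, TrainingConfig(), epoch=3)
        assert total == pytest.approx(1.3 + 0.6)

    def test_unit_weights_reduce_to_plain_sum(self):
        cfg = TrainingConfig(loss_weights={lv: 1.0 for lv in MODULE_LEVELS})
        losses = {"c1": 0.1, "c2": 0.2, "b1": 0.3, "a1": 0.4, "O": 0.5}
        assert multi_loss(losses, self.h, cfg, epoch=6) == pytest.approx(1.5)

    def test_matches_brute_force_on_random_configs(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            losses = {m: float(rng.uniform(0, 2)) for m in self.h.module_order}
            lw = {lv: float(rng.uniform(0.5, 2)) for lv in MODULE_LEVELS}
            epoch = int(rng.integers(1, 8))
            cfg = TrainingConfig(loss_weights=lw)
            expected = 0.0
            for lv in MODULE_LEVELS:
                if epoch >= cfg.inclusion_epochs[lv]:
                    expected += lw[lv] * sum(
                        losses[m] for m in self.h.ids_at(lv))
            assert multi_loss(losses, self.h, cfg, epoch) == \
                pytest.approx(expected, abs=1e-12)


class TestL1Penalty:
    def test_zero_weights(self, minimal_chain):
        net = build_network(minimal_chain, ModuleSpec(), seed=0)
        for p in net.modules.values():
            for l in range(len(p.W)):
                p.W[l][:] = 0
            p.W_head[:] = 0
        assert l1_penalty(net, TrainingConfig()) == 0.0

    def test_hand_arithmetic(self, minimal_chain):
        net = build_network(minimal_chain, ModuleSpec(), seed=0)
        for p in net.modules.values():
            for l in range(len(p.W)):
                p.W[l][:] = 0
            p.W_head[:] = 0
        net.modules["c1"].W[0][0, 0] = 2.0    # first-layer block: 0.1
        net.modules["b1"].W_head[0, 0] = 3.0  # ordinary weight: 0.01
        assert l1_penalty(net, TrainingConfig()) == pytest.approx(0.23)

    def test_sign_flip_invariant(self, minimal_chain):
        net = build_network(minimal_chain, ModuleSpec(), seed=2)
        before = l1_penalty(net, TrainingConfig())
        for p in net.modules.values():
            for l in range(len(p.W)):
                p.W[l] *= -1
            p.W_head *= -1
        assert l1_penalty(net, TrainingConfig()) == pytest.approx(before)

    def test_matches_brute_force_on_random_nets(self, two_pathway):
        rng = np.random.default_rng(23)
        for _ in range(100):
            net = build_network(two_pathway, ModuleSpec(),
                                seed=int(rng.integers(1 << 30)))
            l1a = float(rng.uniform(0.001, 0.1))
            l1i = float(rng.uniform(0.01, 1.0))
            cfg = TrainingConfig(l1_all=l1a, l1_input_layer=l1i)
            expected = 0.0
            for p in net.modules.values():
                expected += l1i * np.abs(p.W[0]).sum()
                expected += l1a * sum(np.abs(w).sum() for w in p.W[1:])
                expected += l1a * np.abs(p.W_head).sum()
            assert l1_penalty(net, cfg) == pytest.approx(expected, abs=1e-12)


class TestSelectBest:
    def test_argmin(self):
        cps = [Checkpoint(e + 1, v, {}) for e, v in enumerate([0.9, 0.4, 0.6])]
        assert select_best(cps).epoch == 2

    def test_tie_goes_to_earliest(self):
        cps = [Checkpoint(1, 0.5, {}), Checkpoint(2, 0.5, {})]
        assert select_best(cps).epoch == 1

    def test_single(self):
        assert select_best([Checkpoint(1, 1.0, {})]).epoch == 1


def _small_problem(seed=0, effect=3.0):
    spec = SyntheticSpec(n_genes=20, n_c=4, n_b=2, n_a=1,
                         n_samples=(100, 100), n_planted=4,
                         effect_size=effect, seed=seed)
    h, x, y, truth = simulate(spec)
    perm = np.random.default_rng(99).permutation(len(y))  # interleave classes
    data = x.values.T[perm]
    y_idx = y.as_indices()[perm]
    return h, data, y_idx


class TestTrain:
    def test_inactive_layers_bit_identical_to_init(self):
        h, data, y = _small_problem()
        net = build_network(h, ModuleSpec(), seed=5)
        init = net.copy_params()
        cfg = TrainingConfig(max_epochs=1, seed=5)
        w = np.ones(2)
        train(net, (data[:150], y[:150]), (data[150:], y[150:]), cfg, w)
        for mid in h.module_order:
            if h.level_of(mid) == "C":
                continue
            for (k1, a1), (k2, a2) in zip(init[mid].arrays(),
                                          net.modules[mid].arrays()):
                np.testing.assert_array_equal(a1, a2), (mid, k1)

    def test_objective_gradient_zero_for_inactive_layer(self, two_pathway):
        # finite differences: perturbing a B-module weight must not move the
        # epoch-1 objective (only level C is active)
        net = build_network(two_pathway, ModuleSpec(), seed=1)
        x = np.random.default_rng(2).normal(size=(6, 2))
        y = np.array([0, 1, 0, 1, 0, 1])
        w = np.ones(2)
        cfg = TrainingConfig()
        base = objective(net, x, y, w, cfg, epoch=1)
        for eps in (1e-3, 1e-1):
            net.modules["b1"].W[1][0, 0] += eps
            assert objective(net, x, y, w, cfg, epoch=1) == base
            net.modules["b1"].W[1][0, 0] -= eps
        # and a C weight must move it
        net.modules["c1"].W[0][0, 0] += 1e-3
        assert objective(net, x, y, w, cfg, epoch=1) != base

    def test_bit_reproducible(self):
        h, data, y = _small_problem()
        outs = []
        for _ in range(2):
            net = build_network(h, ModuleSpec(), seed=5)
            cfg = TrainingConfig(max_epochs=3, seed=5)
            net, hist = train(net, (data[:150], y[:150]), (data[150:], y[150:]),
                              cfg, np.ones(2))
            outs.append((forward(net, data[150:]).head_outputs["O"],
                         hist["val_loss"].to_numpy()))
        np.testing.assert_array_equal(outs[0][0], outs[1][0])
        np.testing.assert_array_equal(outs[0][1], outs[1][1])

    def test_learns_separable_data(self):
        h, data, y = _small_problem(seed=1)
        net = build_network(h, ModuleSpec(), seed=1)
        cfg = TrainingConfig(max_epochs=15, batch_size=16, seed=1)
        net, _ = train(net, (data[:150], y[:150]), (data[150:], y[150:]),
                       cfg, np.ones(2))
        pred = predict(net, data[150:])
        acc = np.mean([np.mean(pred[y[150:] == c] == c) for c in (0, 1)])
        assert acc >= 0.95

    def test_stronger_l1_shrinks_weights(self):
        h, data, y = _small_problem(seed=2)
        mean_abs = []
        for l1 in (0.01, 0.1):
            net = build_network(h, ModuleSpec(), seed=3)
            cfg = TrainingConfig(max_epochs=10, seed=3, l1_all=l1,
                                 l1_input_layer=l1 * 10)
            net, _ = train(net, (data[:150], y[:150]), (data[150:], y[150:]),
                           cfg, np.ones(2))
            ws = np.concatenate([w.ravel() for p in net.modules.values()
                                 for w in (*p.W, p.W_head)])
            mean_abs.append(np.abs(ws).mean())
        assert mean_abs[1] < mean_abs[0]

    def test_multi_loss_matches_brute_force_from_head_outputs(self):
        h, data, y = _small_problem(seed=3)
        net = build_network(h, ModuleSpec(), seed=4)
        res = forward(net, data[:16])
        w = np.array([1.2, 0.8])
        cfg = TrainingConfig()
        losses = module_losses(res, h, y[:16], w)
        total = multi_loss(losses, h, cfg, epoch=6)
        expected = 0.0
        for mid in h.module_order:
            scores = res.head_outputs[mid]
            lse = np.log(np.exp(scores).sum(axis=1))
            per_sample = -w[y[:16]] * (scores[np.arange(16), y[:16]] - lse)
            expected += cfg.loss_weights[h.level_of(mid)] * per_sample.mean()
        assert total == pytest.approx(expected, rel=1e-12)
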