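"""Model families: architecture analytics, networks, trees, search."""

import math

import numpy as np
import pytest

from tmstruct.models import (
    ArchitectureSpec,
    EarlyStopper,
    SearchSpace,
    TARGETS,
    TrainConfig,
    build_network,
    dilated_window_positions,
    group_targets,
    make_samples,
    random_search,
    receptive_field,
    train_gbm,
    train_network,
    train_rf,
    windowize,
)
from tmstruct.models.specs import TARGET_GROUPS


class TestGroups:
    def test_five_groups_cover_all_targets_once(self):
        groups = group_targets()
        assert len(groups) == 5
        names = [t.name for g in groups for t in g]
        assert sorted(names) == sorted(TARGETS)

    def test_ss3_alone(self):
        assert TARGET_GROUPS["secondary_structure"] == ("ss3",)


class TestArchitectureSpec:
    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            ArchitectureSpec("conv", w=4)

    def test_dconv_layers_only_for_dconv(self):
        with pytest.raises(ValueError):
            ArchitectureSpec("conv", n_dconv_layers=3)
        with pytest.raises(ValueError):
            ArchitectureSpec("dconv")  # missing n_dconv_layers


class TestReceptiveField:
    def test_conv_three_layers_window_three(self):
        spec = ArchitectureSpec("conv", n_hidden_layers=3, w=3)
        assert receptive_field(spec) == 7

    def test_dconv_block_of_three(self):
        spec = ArchitectureSpec("dconv", n_hidden_layers=1, w=3,
                                n_dconv_layers=3)
        assert receptive_field(spec) == 15

    def test_window_one_is_pointwise(self):
        assert receptive_field(ArchitectureSpec("conv", n_hidden_layers=5, w=1)) == 1

    def test_lstm_full_sequence(self):
        assert receptive_field(ArchitectureSpec("lstm")) == math.inf

    @pytest.mark.parametrize("layers,w", [(1, 3), (2, 5), (3, 3)])
    def test_conv_matches_perturbation_span(self, layers, w):
        spec = ArchitectureSpec("conv", n_hidden_layers=layers, w=w,
                                n_hidden_neurons=6, n_embedding=4)
        L = 41
        rng = np.random.default_rng(0)
        centre = L // 2
        changed = np.zeros(L, bool)
        for draw in range(6):
            net = build_network(spec, [TARGETS["z"]], seed=draw)
            onehot = np.eye(20)[rng.integers(0, 20, L)].astype(float)
            profile = rng.uniform(0.1, 0.9, (L, 20))
            base = net.predict(onehot, profile)["z"]
            for bump in (0.3, -0.3):
                p2 = profile.copy()
                p2[centre] += bump
                changed |= np.abs(net.predict(onehot, p2)["z"] - base) > 1e-9
        idx = np.flatnonzero(changed)
        assert idx.max() - idx.min() + 1 == receptive_field(spec)
        # and nothing outside the analytic field ever changes
        half = (receptive_field(spec) - 1) // 2
        assert idx.min() >= centre - half and idx.max() <= centre + half


class TestDilatedWindow:
    def test_worked_example(self):
        assert dilated_window_positions(10, 5, 2) == [6, 8, 10, 12, 14]

    def test_unit_cases(self):
        assert dilated_window_positions(3, 3, 1) == [2, 3, 4]
        assert dilated_window_positions(5, 1, 8) == [5]


class TestNetworkContracts:
    def _sample(self, L=11, seed=0):
        rng = np.random.default_rng(seed)
        return {
            "onehot": np.eye(20)[rng.integers(0, 20, L)].astype(float),
            "profile": rng.uniform(0.05, 0.95, (L, 20)),
            "targets": {
                "ss3": np.eye(3)[rng.integers(0, 3, L)].astype(float),
            },
            "masks": {"ss3": rng.random(L) > 0.3},
        }

    def test_softmax_head_shape_and_sums(self):
        spec = ArchitectureSpec("conv", n_hidden_layers=3, w=3)
        net = build_network(spec, [TARGETS["ss3"]], seed=0)
        s = self._sample(L=7)
        out = net.predict(s["onehot"], s["profile"])
        assert out["ss3"].shape == (7, 3)
        assert np.allclose(out["ss3"].sum(axis=1), 1.0, atol=1e-6)

    def test_lstm_concat_residual_doubles_width(self):
        base = ArchitectureSpec("lstm", n_hidden_layers=1, n_hidden_neurons=5,
                                w=1, n_embedding=10, residual="none",
                                n_dense_layers=0)
        cat = ArchitectureSpec("lstm", n_hidden_layers=1, n_hidden_neurons=5,
                               w=1, n_embedding=10, residual="concat",
                               n_dense_layers=0)
        n0 = build_network(base, [TARGETS["z"]], seed=0)
        n1 = build_network(cat, [TARGETS["z"]], seed=0)
        # 2H = 10 = n_embedding + 20 == 30? widths: base head sees 10,
        # concat head sees 10 + 30
        assert n1.heads["z"].c_in == n0.heads["z"].c_in + 30

    def test_masked_targets_do_not_affect_loss(self):
        spec = ArchitectureSpec("dconv", n_hidden_layers=1, w=3,
                                n_dconv_layers=2)
        net = build_network(spec, [TARGETS["ss3"]], seed=1)
        s = self._sample(L=13, seed=3)
        loss1, _ = net.forward(s["onehot"], s["profile"], s["targets"], s["masks"])
        rng = np.random.default_rng(9)
        t2 = s["targets"]["ss3"].copy()
        dead = ~s["masks"]["ss3"]
        t2[dead] = np.eye(3)[rng.integers(0, 3, dead.sum())]
        loss2, _ = net.forward(s["onehot"], s["profile"], {"ss3": t2}, s["masks"])
        assert loss1 == pytest.approx(loss2, abs=1e-12)


class TestEarlyStopper:
    def test_constant_loss_stops_at_eleven(self):
        stopper = EarlyStopper(patience_stop=10, patience_lr=5)
        actions = [stopper.update(1.0) for _ in range(11)]
        assert actions[0] == "improved"
        assert actions[5] == "decay"
        assert actions[10] == "stop"
        assert stopper.best_epoch == 1

    def test_strict_improvement_never_stops(self):
        stopper = EarlyStopper()
        actions = [stopper.update(10.0 - i) for i in range(30)]
        assert all(a == "improved" for a in actions)
        assert stopper.best_epoch == 30

    def test_second_decay_after_five_more(self):
        stopper = EarlyStopper(patience_stop=12, patience_lr=5)
        stopper.update(1.0)
        actions = [stopper.update(1.0) for _ in range(10)]
        assert actions[4] == "decay" and actions[9] == "decay"


class TestTrainNetwork:
    def test_best_state_restored(self, small_dataset):
        samples = make_samples(small_dataset[:6])
        group = [TARGETS["z"]]
        spec = ArchitectureSpec("conv", n_hidden_layers=1, n_hidden_neurons=6,
                                w=3, n_embedding=4)
        net = build_network(spec, group, seed=0)
        cfg = TrainConfig(batch_size=2, initial_lr=0.02, max_epochs=6, seed=0)
        net, hist = train_network(net, samples[:4], samples[4:], cfg)
        best = min(hist["val_loss"])
        assert net.evaluate(samples[4:]) == pytest.approx(best, rel=1e-9)
        assert hist["best_epoch"] == int(np.argmin(hist["val_loss"])) + 1


class TestWindowize:
    def test_padding_single_row(self):
        out = windowize(np.array([[1.0, 2.0]]), 3)
        assert out.tolist() == [[0, 0, 1, 2, 0, 0]]

    def test_w1_identity(self):
        X = np.arange(12.0).reshape(4, 3)
        assert np.array_equal(windowize(X, 1), X)

    def test_interior_row_matches_slice_concat(self):
        rng = np.random.default_rng(0)
        X = rng.random((9, 4))
        out = windowize(X, 5)
        assert np.allclose(out[4], X[2:7].reshape(-1))


@pytest.fixture(scope="module")
def samples(small_dataset):
    return make_samples(small_dataset)


class TestTrees:
    def test_rf_deterministic_and_grid(self, samples):
        grid = {"n_features": [0.5, 0.8], "n_min_samples": [2], "w": [3]}
        m1, i1 = train_rf(samples[:8], samples[8:], TARGETS["flex_bin"],
                          grid, seed=3, max_trees=100)
        m2, i2 = train_rf(samples[:8], samples[8:], TARGETS["flex_bin"],
                          grid, seed=3, max_trees=100)
        assert i1 == i2
        s = samples[0]
        assert np.array_equal(m1.predict(s["onehot"], s["profile"])["flex_bin"],
                              m2.predict(s["onehot"], s["profile"])["flex_bin"])

    def test_rf_classification_in_unit_interval(self, samples):
        model, _ = train_rf(samples[:8], samples[8:], TARGETS["topo"],
                            {"n_features": [0.5], "n_min_samples": [2], "w": [3]},
                            seed=0, max_trees=100)
        s = samples[9]
        probs = model.predict(s["onehot"], s["profile"])["topo"]
        assert probs.shape == (len(s["onehot"]), 4)
        assert np.all(probs >= 0) and np.all(probs <= 1)

    def test_gbm_single_trial_and_determinism(self, samples):
        space = SearchSpace(values={"w": [3], "r": [0.3], "n_depth": [3],
                                    "n_features": [0.8], "n_samples": [0.8],
                                    "gamma": [0.0], "n_min_child_weight": [1.0]},
                            n_trials=1, seed=5)
        m1, i1 = train_gbm(samples[:8], samples[8:], TARGETS["z"], space,
                           seed=1, max_trees=30)
        m2, i2 = train_gbm(samples[:8], samples[8:], TARGETS["z"], space,
                           seed=1, max_trees=30)
        assert i1 == i2

    def test_gbm_beats_single_tree_on_additive_signal(self):
        rng = np.random.default_rng(0)
        import xgboost as xgb

        X = rng.random((400, 6))
        y = X @ np.array([2.0, -1.0, 0.5, 0, 0, 1.0]) + 0.05 * rng.normal(size=400)
        Xv, yv = X[300:], y[300:]
        X, y = X[:300], y[:300]
        boosted = xgb.XGBRegressor(n_estimators=100, max_depth=3,
                                   learning_rate=0.3, random_state=0)
        single = xgb.XGBRegressor(n_estimators=1, max_depth=3,
                                  learning_rate=1.0, random_state=0)
        boosted.fit(X, y)
        single.fit(X, y)
        err_b = np.mean((boosted.predict(Xv) - yv) ** 2)
        err_s = np.mean((single.predict(Xv) - yv) ** 2)
        assert err_b <= err_s


class TestRandomSearch:
    def test_single_configuration(self):
        space = SearchSpace(values={"a": [3]}, n_trials=4, seed=0)
        best, score, trials = random_search(space, lambda c: c["a"])
        assert best == {"a": 3} and score == 3

    def test_monotone_score_finds_extreme(self):
        space = SearchSpace(values={"a": [1, 2, 3]}, n_trials=30, seed=0)
        best, _, _ = random_search(space, lambda c: -c["a"])  # minimize -a
        assert best == {"a": 3}

    def test_seeded_draw_sequence_identical(self):
        space = SearchSpace(values={"a": [1, 2, 3], "b": [10, 20]},
                            n_trials=6, seed=9)
        _, _, t1 = random_search(space, lambda c: c["a"] + c["b"])
        _, _, t2 = random_search(space, lambda c: c["a"] + c["b"])
        assert t1 == t2

    def test_tie_keeps_earlier_draw(self):
        space = SearchSpace(values={"a": [1, 2]}, n_trials=10, seed=0)
        seen = []

        def ev(cfg):
            seen.append(dict(cfg))
            return 0.0

        best, _, _ = random_search(space, ev)
        assert best == seen[0]
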