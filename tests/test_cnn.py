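import numpy as np
import pytest

from elmh import MicroCNN, arrange_input, count_parameters, forward_pass
from elmh.cnn import (CnnConfig, CnnParameters, _loss_and_grad,
                      load_parameters, save_parameters, train)
from elmh.errors import GeometryError, InputError


class TestArrangeInput:
    def test_all_minimum_maps_to_zero_grid(self):
        grid = arrange_input(np.ones(44), 1, 5)
        assert grid.shape == (10, 10)
        assert (grid == 0).all()

    def test_all_maximum_fills_first_44_cells(self):
        grid = arrange_input(np.full(44, 5), 1, 5)
        flat = grid.ravel()
        assert (flat[:44] == 1.0).all() and (flat[44:] == 0.0).all()

    def test_row_major_rescaling(self):
        resp = np.tile([1, 2, 3, 4, 5], 9)[:44]
        grid = arrange_input(resp, 1, 5)
        assert grid[0, 0] == 0.0
        assert grid[0, 1] == 0.25

    def test_rejects_out_of_range_and_overflow(self):
        with pytest.raises(InputError):
            arrange_input(np.full(44, 6), 1, 5)
        with pytest.raises(InputError):
            arrange_input(np.ones(101), 1, 5)


class TestParameterAccounting:
    def test_default_geometry_has_108_parameters(self):
        assert count_parameters(CnnConfig()) == 108

    def test_single_class_has_27(self):
        assert count_parameters(CnnConfig(n_classes=1)) == 27

    def test_two_class_demo_geometry_has_38(self):
        demo = CnnConfig(n_classes=2, input_side=(10, 6))
        assert demo.pooled_length == 8
        assert count_parameters(demo) == 38

    def test_non_dividing_pooling_rejected(self):
        with pytest.raises(GeometryError):
            CnnConfig(input_side=9)

    def test_loader_rejects_count_mismatch(self, tmp_path):
        cfg = CnnConfig()
        params = CnnParameters.zeros(cfg)
        path = save_parameters(params, cfg, tmp_path / "p.json")
        import json

        doc = json.loads(path.read_text())
        doc["pool_weights"] = [w[:-1] for w in doc["pool_weights"]]
        path.write_text(json.dumps(doc))
        with pytest.raises(InputError, match="parameters"):
            load_parameters(path)

    def test_parameter_json_round_trip(self, tmp_path):
        cfg = CnnConfig()
        rng = np.random.default_rng(0)
        params = CnnParameters.random(cfg, rng)
        path = save_parameters(params, cfg, tmp_path / "p.json")
        back, cfg2, meta = load_parameters(path)
        assert np.allclose(back.flat(), params.flat())
        assert cfg2 == cfg and meta["likert_max"] == 5


class TestForwardPass:
    def test_zero_parameters_give_half_everywhere(self):
        params = CnnParameters.zeros(CnnConfig())
        out, info = forward_pass(np.zeros((10, 10)), params)
        assert np.allclose(out, 0.5)
        assert np.allclose(info["conv"], 0.5)
        assert info["predicted_class"] == 0  # tie broken to lowest index

    def test_all_ones_window_saturates_sigmoid(self):
        cfg = CnnConfig(n_classes=1)
        params = CnnParameters.zeros(cfg)
        params.filters[0] = 1.0
        out, info = forward_pass(np.ones((10, 10)), params, cfg)
        assert info["conv"][0, 0, 0] == pytest.approx(1 / (1 + np.exp(-9.0)))

    def test_max_pooling_takes_block_maximum(self):
        cfg = CnnConfig(n_classes=1, input_side=4, filter_side=1)
        params = CnnParameters.zeros(cfg)
        params.filters[0] = 6.0  # conv cell = sigmoid(6*x), monotone in x
        grid = np.zeros((4, 4))
        grid[:2, :2] = [[0.1, 0.7], [0.3, 0.2]]
        _, info = forward_pass(grid, params, cfg)
        assert info["pooled"][0, 0, 0] == pytest.approx(
            1 / (1 + np.exp(-6 * 0.7)))

    def test_permutation_covariance(self):
        rng = np.random.default_rng(5)
        cfg = CnnConfig()
        params = CnnParameters.random(cfg, rng)
        grid = rng.random((10, 10))
        out, _ = forward_pass(grid, params, cfg)
        perm = [2, 0, 3, 1]
        permuted = CnnParameters(params.filters[perm],
                                 params.filter_bias[perm],
                                 params.pool_weights[perm],
                                 params.pool_bias[perm])
        out2, _ = forward_pass(grid, permuted, cfg)
        assert np.allclose(out2, out[perm])


class TestTraining:
    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(0)
        cfg = CnnConfig(n_classes=3, input_side=6)
        grids = rng.random((5, 6, 6))
        targets = np.eye(3)[rng.integers(0, 3, 5)]
        params = CnnParameters.random(cfg, rng)
        _, grad, _ = _loss_and_grad(grids, targets, params, cfg)
        flat, gflat = params.flat(), grad.flat()
        eps = 1e-6
        for i in range(0, flat.size, 7):  # subsample coordinates
            up, dn = flat.copy(), flat.copy()
            up[i] += eps
            dn[i] -= eps
            lp, _, _ = _loss_and_grad(grids, targets,
                                      CnnParameters.from_flat(up, cfg), cfg)
            lm, _, _ = _loss_and_grad(grids, targets,
                                      CnnParameters.from_flat(dn, cfg), cfg)
            num = (lp - lm) / (2 * eps)
            rel = abs(num - gflat[i]) / max(1e-8, abs(num) + abs(gflat[i]))
            assert rel < 1e-5

    def test_separable_toy_reaches_perfect_accuracy(self):
        X = np.vstack([np.ones((20, 44)), np.full((20, 44), 5.0)])
        y = ["III"] * 20 + ["II"] * 20
        clf = MicroCNN(seed=0, max_epochs=2000).fit(X, y)
        assert clf.score(X, y) == 1.0
        # the true class's output dominates on every training point
        out = clf.decision_function(X)
        target_idx = np.array([list(clf.classes_).index(lab) for lab in y])
        assert (np.argmax(out, axis=1) == target_idx).all()
        assert ((out > 0) & (out < 1)).all()

    def test_training_is_deterministic(self):
        X = np.vstack([np.ones((5, 44)), np.full((5, 44), 5.0)])
        y = ["III"] * 5 + ["II"] * 5
        a = MicroCNN(seed=3, max_epochs=50).fit(X, y)
        b = MicroCNN(seed=3, max_epochs=50).fit(X, y)
        assert np.array_equal(a.params_.flat(), b.params_.flat())

    def test_returned_loss_not_above_initial(self):
        rng = np.random.default_rng(8)
        X = rng.integers(1, 6, size=(30, 44))
        y = rng.choice(["II", "III"], size=30)
        clf = MicroCNN(seed=1, max_epochs=200).fit(X, y)
        grids = clf._grids(X)
        targets = np.zeros((30, 2))
        for i, lab in enumerate(y):
            targets[i, list(clf.classes_).index(lab)] = 1.0
        final, _, _ = _loss_and_grad(grids, targets, clf.params_,
                                     clf._config(2))
        assert final <= clf.loss_trace_[0]

    def test_empty_training_set_rejected(self):
        with pytest.raises(InputError):
            train(np.empty((0, 10, 10)), [])
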