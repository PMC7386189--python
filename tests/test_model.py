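"""Network forward/Jacobian correctness, LM behavior, early stopping, and
ensemble semantics."""

import numpy as np
import pytest

from kbdose import (
    EnsembleModel,
    NetworkParameters,
    Normalizer,
    TrainConfig,
    VoxelGrid,
    derive_structure_set,
    predict_dose,
    sphere_mask,
    train_ensemble,
    train_network,
)
from kbdose.model import N_PARAMS, _forward_jacobian, lm_step


def random_net(rng):
    return NetworkParameters(
        w1=rng.normal(0, 0.5, (2, 16)),
        b1=rng.normal(0, 0.5, 2),
        w2=rng.normal(0, 0.5, (1, 2)),
        b2=rng.normal(0, 0.5, 1),
    )


def test_parameter_count_is_37(rng):
    assert N_PARAMS == 37
    net = random_net(rng)
    assert net.n_params == 37
    assert np.allclose(
        NetworkParameters.from_vector(net.to_vector()).to_vector(), net.to_vector()
    )


def test_jacobian_matches_finite_differences(rng):
    x = rng.normal(size=(7, 16))
    w = random_net(rng).to_vector()
    out, jac = _forward_jacobian(w, x)
    eps = 1e-6
    fd = np.empty_like(jac)
    for j in range(N_PARAMS):
        wp, wm = w.copy(), w.copy()
        wp[j] += eps
        wm[j] -= eps
        op, _ = _forward_jacobian(wp, x)
        om, _ = _forward_jacobian(wm, x)
        fd[:, j] = (op - om) / (2 * eps)
    assert np.allclose(jac, fd, atol=1e-6)


class TestLMStep:
    def test_large_damping_approaches_gradient_descent(self, rng):
        x = rng.normal(size=(50, 16))
        w = random_net(rng).to_vector()
        y = rng.normal(size=50)
        out, jac = _forward_jacobian(w, x)
        g = jac.T @ (out - y)
        mu = 1e9
        delta = lm_step(w, x, y, mu) - w
        # delta ~ -g / mu: same direction as steepest descent
        cos = (delta @ -g) / (np.linalg.norm(delta) * np.linalg.norm(g))
        assert cos > 0.999999
        assert np.allclose(delta, -g / mu, rtol=1e-4)

    def test_zero_damping_is_gauss_newton(self, rng):
        x = rng.normal(size=(200, 16))
        w = random_net(rng).to_vector()
        y = rng.normal(size=200)
        out, jac = _forward_jacobian(w, x)
        r = out - y
        gn = np.linalg.solve(jac.T @ jac, -jac.T @ r)
        assert np.allclose(lm_step(w, x, y, 0.0) - w, gn, rtol=1e-8)


class TestTrainNetwork:
    def test_constant_target_fit_to_machine_tolerance(self, rng):
        x = rng.uniform(0, 5, (400, 16))
        y = np.full(400, 0.87)
        params, norm, hist = train_network(x, y, TrainConfig(seed=1))
        pred = params.forward(norm.transform(x))
        assert np.allclose(pred, 0.87, atol=1e-6)

    def test_recovers_self_realizable_function(self, rng):
        # targets generated noiselessly by a frozen random 16->2->1 net
        teacher = random_net(np.random.default_rng(42))
        x = rng.uniform(-1, 1, (2000, 16))
        y = teacher.forward(x)
        params, norm, hist = train_network(x, y, TrainConfig(seed=5))
        val = min(hist.val_mse)
        assert val < 1e-4

    def test_training_mse_never_increases_between_accepted_epochs(self, rng):
        x = rng.uniform(0, 1, (300, 16))
        y = rng.normal(1.0, 0.2, 300)
        _, _, hist = train_network(x, y, TrainConfig(seed=2))
        assert np.all(np.diff(hist.train_mse) <= 1e-15)

    def test_early_stopping_on_six_consecutive_increases(self):
        # noise targets on a small sample: validation error drifts up
        x = np.random.default_rng(0).uniform(0, 10, (300, 16))
        y = np.random.default_rng(0).normal(0.9, 0.1, 300)
        _, _, hist = train_network(x, y, TrainConfig(seed=0))
        assert hist.stop_reason == "early_stop"
        assert hist.n_epochs < 200
        tail = np.array(hist.val_mse[-7:])
        assert np.all(np.diff(tail) > 0)  # exactly 6 consecutive increases
        # best-validation weights are the ones restored
        assert hist.best_epoch == int(np.argmin(hist.val_mse))

    def test_never_exceeds_max_epochs(self, rng):
        x = rng.uniform(0, 1, (200, 16))
        y = rng.normal(size=200)
        _, _, hist = train_network(x, y, TrainConfig(seed=3, max_epochs=20))
        assert hist.n_epochs <= 20

    def test_zero_variance_column_warned_and_silenced(self, rng):
        x = rng.uniform(0, 1, (200, 16))
        x[:, 4] = 7.0
        y = rng.uniform(0.8, 1.0, 200)
        with pytest.warns(UserWarning, match="zero-variance"):
            _, norm, _ = train_network(x, y, TrainConfig(seed=0))
        assert 4 in norm.constant_columns
        assert np.all(norm.transform(x)[:, 4] == 0.0)

    def test_non_finite_inputs_rejected(self, rng):
        x = rng.uniform(0, 1, (150, 16))
        y = rng.uniform(size=150)
        x[3, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            train_network(x, y, TrainConfig())


class TestEnsemble:
    def test_single_repeat_gives_single_member(self, rng):
        x = rng.uniform(0, 1, (200, 16))
        y = rng.uniform(0.7, 1.1, 200)
        model = train_ensemble(x, y, TrainConfig(seed=0), n_repeats=1)
        assert len(model.members) == 1

    def test_fixed_seed_is_bit_identical(self, rng):
        x = rng.uniform(0, 1, (200, 16))
        y = rng.uniform(0.7, 1.1, 200)
        a = train_ensemble(x, y, TrainConfig(seed=9), n_repeats=3)
        b = train_ensemble(x, y, TrainConfig(seed=9), n_repeats=3)
        assert a.to_json() == b.to_json()

    def test_ensemble_mean_less_variable_than_members(self, rng):
        # noisy linear target: member predictions scatter, the mean less so
        x = rng.uniform(-1, 1, (600, 16))
        y = 0.9 + 0.1 * x[:, 0] + rng.normal(0, 0.05, 600)
        model = train_ensemble(x, y, TrainConfig(seed=4), n_repeats=8)
        x_new = rng.uniform(-1, 1, (200, 16))
        member_preds = np.array(
            [p.forward(n.transform(x_new)) for p, n in model.members]
        )
        truth = 0.9 + 0.1 * x_new[:, 0]
        member_mse = np.mean((member_preds - truth) ** 2, axis=1)
        ensemble_mse = np.mean((member_preds.mean(axis=0) - truth) ** 2)
        assert ensemble_mse < member_mse.mean()

    def test_json_round_trip_is_bit_exact(self, tmp_path, rng):
        x = rng.uniform(0, 1, (200, 16))
        y = rng.uniform(0.7, 1.1, 200)
        model = train_ensemble(x, y, TrainConfig(seed=6), n_repeats=2)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = EnsembleModel.from_json(path)
        for (p1, n1), (p2, n2) in zip(model.members, back.members):
            assert np.array_equal(p1.to_vector(), p2.to_vector())
            assert np.array_equal(n1.center, n2.center)
            assert np.array_equal(n1.scale, n2.scale)
        assert back.to_json() == model.to_json()


class TestPredictDose:
    def _structs(self):
        grid = VoxelGrid((20, 20, 20), (3.0, 3.0, 3.0))
        gtv = sphere_mask(grid, (28, 28, 28), 12)
        oar = sphere_mask(grid, (48, 28, 28), 9)
        return derive_structure_set(gtv, oar)

    def test_identical_members_equal_single_member(self, rng):
        x = rng.uniform(0, 1, (200, 16))
        y = rng.uniform(0.7, 1.1, 200)
        single = train_ensemble(x, y, TrainConfig(seed=0), n_repeats=1)
        tripled = EnsembleModel(members=single.members * 3, n_repeats=3)
        structs = self._structs()
        d1 = predict_dose(single, structs, rx=50.0)
        d3 = predict_dose(tripled, structs, rx=50.0)
        assert np.allclose(
            d1.dose[structs.gtv.voxels], d3.dose[structs.gtv.voxels]
        )

    def test_nan_sentinel_outside_gtv_and_rx_scaling(self, rng):
        x = rng.uniform(0, 1, (200, 16))
        y = rng.uniform(0.7, 1.1, 200)
        model = train_ensemble(x, y, TrainConfig(seed=0), n_repeats=1)
        structs = self._structs()
        d50 = predict_dose(model, structs, rx=50.0)
        d100 = predict_dose(model, structs, rx=100.0)
        assert np.all(np.isnan(d50.dose[~structs.gtv.voxels]))
        assert np.all(np.isfinite(d50.dose[structs.gtv.voxels]))
        assert np.allclose(
            2 * d50.dose[structs.gtv.voxels], d100.dose[structs.gtv.voxels]
        )
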