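"""Network evaluation, Jacobian, split contract, trainers, metrics."""

import math

import numpy as np
import pandas as pd
import pytest

import labferm as lf
from labferm import ann
from labferm.dataio import ViabilityDataset
from labferm.models import ANNModel, ScalingSpec


def _raw_net(A, B, bi, bii, activation="neg_half_tanh"):
    return ANNModel(A=np.asarray(A, float), B=np.asarray(B, float),
                    bi=np.asarray(bi, float), bii=bii,
                    scaling=ScalingSpec(mode="raw"), activation=activation)


def _toy_dataset(fn, n=40, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 24, n)
    wf = rng.uniform(90, 100, n)
    v = np.array([fn(ti, wi, 100 - wi) for ti, wi in zip(t, wf)])
    if noise:
        v = v + rng.normal(0, noise, n)
    return ViabilityDataset(pd.DataFrame({
        "time_h": t, "wf_pct": wf, "sf_pct": 100 - wf,
        "culture": "Lp", "replicate": 1, "viability_log10cfu_ml": v,
    }))


class TestForward:
    def test_zero_preactivation_returns_output_bias(self):
        net = _raw_net([1.0, -2.0], [[1, 1, 1], [2, 0, 1]], [0.0, 0.0], 0.7)
        assert float(net.predict((0.0, 0.0, 0.0))[0]) == pytest.approx(0.7)

    def test_printed_activation_closed_form(self):
        # f(ln 3) = 2/(3+1) - 1 = -0.5 for the printed transfer function
        net = _raw_net([1.0], [[1.0, 0.0, 0.0]], [0.0], 0.0)
        assert float(net.predict((math.log(3.0), 50.0, 50.0))[0]) == pytest.approx(
            -0.5, abs=1e-14)

    def test_output_bounded_by_weight_sum(self):
        """Pre-descaling output never exceeds bii +/- sum|A| on a huge sweep."""
        for case in ("Lp", "Lc", "LpLc"):
            net = lf.load_reference_ann(case)
            rng = np.random.default_rng(1)
            pts = np.column_stack([
                rng.uniform(-1e3, 1e3, 4000),
                rng.uniform(-1e3, 1e3, 4000),
                rng.uniform(-1e3, 1e3, 4000)])
            core = net.forward_core(net.scaling.scale_inputs(pts))
            assert np.all(np.abs(core - net.bii) <= np.abs(net.A).sum() + 1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            ANNModel(A=np.ones(3), B=np.ones((2, 3)), bi=np.ones(2), bii=0.0)


class TestJacobian:
    @staticmethod
    def _fd_jacobian(net, X, h=1e-6):
        from labferm.ann import _core_output, _pack

        theta = _pack(net.A, net.B, net.bi, net.bii)
        J = np.empty((X.shape[0], theta.size))
        for j in range(theta.size):
            up, dn = theta.copy(), theta.copy()
            up[j] += h
            dn[j] -= h
            J[:, j] = (_core_output(up, net.n_hidden, X, net.activation)[0]
                       - _core_output(dn, net.n_hidden, X, net.activation)[0]) / (2 * h)
        return J

    @pytest.mark.parametrize("activation", ["neg_half_tanh", "tanh"])
    def test_matches_central_differences(self, activation):
        """Analytic Jacobian vs finite differences on 50 random nets."""
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(1, 5))
            net = _raw_net(rng.normal(size=n), rng.normal(size=(n, 3)),
                           rng.normal(size=n), float(rng.normal()),
                           activation=activation)
            X = rng.uniform(-1, 1, size=(6, 3))
            J = ann.network_jacobian(net, X)
            J_fd = self._fd_jacobian(net, X)
            np.testing.assert_allclose(J, J_fd, rtol=2e-6, atol=2e-6)

    def test_bias_column_is_one(self):
        net = _raw_net([0.3, -0.1], np.ones((2, 3)), [0.2, 0.1], 1.0)
        J = ann.network_jacobian(net, np.zeros((4, 3)))
        np.testing.assert_array_equal(J[:, -1], 1.0)

    def test_zero_weights_A_columns_are_activation_of_bias(self):
        bi = np.array([0.5, -0.7])
        net = _raw_net([0.0, 0.0], np.zeros((2, 3)), bi, 0.0)
        J = ann.network_jacobian(net, np.random.default_rng(0).normal(size=(3, 3)))
        expected = -np.tanh(bi / 2.0)  # printed transfer at the bias
        np.testing.assert_allclose(J[:, :2], np.tile(expected, (3, 1)), rtol=1e-12)


class TestSplit:
    def test_75_25_counts(self):
        ds = _toy_dataset(lambda t, w, s: 7 + 0.1 * t, n=8)
        train, test = ann.split_systematic(ds, seed=0)
        assert (len(train), len(test)) == (6, 2)

    def test_interleaving_one_in_four(self):
        ds = _toy_dataset(lambda t, w, s: 7 + 0.1 * t, n=16, seed=3)
        train, test = ann.split_systematic(ds, seed=1)
        merged = np.concatenate([np.repeat("r", len(train)),
                                 np.repeat("e", len(test))])
        v = np.concatenate([train.viability, test.viability])
        labels = merged[np.argsort(v, kind="stable")]
        test_pos = np.flatnonzero(labels == "e")
        assert np.all(np.diff(test_pos) == 4)  # exactly 3 train rows between

    def test_determinism_and_offset_exhaustion(self):
        ds = _toy_dataset(lambda t, w, s: 7 + 0.1 * t, n=20, seed=4)
        a1 = ann.split_systematic(ds, seed=7)
        a2 = ann.split_systematic(ds, seed=7)
        assert a1[1].equals(a2[1])
        seen = set()
        for seed in range(40):
            _, test = ann.split_systematic(ds, seed=seed)
            seen.add(tuple(np.round(test.viability, 12)))
        assert len(seen) == 4  # offsets 0-3 exhaust the possible splits

    def test_too_small_raises(self):
        ds = _toy_dataset(lambda t, w, s: 7 + 0.1 * t, n=3)
        with pytest.raises(ValueError):
            ann.split_systematic(ds)


class TestTrainers:
    def test_lm_recovers_teacher_network(self):
        """LM from a start near a known 3-neuron teacher reaches the
        noiseless target to machine-level cost."""
        from labferm.ann import _core_output

        n = 3
        rng = np.random.default_rng(0)
        theta_init = rng.uniform(-0.5, 0.5, size=5 * n + 1)
        teacher = theta_init + 0.05 * np.random.default_rng(1).normal(
            size=theta_init.size)
        X = np.random.default_rng(2).uniform(-1, 1, size=(30, 3))
        t = _core_output(teacher, n, X, "tanh")[0]
        cfg = lf.TrainingConfig(method="levenberg_marquardt", neurons=n,
                                seed=0, max_epochs=400, scaling_mode="raw")
        from labferm.ann import _train_lm

        theta, costs, converged, _ = _train_lm(
            theta_init, n, X, t, cfg, "tanh")
        assert costs[-1] < 1e-8

    def test_lm_accepted_costs_non_increasing(self, lp_dataset):
        train_ds, _ = ann.split_systematic(lp_dataset, seed=0)
        cfg = lf.TrainingConfig(method="levenberg_marquardt", neurons=4,
                                seed=1, max_epochs=60)
        _, history = lf.train(train_ds, cfg)
        assert np.all(np.diff(history.costs) <= 0)

    @pytest.mark.parametrize("method", [
        "levenberg_marquardt", "quasi_newton_bfgs",
        "scaled_conjugate_gradient", "cg_fletcher", "cg_polak_ribiere"])
    def test_beats_linear_fit_on_linear_data(self, method):
        """A 6-neuron net trained on noisy linear data reaches a training
        MSE at or below the best linear fit (least-squares oracle)."""
        ds = _toy_dataset(lambda t, w, s: 7.0 + 0.1 * t, n=40, seed=5,
                          noise=0.05)
        X1 = np.column_stack([np.ones(len(ds)), ds.points[:, 0]])
        beta, *_ = np.linalg.lstsq(X1, ds.viability, rcond=None)
        lin_mse = float(np.mean((ds.viability - X1 @ beta) ** 2))
        cfg = lf.TrainingConfig(method=method, neurons=6, seed=0,
                                max_epochs=400)
        model, _ = lf.train(ds, cfg)
        net_mse = float(np.mean((model.predict(ds.points) - ds.viability) ** 2))
        assert net_mse <= lin_mse * (1 + 1e-6)

    @pytest.mark.parametrize("method", ann.METHODS)
    def test_all_trainers_reduce_cost_over_seed_battery(self, method):
        ds = _toy_dataset(lambda t, w, s: 7 + 0.1 * t + 0.002 * (t - 12) ** 2,
                          n=24, seed=6, noise=0.02)
        for seed in range(20):
            cfg = lf.TrainingConfig(method=method, neurons=3, seed=seed,
                                    max_epochs=25)
            _, history = lf.train(ds, cfg)
            assert history.costs[-1] < history.costs[0]

    def test_seeded_determinism_bitwise(self, lp_dataset):
        train_ds, _ = ann.split_systematic(lp_dataset, seed=2)
        cfg = lf.TrainingConfig(method="scaled_conjugate_gradient", neurons=4,
                                seed=3, max_epochs=40)
        m1, h1 = lf.train(train_ds, cfg)
        m2, h2 = lf.train(train_ds, cfg)
        assert np.array_equal(m1.A, m2.A) and np.array_equal(m1.B, m2.B)
        assert np.array_equal(m1.bi, m2.bi) and m1.bii == m2.bii
        assert h1.costs == h2.costs


class TestEvaluate:
    def test_perfect_predictions(self):
        ds = _toy_dataset(lambda t, w, s: 7 + 0.1 * t, n=10)
        reg = lf.load_reference_regression("Lp")
        # build a model whose predictions equal the observations exactly:
        # use the dataset's own generating rule through a fitted polynomial
        from labferm import rsm

        model, _ = rsm.fit_rsm(ds, [(0, 0, 0), (1, 0, 0)])
        metrics = ann.evaluate(_PolyAdapter(model), ds)
        assert metrics.mse == pytest.approx(0.0, abs=1e-20)
        assert metrics.r_value == pytest.approx(1.0, abs=1e-9)

    def test_constant_offset(self):
        ds = _toy_dataset(lambda t, w, s: 7 + 0.1 * t, n=12)
        from labferm import rsm

        model, _ = rsm.fit_rsm(ds, [(0, 0, 0), (1, 0, 0)])
        metrics = ann.evaluate(_PolyAdapter(model, offset=-0.5), ds)
        assert metrics.mse == pytest.approx(0.25, rel=1e-9)
        assert metrics.r_value == pytest.approx(1.0, abs=1e-9)

    def test_null_predictions_rarely_significant(self):
        """Predictions independent of the observations give p > 0.01 in at
        least 95 of 100 Monte-Carlo draws."""
        rng = np.random.default_rng(11)
        n, hits = 100, 0
        obs = rng.normal(9, 0.5, n)
        ds = _toy_dataset(lambda t, w, s: 8.0, n=n, seed=12)
        ds.df["viability_log10cfu_ml"] = obs
        ds2 = ViabilityDataset(ds.df)
        for _ in range(100):
            pred = rng.normal(9, 0.5, n)
            from scipy import stats

            p = stats.linregress(pred, ds2.viability).pvalue
            hits += p > 0.01
        assert hits >= 95

    def test_few_rows_p_undefined(self):
        ds = _toy_dataset(lambda t, w, s: 7 + 0.1 * t, n=2)
        net = lf.load_reference_ann("Lp")
        metrics = ann.evaluate(net, ds)
        assert math.isnan(metrics.p_value)


class _PolyAdapter:
    """Duck-typed model: polynomial predictions plus an optional offset."""

    def __init__(self, rsm_model, offset=0.0):
        self._m = rsm_model
        self._offset = offset

    def predict(self, pts):
        return self._m.predict(pts) + self._offset


class TestComparison:
    def test_winner_by_mse(self):
        cands = [
            ("quasi_newton/8", lf.FitMetrics(0.0523, 0.9825, 1e-15)),
            ("levenberg_marquardt/8", lf.FitMetrics(0.0014, 0.9994, 1e-29)),
            ("cg_fletcher/10", lf.FitMetrics(0.0113, 0.9955, 1e-20)),
        ]
        table = ann.model_comparison(cands)
        assert table.iloc[0]["model"] == "levenberg_marquardt/8"
        assert table.iloc[0]["mse"] == 0.0014

    def test_single_candidate_unchanged(self):
        table = ann.model_comparison([("only", lf.FitMetrics(0.1, 0.9, 0.01))])
        assert len(table) == 1 and table.iloc[0]["model"] == "only"

    def test_tie_broken_by_r(self):
        cands = [("a", lf.FitMetrics(0.01, 0.90, 0.1)),
                 ("b", lf.FitMetrics(0.01, 0.99, 0.1))]
        assert ann.model_comparison(cands).iloc[0]["model"] == "b"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ann.model_comparison([])
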