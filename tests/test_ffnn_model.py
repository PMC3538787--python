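import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from devtiming import (FFNNArch, FFNNParams, count_params, ffnn_design,
                       forward, penalized_loss, penalized_loss_grad,
                       predict_ffnn, train)


def random_params(arch, rng):
    return FFNNParams.from_flat(arch, rng.uniform(-1, 1, size=arch.n_params))


def zero_params(arch, output_bias=0.0):
    return FFNNParams(
        arch=arch,
        input_to_hidden=np.zeros((arch.hidden_units, arch.n_inputs)),
        hidden_biases=np.zeros(arch.hidden_units),
        hidden_to_output=np.zeros(arch.hidden_units),
        output_bias=output_bias,
        skip_weights=np.zeros(arch.n_inputs) if arch.skip else None,
    )


class TestCountParams:
    def test_empirical_scale_matches_fd_comparison(self):
        # 105 inputs (10 species + 95 events), one hidden unit, no skip
        assert count_params(105, 1, False) == 108

    def test_small_architecture(self):
        assert count_params(2, 1, False) == 5  # 1*3 + 2

    def test_skip_adds_one_weight_per_input(self):
        assert count_params(105, 1, True) == 213

    @given(st.integers(1, 200), st.integers(1, 8), st.booleans())
    def test_identity_matches_constructed_arrays(self, d, h, skip):
        arch = FFNNArch(n_inputs=d, hidden_units=h, skip=skip)
        p = zero_params(arch)
        assert p.flat().size == count_params(d, h, skip) == arch.n_params


class TestForward:
    def test_zero_weights_give_output_bias(self):
        arch = FFNNArch(n_inputs=4, hidden_units=3)
        p = zero_params(arch, output_bias=2.5)
        rows = np.eye(4)
        assert np.allclose(forward(p, rows), 2.5)

    def test_logistic_at_zero_is_half(self):
        arch = FFNNArch(n_inputs=2, hidden_units=1)
        p = zero_params(arch)
        p.hidden_to_output = np.array([2.0])
        assert forward(p, np.zeros((1, 2)))[0] == pytest.approx(1.0)

    def test_matches_scalar_loop_oracle(self, rng):
        arch = FFNNArch(n_inputs=6, hidden_units=3, skip=True)
        p = random_params(arch, rng)
        rows = rng.integers(0, 2, size=(10, 6)).astype(float)
        got = forward(p, rows)
        for n in range(10):
            out = p.output_bias
            for j in range(3):
                z = p.hidden_biases[j]
                for i in range(6):
                    z += p.input_to_hidden[j, i] * rows[n, i]
                out += p.hidden_to_output[j] * (1.0 / (1.0 + np.exp(-z)))
            for i in range(6):
                out += p.skip_weights[i] * rows[n, i]
            assert got[n] == pytest.approx(out, abs=1e-12)

    def test_width_mismatch_rejected(self):
        arch = FFNNArch(n_inputs=4, hidden_units=1)
        with pytest.raises(ValueError, match="n_inputs"):
            forward(zero_params(arch), np.zeros((2, 3)))


class TestPenalizedLoss:
    def test_perfect_fit_zero_decay_is_zero(self):
        arch = FFNNArch(n_inputs=3, hidden_units=1, decay=0.0)
        p = zero_params(arch, output_bias=1.5)
        rows = np.eye(3)
        targets = np.full(3, 1.5)
        assert penalized_loss(p, rows, targets) == 0.0

    def test_zero_decay_reduces_to_sse(self, rng):
        arch = FFNNArch(n_inputs=5, hidden_units=2, decay=0.0)
        p = random_params(arch, rng)
        rows = rng.integers(0, 2, size=(8, 5)).astype(float)
        targets = rng.normal(size=8)
        resid = forward(p, rows) - targets
        assert penalized_loss(p, rows, targets) == pytest.approx(resid @ resid)

    def test_decay_adds_squared_parameter_norm(self, rng):
        arch = FFNNArch(n_inputs=5, hidden_units=2, decay=0.0)
        p = random_params(arch, rng)
        rows = rng.integers(0, 2, size=(8, 5)).astype(float)
        targets = rng.normal(size=8)
        sse = penalized_loss(p, rows, targets)
        theta = p.flat()
        assert penalized_loss(p, rows, targets, decay=0.3) == pytest.approx(
            sse + 0.3 * theta @ theta)

    @pytest.mark.parametrize("skip", [False, True])
    def test_gradient_matches_finite_differences(self, skip, rng):
        arch = FFNNArch(n_inputs=4, hidden_units=2, skip=skip, decay=0.07)
        p = random_params(arch, rng)
        rows = rng.integers(0, 2, size=(12, 4)).astype(float)
        targets = rng.normal(loc=2.0, size=12)
        analytic = penalized_loss_grad(p, rows, targets)
        theta = p.flat()
        eps = 1e-6
        for idx in range(theta.size):
            up, dn = theta.copy(), theta.copy()
            up[idx] += eps
            dn[idx] -= eps
            fd = (penalized_loss(FFNNParams.from_flat(arch, up), rows, targets)
                  - penalized_loss(FFNNParams.from_flat(arch, dn), rows, targets)
                  ) / (2 * eps)
            assert analytic[idx] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestTrain:
    def test_realizable_linear_target_fits_exactly(self, rng):
        # with a skip layer the network contains the linear map exactly
        arch = FFNNArch(n_inputs=5, hidden_units=1, skip=True, decay=1e-6)
        rows = rng.integers(0, 2, size=(20, 5)).astype(float)
        w = rng.normal(size=5)
        targets = rows @ w + 0.7
        p = train(rows, targets, arch, seed=0)
        resid = forward(p, rows) - targets
        assert resid @ resid < 1e-6

    def test_deterministic_given_seed(self, rng):
        arch = FFNNArch(n_inputs=4, hidden_units=2, decay=0.01)
        rows = rng.integers(0, 2, size=(15, 4)).astype(float)
        targets = rng.normal(loc=3.0, size=15)
        p1 = train(rows, targets, arch, seed=123)
        p2 = train(rows, targets, arch, seed=123)
        assert np.array_equal(p1.flat(), p2.flat())

    def test_beats_random_search(self, rng):
        arch = FFNNArch(n_inputs=4, hidden_units=1, decay=0.05)
        rows = rng.integers(0, 2, size=(15, 4)).astype(float)
        targets = rng.normal(loc=3.0, size=15)
        p = train(rows, targets, arch, seed=5)
        trained = penalized_loss(p, rows, targets)
        draws = np.random.default_rng(99)
        for _ in range(100):
            q = FFNNParams.from_flat(arch, draws.uniform(-0.5, 0.5, arch.n_params))
            assert trained <= penalized_loss(q, rows, targets)

    def test_too_few_rows_rejected(self):
        arch = FFNNArch(n_inputs=2, hidden_units=1)
        with pytest.raises(ValueError):
            train(np.ones((1, 2)), np.ones(1), arch, seed=0)


class TestPredict:
    def test_zero_network_predicts_one_day(self, tiny_table):
        design = ffnn_design(tiny_table)
        arch = FFNNArch(n_inputs=design.n_cols, hidden_units=1)
        p = zero_params(arch)
        assert predict_ffnn(p, design, "rat", "ev2") == pytest.approx(1.0)

    def test_predictions_positive(self, tiny_table, rng):
        design = ffnn_design(tiny_table)
        arch = FFNNArch(n_inputs=design.n_cols, hidden_units=2, skip=True)
        p = random_params(arch, rng)
        for sp in tiny_table.species:
            for ev in tiny_table.events:
                assert predict_ffnn(p, design, sp, ev) > 0

    def test_heldout_recovery_on_skip_representable_data(self, dense_noiseless):
        # noiseless additive log structure is exactly representable by the
        # skip layer; held-out prediction should be within 1% relative
        table, truth, spec = dense_noiseless
        held = table.data.iloc[11]
        fold = table.drop_observation(held["species"], held["event"])
        design = ffnn_design(fold)
        arch = FFNNArch(n_inputs=design.n_cols, hidden_units=1, skip=True,
                        decay=1e-8)
        # response here is total ln(pc), not ln(pc - k): use a k-free truth
        y = np.log(fold.data["pc_day"].to_numpy())
        best = None
        for r in range(3):
            p = train(design.X, y, arch, seed=r)
            loss = penalized_loss(p, design.X, y)
            if best is None or loss < best[0]:
                best = (loss, p)
        pred = predict_ffnn(best[1], design, held["species"], held["event"])
        assert pred == pytest.approx(held["pc_day"], rel=0.05)


class TestStructuralProperties:
    def test_linear_limit_matches_ols(self, rng):
        # hidden-to-output weight clamped to 0, skip on, decay 0: the model
        # IS an ordinary linear regression and must match OLS fitted values
        rows = rng.integers(0, 2, size=(25, 6)).astype(float)
        w = rng.normal(size=6)
        targets = rows @ w + rng.normal(scale=0.1, size=25)
        arch = FFNNArch(n_inputs=6, hidden_units=1, skip=True, decay=0.0)
        bounds = [(None, None)] * arch.n_params
        bounds[6 * 1 + 1] = (0.0, 0.0)  # v_1, after W (6) and b (1)
        p = train(rows, targets, arch, seed=1, max_iter=10000, tol=1e-16,
                  bounds=bounds)
        Xa = np.column_stack([rows, np.ones(len(rows))])
        beta, *_ = np.linalg.lstsq(Xa, targets, rcond=None)
        ols_fit = Xa @ beta
        assert np.allclose(forward(p, rows), ols_fit, atol=1e-6)

    def test_sse_nondecreasing_in_decay(self, rng):
        rows = rng.integers(0, 2, size=(20, 5)).astype(float)
        targets = rows @ rng.normal(size=5) + rng.normal(scale=0.2, size=20)
        sses = []
        for lam in [0.0, 0.01, 0.05, 0.1]:
            arch = FFNNArch(n_inputs=5, hidden_units=1, decay=lam)
            p = train(rows, targets, arch, seed=7)
            resid = forward(p, rows) - targets
            sses.append(resid @ resid)
        assert all(a <= b + 1e-9 for a, b in zip(sses, sses[1:]))

    def test_invalid_arch_rejected(self):
        with pytest.raises(ValueError):
            FFNNArch(n_inputs=3, hidden_units=0)
        with pytest.raises(ValueError):
            FFNNArch(n_inputs=3, hidden_units=1, decay=-0.1)
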