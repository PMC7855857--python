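import numpy as np
import pytest

from survnet import (
    ArchitectureConfig,
    cox_loss,
    init_model,
    load_checkpoint,
    save_checkpoint,
)
from survnet.network import coxnet_baseline_config
from survnet.losses import (
    classification_loss,
    classification_loss_grad,
    classification_targets,
    cox_loss_grad,
    reconstruction_loss,
    reconstruction_loss_grad,
)


class TestArchitectureConfig:
    def test_defaults_match_declared_layout(self):
        arch = ArchitectureConfig()
        assert (arch.input_dim, arch.encoder_units, arch.hidden_units) == (9, 64, 32)
        assert arch.use_batchnorm and arch.dropout_rate == 0.0

    def test_gating_requires_classification(self):
        with pytest.raises(ValueError, match="gating"):
            ArchitectureConfig(use_classification=False, use_gating=True)

    def test_invalid_dropout(self):
        with pytest.raises(ValueError):
            ArchitectureConfig(dropout_rate=1.0)


class TestInitModel:
    def test_deterministic(self, default_arch):
        a = init_model(default_arch, seed=3)
        b = init_model(default_arch, seed=3)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])
        c = init_model(default_arch, seed=4)
        assert any(not np.array_equal(a.params[k], c.params[k]) for k in a.params)

    def test_ablation_drops_decoder(self):
        arch = ArchitectureConfig(use_reconstruction=False)
        model = init_model(arch, seed=0)
        assert "Wd" not in model.params and "bd" not in model.params

    def test_parameter_count_closed_form(self, default_arch):
        # hand count: We 9*64+64, Wd 64*9+9, bn 64+64, W3 64*32+32,
        # Wc 32+1, Wp 32+1
        model = init_model(default_arch, seed=0)
        expected = (9 * 64 + 64) + (64 * 9 + 9) + (64 + 64) + (64 * 32 + 32) + 33 + 33
        assert model.n_parameters() == expected == 3499

    def test_no_bias_mode(self):
        model = init_model(ArchitectureConfig(bias_terms=False), seed=0)
        assert not any(k in model.params for k in ("be", "bd", "b3", "bc", "bp"))


class TestForward:
    def test_output_ranges(self, small_cohort, default_arch):
        model = init_model(default_arch, seed=1).eval_mode()
        out = model.forward(small_cohort.X)
        assert np.all((out.a_c > 0) & (out.a_c < 1))
        assert np.all(np.isfinite(out.p_x))
        assert out.x_star.shape == small_cohort.X.shape

    def test_gating_is_elementwise_product(self, small_cohort, default_arch):
        model = init_model(default_arch, seed=1).eval_mode()
        out = model.forward(small_cohort.X)
        np.testing.assert_allclose(out.p_x, out.a_p * out.a_c)

    def test_gating_hand_value(self):
        # a_p = 2, a_c = 0.5 -> p_x = 1
        assert 2.0 * 0.5 == 1.0  # the contract itself
        model = init_model(ArchitectureConfig(), seed=2).eval_mode()
        out = model.forward(np.zeros((3, 9)))
        np.testing.assert_allclose(out.p_x, out.a_p * out.a_c)

    def test_gating_disabled_passthrough(self, small_cohort):
        arch = ArchitectureConfig(use_gating=False)
        model = init_model(arch, seed=1).eval_mode()
        out = model.forward(small_cohort.X)
        np.testing.assert_array_equal(out.p_x, out.a_p)

    def test_saturated_gate_identity(self, small_cohort, default_arch):
        model = init_model(default_arch, seed=1).eval_mode()
        model.params["bc"] = np.array([50.0])  # saturate sigmoid -> a_c ~ 1
        model.params["Wc"][:] = 0.0
        out = model.forward(small_cohort.X)
        np.testing.assert_allclose(out.p_x, out.a_p, rtol=1e-12)

    def test_all_zero_row_is_total(self, default_arch):
        model = init_model(default_arch, seed=5).eval_mode()
        out = model.forward(np.zeros((1, 9)))
        assert np.isfinite(out.p_x).all()
        assert 0 < out.a_c[0] < 1

    def test_shape_mismatch_errors(self, default_arch):
        model = init_model(default_arch, seed=0)
        with pytest.raises(ValueError, match="shape"):
            model.forward(np.zeros((4, 5)))

    def test_single_row_training_batch_rejected(self, default_arch):
        model = init_model(default_arch, seed=0).train_mode()
        with pytest.raises(ValueError, match="batch size"):
            model.forward(np.zeros((1, 9)))

    def test_inference_batch_size_invariant(self, small_cohort, default_arch):
        model = init_model(default_arch, seed=6).eval_mode()
        X = small_cohort.X
        full = model.forward(X).p_x
        split = np.concatenate(
            [model.forward(X[:7]).p_x, model.forward(X[7:]).p_x]
        )
        np.testing.assert_allclose(full, split, atol=1e-12)

    def test_inference_deterministic_with_dropout_configured(self, small_cohort):
        arch = ArchitectureConfig(dropout_rate=0.5)
        model = init_model(arch, seed=6).eval_mode()
        a = model.forward(small_cohort.X).p_x
        b = model.forward(small_cohort.X).p_x
        np.testing.assert_array_equal(a, b)

    def test_outputs_finite_for_extreme_inputs(self, default_arch):
        model = init_model(default_arch, seed=7).eval_mode()
        X = np.full((4, 9), 1e6)
        out = model.forward(X)
        for arr in (out.x_star, out.a_c, out.a_p, out.p_x):
            assert np.all(np.isfinite(arr))


class TestBackward:
    """Finite-difference check of the full reverse pass through the
    multi-task objective."""

    def _objective(self, model, X, R, t, s, weights):
        out = model.forward(X)
        tg = classification_targets(t, s, weights["T"])
        return (
            weights["alpha"] * cox_loss(out.p_x, t, s)
            + weights["beta"] * classification_loss(out.a_c, tg)
            + weights["gamma"] * reconstruction_loss(X, out.x_star, R)
        )

    @pytest.mark.parametrize("use_batchnorm", [True, False])
    def test_gradients_match_finite_differences(self, use_batchnorm, rng):
        arch = ArchitectureConfig(
            input_dim=4, encoder_units=6, hidden_units=3,
            use_batchnorm=use_batchnorm,
        )
        model = init_model(arch, seed=8).train_mode()
        n = 12
        X = rng.normal(size=(n, 4))
        R = (rng.uniform(size=(n, 4)) > 0.3).astype(float)
        X = X * R
        t = rng.integers(1, 60, size=n).astype(float)
        s = (rng.uniform(size=n) < 0.6).astype(float)
        s[0] = 1.0
        weights = {"alpha": 0.2, "beta": 1.0, "gamma": 3.0, "T": 36.0}

        out, cache = model.forward(X, return_cache=True)
        tg = classification_targets(t, s, weights["T"])
        d_px = weights["alpha"] * cox_loss_grad(out.p_x, t, s)
        d_ac = weights["beta"] * classification_loss_grad(out.a_c, tg)
        d_xstar = weights["gamma"] * reconstruction_loss_grad(X, out.x_star, R)
        grads = model.backward(cache, d_px, d_xstar=d_xstar, d_ac=d_ac)

        h = 1e-6
        bn_mean = model.bn_state["running_mean"].copy()
        bn_var = model.bn_state["running_var"].copy()
        for key in grads:
            flat = model.params[key].ravel()
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                model.bn_state["running_mean"] = bn_mean.copy()
                model.bn_state["running_var"] = bn_var.copy()
                up = self._objective(model, X, R, t, s, weights)
                flat[idx] = orig - h
                model.bn_state["running_mean"] = bn_mean.copy()
                model.bn_state["running_var"] = bn_var.copy()
                down = self._objective(model, X, R, t, s, weights)
                flat[idx] = orig
                fd = (up - down) / (2 * h)
                np.testing.assert_allclose(
                    fd, grads[key].ravel()[idx], atol=5e-5,
                    err_msg=f"gradient mismatch for {key}[{idx}]",
                )


class TestCoxNetBaseline:
    def test_reduction_to_baseline(self, small_cohort):
        """With reconstruction/classification/gating off, the model is the
        plain Cox backbone: encoder -> batchnorm -> hidden -> linear head."""
        arch = coxnet_baseline_config(ArchitectureConfig())
        model = init_model(arch, seed=9).eval_mode()
        out = model.forward(small_cohort.X)
        assert out.x_star is None and out.a_c is None
        np.testing.assert_array_equal(out.p_x, out.a_p)

        # standalone minimal reimplementation on the same fixed weights
        P = model.params
        mu = model.bn_state["running_mean"]
        var = model.bn_state["running_var"]
        a2 = np.tanh(small_cohort.X @ P["We"] + P["be"])
        a3 = P["bn_gamma"] * (a2 - mu) / np.sqrt(var + 1e-5) + P["bn_beta"]
        a4 = np.tanh(a3 @ P["W3"] + P["b3"])
        a_p = (a4 @ P["Wp"] + P["bp"])[:, 0]
        np.testing.assert_allclose(out.p_x, a_p, atol=1e-12)
        np.testing.assert_allclose(
            cox_loss(out.p_x, small_cohort.t, small_cohort.s),
            cox_loss(a_p, small_cohort.t, small_cohort.s),
            atol=1e-12,
        )


class TestCheckpoint:
    def test_round_trip_bit_identical(self, tmp_path, small_cohort, default_arch):
        model = init_model(default_arch, seed=10).eval_mode()
        before = model.forward(small_cohort.X).p_x
        path = tmp_path / "model.json"
        save_checkpoint(model, path,
                        standardization_stats=small_cohort.standardization_stats,
                        schema=small_cohort.schema)
        restored, stats, schema = load_checkpoint(path)
        after = restored.forward(small_cohort.X).p_x
        np.testing.assert_array_equal(before, after)
        assert stats.location == small_cohort.standardization_stats.location
        assert schema.names == small_cohort.schema.names
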