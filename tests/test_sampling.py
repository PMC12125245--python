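"""Reverse-sampling strategies: determinism, equivalences, and the
reproducibility (seed-lineage) contract."""

import numpy as np
import pytest

from stainbridge import make_schedule
from stainbridge.network import DenoiserConfig, build_denoiser
from stainbridge.sampling import (SamplingConfig, average_inferences,
                                  mean_step, repeat_inferences, rng_for,
                                  run_reverse, run_reverse_batch, skip_exit,
                                  vanilla_step)


class StubModel:
    """Model stand-in with a prescribed error function (e.g. the exact
    forward error when x0 is known); mimics the DenoiserModel surface."""

    def __init__(self, err_fn, af_channels=3):
        self.err_fn = err_fn
        self.normalization_spec = {"target_offset": 0.0, "target_scale": 1.0}
        self.config = type("C", (), {"af_channels": af_channels})()

    def predict_error(self, x_t, y, t):
        return np.asarray(self.err_fn(np.asarray(x_t), np.asarray(y), t),
                          dtype=np.float32)

    def dimension_match(self, y0):
        return np.asarray(y0, dtype=np.float32)


def small_model(seed=0):
    cfg = DenoiserConfig(levels=2, base_channels=4, channel_mult=(1, 2),
                         attention_heads=2, time_embed_dim=8, fc_hidden=4,
                         attention_levels=(2,), res_convs=1, af_channels=4)
    m = build_denoiser(cfg, seed=seed)
    m.t_max = 40
    return m


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SamplingConfig(strategy="nope")
        with pytest.raises(ValueError):
            SamplingConfig(n_avg=0)
        with pytest.raises(ValueError):
            SamplingConfig(t_e=0)
        sch = make_schedule(40)
        with pytest.raises(ValueError):
            SamplingConfig(t_e=41).validate_against(sch)


class TestSteps:
    def test_vanilla_with_zeroed_noise_equals_mean_step(self):
        sch = make_schedule(40).without_noise()
        model = StubModel(lambda x, y, t: 0.2 * x + 0.1 * y)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 8, 8)).astype(np.float32)
        y = rng.normal(size=(3, 8, 8)).astype(np.float32)
        for t in (1, 7, 39, 40):
            np.testing.assert_array_equal(
                vanilla_step(x, y, t, model, sch, rng_for(0, 1, t)),
                mean_step(x, y, t, model, sch))

    def test_same_rng_state_means_identical_outputs(self):
        sch = make_schedule(40)
        model = StubModel(lambda x, y, t: np.zeros_like(x))
        x = np.ones((3, 8, 8), np.float32)
        y = np.zeros((3, 8, 8), np.float32)
        a = vanilla_step(x, y, 20, model, sch, rng_for(3, 1, 20))
        b = vanilla_step(x, y, 20, model, sch, rng_for(3, 1, 20))
        np.testing.assert_array_equal(a, b)
        c = vanilla_step(x, y, 20, model, sch, rng_for(3, 2, 20))
        assert not np.array_equal(a, c)

    def test_vanilla_step_moments_match_transition_law(self):
        """With a frozen error field, draws over many pixels have mean
        mu'_t and variance delta_tilde_t within 3 SE."""
        sch = make_schedule(100)
        model = StubModel(lambda x, y, t: np.full_like(x, 0.25))
        n = 400
        x = np.full((3, n, n), 0.8, np.float32)
        y = np.full((3, n, n), -0.4, np.float32)
        t = 50
        out = vanilla_step(x, y, t, model, sch, rng_for(1, 1, t))
        c_x, c_y, c_eps = sch.posterior_coefficients(t)
        mu = c_x * 0.8 + c_y * (-0.4) - c_eps * 0.25
        var = sch.delta_tilde[t]
        n_draws = out.size
        assert abs(out.mean() - mu) < 3 * np.sqrt(var / n_draws)
        assert abs(out.var(ddof=1) - var) < 3 * var * np.sqrt(2 / n_draws)

    def test_no_step_below_one(self):
        sch = make_schedule(10)
        model = StubModel(lambda x, y, t: np.zeros_like(x))
        x = np.zeros((3, 4, 4), np.float32)
        with pytest.raises(ValueError):
            vanilla_step(x, x, 0, model, sch, rng_for(0, 1, 0))
        with pytest.raises(ValueError):
            mean_step(x, x, 0, model, sch)

    def test_mean_step_telescopes_to_x0_with_exact_error(self):
        sch = make_schedule(60)
        rng = np.random.default_rng(5)
        x0 = rng.normal(size=(3, 6, 6)).astype(np.float32)
        model = StubModel(lambda x, y, t: x - x0)
        y = rng.normal(size=(3, 6, 6)).astype(np.float32)
        t_e = 30
        x = ((1 - sch.m[t_e]) * x0 + sch.m[t_e] * y).astype(np.float32)
        for t in range(t_e, 0, -1):
            x = mean_step(x, y, t, model, sch)
        np.testing.assert_allclose(x, x0, atol=1e-5)

    def test_skip_exit_exact_and_deterministic(self):
        rng = np.random.default_rng(2)
        x0 = rng.normal(size=(3, 5, 5)).astype(np.float32)
        model = StubModel(lambda x, y, t: x - x0)
        x_te = rng.normal(size=(3, 5, 5)).astype(np.float32)
        y = rng.normal(size=(3, 5, 5)).astype(np.float32)
        out = skip_exit(x_te, 13, y, model)
        np.testing.assert_allclose(out, x0, atol=1e-6)
        np.testing.assert_array_equal(out, skip_exit(x_te, 13, y, model))


class TestRunReverse:
    def test_noiseless_strategy_ignores_seed(self):
        model = small_model()
        sch = make_schedule(40)
        y0 = np.random.default_rng(1).normal(
            size=(4, 16, 16)).astype(np.float32)
        cfg_a = SamplingConfig(strategy="mean", t_e=40, base_seed=1)
        cfg_b = SamplingConfig(strategy="mean", t_e=40, base_seed=999)
        a = run_reverse(y0, model, sch, cfg_a)
        b = run_reverse(y0, model, sch, cfg_b)
        np.testing.assert_array_equal(a, b)
        assert a.dtype == np.uint8 and a.shape == (3, 16, 16)

    def test_vanilla_reproducible_and_seed_sensitive(self):
        model = small_model()
        sch = make_schedule(40)
        y0 = np.random.default_rng(1).normal(
            size=(4, 16, 16)).astype(np.float32)
        cfg = SamplingConfig(strategy="vanilla", base_seed=7)
        a = run_reverse(y0, model, sch, cfg, run_index=1)
        np.testing.assert_array_equal(
            a, run_reverse(y0, model, sch, cfg, run_index=1))
        b = run_reverse_batch(y0, model, sch, cfg, [2])
        assert not np.array_equal(a, np.clip(np.rint(b[0]), 0, 255))

    def test_mean_and_skip_depend_only_on_stochastic_segment(self):
        """Two runs with the same noise above t_e give identical mean /
        skip outputs (they are deterministic below the exit point)."""
        model = small_model()
        sch = make_schedule(40)
        y0 = np.random.default_rng(4).normal(
            size=(4, 16, 16)).astype(np.float32)
        for strat in ("mean", "skip"):
            cfg = SamplingConfig(strategy=strat, t_e=10, base_seed=3)
            a = run_reverse(y0, model, sch, cfg, run_index=5)
            b = run_reverse(y0, model, sch, cfg, run_index=5)
            np.testing.assert_array_equal(a, b)

    def test_strategy_nesting_identity(self):
        """Vanilla with all step noise zeroed, mean with t_e = T and the
        noiseless trajectory coincide bit for bit."""
        model = small_model()
        sch = make_schedule(40)
        y0 = np.random.default_rng(6).normal(
            size=(4, 16, 16)).astype(np.float32)
        van = run_reverse_batch(y0, model, sch.without_noise(),
                                SamplingConfig(strategy="vanilla",
                                               base_seed=1), [1])
        mean = run_reverse_batch(y0, model, sch,
                                 SamplingConfig(strategy="mean", t_e=40,
                                                base_seed=2), [9])
        np.testing.assert_array_equal(van, mean)


class TestAveraging:
    def test_single_average_equals_single_run(self):
        model = small_model()
        sch = make_schedule(40)
        y0 = np.random.default_rng(0).normal(
            size=(4, 16, 16)).astype(np.float32)
        cfg = SamplingConfig(strategy="vanilla", n_avg=1, base_seed=11)
        np.testing.assert_array_equal(
            average_inferences(y0, model, sch, cfg),
            run_reverse(y0, model, sch, cfg, run_index=1))

    def test_deterministic_strategy_average_equals_any_run(self):
        model = small_model()
        sch = make_schedule(40)
        y0 = np.random.default_rng(0).normal(
            size=(4, 16, 16)).astype(np.float32)
        cfg = SamplingConfig(strategy="mean", t_e=40, n_avg=3, base_seed=1)
        np.testing.assert_array_equal(
            average_inferences(y0, model, sch, cfg),
            run_reverse(y0, model, sch, cfg, run_index=2))

    def test_repeat_blocks_use_disjoint_runs(self):
        """repeat_inferences(k reps of n_avg) consumes k * n_avg distinct
        run indices: repeats differ for a stochastic strategy."""
        model = small_model()
        sch = make_schedule(40)
        y0 = np.random.default_rng(0).normal(
            size=(4, 16, 16)).astype(np.float32)
        cfg = SamplingConfig(strategy="vanilla", n_avg=2, base_seed=5)
        reps = repeat_inferences(y0, model, sch, cfg, n_repeats=3)
        assert reps.shape == (3, 3, 16, 16)
        assert not np.array_equal(reps[0], reps[1])
        # block 1 equals the average over run indices 1..2 computed directly
        direct = run_reverse_batch(y0, model, sch, cfg, [1, 2]).mean(axis=0)
        np.testing.assert_array_equal(
            reps[0], np.clip(np.rint(direct), 0, 255).astype(np.uint8))

    def test_averaging_count_validation(self):
        with pytest.raises(ValueError):
            SamplingConfig(strategy="vanilla", n_avg=0)
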