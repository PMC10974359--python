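import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dhmkit.diffusion import (
    DiffusionConfig,
    HeightScaler,
    build_schedule,
    denoise_profile,
    kl_gaussian,
    load_model,
    losses,
    posterior_mean,
    predict_x0,
    q_sample,
    q_step,
    reverse_sample,
    save_model,
    train_conditional_denoiser,
)


class TestSchedule:
    def test_constant_beta_has_closed_form_alpha_bar(self):
        sched = build_schedule(20, kind="linear", beta_min=0.05, beta_max=0.05)
        assert np.allclose(sched.alpha_bars, 0.95 ** np.arange(1, 21), rtol=1e-12)

    @given(
        st.integers(1, 60),
        st.floats(1e-5, 0.3),
        st.floats(1e-5, 0.3),
    )
    @settings(derandomize=True, max_examples=60)
    def test_alpha_bar_strictly_decreasing(self, T, b1, b2):
        lo, hi = sorted((b1, b2))
        sched = build_schedule(T, kind="linear", beta_min=lo, beta_max=hi)
        assert np.all(np.diff(sched.alpha_bars) < 0)

    def test_cosine_schedule_reaches_near_zero_terminal(self):
        sched = build_schedule(50, kind="cosine")
        assert sched.alpha_bars[-1] < 1e-3
        assert np.all((sched.betas > 0) & (sched.betas < 1))

    @pytest.mark.parametrize("bad", [(0, "linear"), (10, "warped")])
    def test_invalid_requests_rejected(self, bad):
        T, kind = bad
        with pytest.raises(ValueError):
            build_schedule(T, kind=kind)

    def test_unit_beta_rejected(self):
        with pytest.raises(ValueError):
            build_schedule(10, kind="linear", beta_min=0.1, beta_max=1.0)


class TestForwardProcess:
    def test_tiny_beta_keeps_signal(self, rng):
        sched = build_schedule(5, kind="linear", beta_min=1e-9, beta_max=1e-9)
        x0 = rng.normal(size=(8, 8))
        x_t = q_sample(x0, 5, sched, rng.standard_normal((8, 8)))
        assert np.allclose(x_t, x0, atol=1e-3)

    def test_zero_signal_scales_noise_exactly(self, rng):
        sched = build_schedule(30, kind="cosine")
        eps = rng.standard_normal((8, 8))
        x_t = q_sample(np.zeros((8, 8)), 17, sched, eps)
        assert np.allclose(x_t, np.sqrt(1 - sched.alpha_bars[16]) * eps, rtol=1e-12)

    def test_marginal_moments_match_monte_carlo(self, rng):
        """Eq-by-step composition and the closed-form marginal agree on the
        first two moments within Monte-Carlo error."""
        sched = build_schedule(8, kind="linear", beta_min=0.02, beta_max=0.2)
        x0 = 0.7
        n = 100_000
        # compose single steps
        x = np.full(n, x0)
        for t in range(1, 9):
            x = q_step(x, t, sched, rng.standard_normal(n))
        ab = sched.alpha_bars[-1]
        se_mean = np.sqrt((1 - ab) / n)
        assert abs(x.mean() - np.sqrt(ab) * x0) < 3 * se_mean
        assert x.var() == pytest.approx(1 - ab, rel=0.05)

    def test_single_step_variance_matches_beta(self, rng):
        sched = build_schedule(10, kind="linear", beta_min=0.05, beta_max=0.15)
        x_prev = np.zeros(50_000)
        x_t = q_step(x_prev, 4, sched, rng.standard_normal(50_000))
        assert x_t.var() == pytest.approx(sched.betas[3], rel=0.05)

    def test_step_out_of_range_rejected(self, rng):
        sched = build_schedule(10, kind="cosine")
        with pytest.raises(ValueError, match="range"):
            q_sample(np.zeros((4, 4)), 11, sched, np.zeros((4, 4)))
        with pytest.raises(ValueError, match="range"):
            q_step(np.zeros((4, 4)), 0, sched, np.zeros((4, 4)))


class TestPredictX0:
    def test_exact_inverse_of_q_sample(self, rng):
        sched = build_schedule(50, kind="cosine")
        x0 = rng.normal(size=(16, 16))
        for t in (1, 25, 50):
            eps = rng.standard_normal((16, 16))
            x_t = q_sample(x0, t, sched, eps)
            assert np.allclose(predict_x0(x_t, t, eps, sched), x0, atol=1e-10)

    def test_zero_predicted_noise_rescales_x_t(self, rng):
        sched = build_schedule(20, kind="cosine")
        x_t = rng.normal(size=(8, 8))
        out = predict_x0(x_t, 10, np.zeros((8, 8)), sched)
        assert np.allclose(out, x_t / np.sqrt(sched.alpha_bars[9]), rtol=1e-12)

    def test_matches_direct_formula_on_random_inputs(self, rng):
        sched = build_schedule(30, kind="linear", beta_min=0.01, beta_max=0.2)
        x_t = rng.normal(size=(6, 6))
        eps_hat = rng.normal(size=(6, 6))
        t = 12
        ab = sched.alpha_bars[t - 1]
        direct = (x_t - np.sqrt(1 - ab) * eps_hat) / np.sqrt(ab)
        assert np.allclose(predict_x0(x_t, t, eps_hat, sched), direct, rtol=1e-13)


class TestKL:
    def test_identical_gaussians_have_zero_kl(self):
        assert kl_gaussian(1.3, 0.5, 1.3, 0.5) == pytest.approx(0.0, abs=1e-14)

    def test_unit_shift_standard_gaussians(self):
        assert kl_gaussian(0.0, 1.0, 1.0, 1.0) == pytest.approx(0.5, rel=1e-12)

    def test_matches_numerical_quadrature(self):
        from scipy.integrate import quad

        m1, v1, m2, v2 = 0.3, 0.8, -0.5, 1.7

        def integrand(x):
            q = np.exp(-((x - m1) ** 2) / (2 * v1)) / np.sqrt(2 * np.pi * v1)
            p = np.exp(-((x - m2) ** 2) / (2 * v2)) / np.sqrt(2 * np.pi * v2)
            return q * np.log(q / p)

        numeric, _ = quad(integrand, -20, 20)
        assert kl_gaussian(m1, v1, m2, v2) == pytest.approx(numeric, abs=1e-6)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            kl_gaussian(0.0, 0.0, 0.0, 1.0)


class TestLosses:
    def test_perfect_prediction_zeroes_simple_loss(self, rng):
        sched = build_schedule(50, kind="cosine")
        x0 = np.clip(rng.normal(0, 0.4, (12, 12)), -1, 1)
        eps = rng.standard_normal((12, 12))
        report = losses(x0, 20, eps, eps, sched)
        assert report.l_simple == 0.0
        # with matched means the KL reduces to the pure variance-ratio term
        beta = sched.betas[19]
        ab_t, ab_prev = sched.alpha_bars[19], sched.alpha_bars[18]
        var_q = (1 - ab_prev) / (1 - ab_t) * beta
        expected = 0.5 * (np.log(beta / var_q) + var_q / beta - 1.0)
        assert report.l_vlb_term == pytest.approx(expected, rel=1e-9)

    def test_simple_loss_is_mean_squared_difference(self, rng):
        sched = build_schedule(10, kind="cosine")
        x0 = np.zeros((8, 8))
        eps = rng.standard_normal((8, 8))
        eps_hat = rng.standard_normal((8, 8))
        report = losses(x0, 5, eps, eps_hat, sched)
        assert report.l_simple == pytest.approx(float(np.mean((eps - eps_hat) ** 2)), rel=1e-14)
        assert report.hybrid == pytest.approx(
            report.l_simple + report.lambda_kl * report.l_vlb_term, rel=1e-12
        )

    def test_terminal_kl_vanishes_when_alpha_bar_reaches_zero(self, rng):
        x0 = np.clip(rng.normal(0, 0.4, (8, 8)), -1, 1)
        eps = rng.standard_normal((8, 8))
        short = build_schedule(5, kind="linear", beta_min=0.01, beta_max=0.05)
        long = build_schedule(400, kind="cosine")
        r_short = losses(x0, 2, eps, eps, short)
        r_long = losses(x0, 2, eps, eps, long)
        assert r_long.l_terminal < 1e-6 < r_short.l_terminal

    def test_shape_mismatch_rejected(self):
        sched = build_schedule(10, kind="cosine")
        with pytest.raises(ValueError, match="shape"):
            losses(np.zeros((4, 4)), 3, np.zeros((4, 4)), np.zeros((4, 5)), sched)


def _toy_pairs(rng, n, size=16, noise=0.6):
    clean = []
    for _ in range(n):
        x = np.linspace(-1, 1, size)
        xx, yy = np.meshgrid(x, x)
        cx, cy = rng.uniform(-0.3, 0.3, 2)
        r = rng.uniform(0.4, 0.7)
        bump = np.sqrt(np.clip(1 - ((xx - cx) ** 2 + (yy - cy) ** 2) / r**2, 0, None))
        clean.append(bump * rng.uniform(4, 8))
    noisy = [c + rng.normal(0, noise, c.shape) for c in clean]
    scaler = HeightScaler.fit(noisy + clean)
    pairs = [(scaler.transform(nz), scaler.transform(cl)) for nz, cl in zip(noisy, clean)]
    return pairs, scaler, clean, noisy


class TestConditionalTraining:
    def test_zero_iterations_returns_initialized_model(self, rng):
        pairs, scaler, _, _ = _toy_pairs(rng, 3)
        cfg = DiffusionConfig(T=10, iterations=0, channels=4, emb_dim=8)
        model = train_conditional_denoiser(pairs, cfg, seed=1, scaler=scaler)
        assert model.loss_history == []
        assert not model.net.params["W3"].any()  # zero-initialized output conv

    def test_running_loss_decreases(self, rng):
        pairs, scaler, _, _ = _toy_pairs(rng, 8)
        cfg = DiffusionConfig(T=25, iterations=120, channels=8, emb_dim=16,
                              batch_size=4, learning_rate=3e-3)
        model = train_conditional_denoiser(pairs, cfg, seed=2, scaler=scaler)
        hist = np.array(model.loss_history)
        assert hist[-20:].mean() < hist[:20].mean()

    def test_unnormalized_inputs_rejected(self, rng):
        bad = [(rng.normal(0, 5, (8, 8)), rng.normal(0, 5, (8, 8)))]
        with pytest.raises(ValueError, match="normalized"):
            train_conditional_denoiser(bad, DiffusionConfig(iterations=1), seed=0)

    def test_training_is_seed_reproducible(self, rng):
        pairs, scaler, _, _ = _toy_pairs(rng, 3)
        cfg = DiffusionConfig(T=10, iterations=20, channels=4, emb_dim=8, batch_size=2)
        a = train_conditional_denoiser(pairs, cfg, seed=11, scaler=scaler)
        b = train_conditional_denoiser(pairs, cfg, seed=11, scaler=scaler)
        for k in a.net.params:
            assert np.array_equal(a.net.params[k], b.net.params[k])


class TestReverseSampling:
    def test_oracle_noise_prediction_recovers_x0(self, rng):
        """Deterministic reverse walk with the true marginal noise at every
        step lands exactly on x₀ (the final posterior mean collapses there)."""
        sched = build_schedule(8, kind="linear", beta_min=0.05, beta_max=0.3)
        cfg = DiffusionConfig(T=8, iterations=0, channels=4, emb_dim=8)
        x0 = np.clip(rng.normal(0, 0.3, (10, 10)), -1, 1)
        model = train_conditional_denoiser(
            [(x0, x0)], cfg, seed=0, scaler=None
        )
        object.__setattr__(model, "schedule", sched)

        def oracle(x_t, t):
            ab = sched.alpha_bars[t - 1]
            return (x_t - np.sqrt(ab) * x0) / np.sqrt(1 - ab)

        out = reverse_sample(x0, model, np.random.default_rng(3), eps_fn=oracle,
                             stochastic=False)
        assert np.allclose(out, x0, atol=1e-8)

    def test_same_seed_gives_identical_output(self, rng):
        pairs, scaler, _, noisy = _toy_pairs(rng, 3)
        cfg = DiffusionConfig(T=10, iterations=10, channels=4, emb_dim=8, batch_size=2)
        model = train_conditional_denoiser(pairs, cfg, seed=4, scaler=scaler)
        a = denoise_profile(noisy[0], model, seed=9, n_samples=2)
        b = denoise_profile(noisy[0], model, seed=9, n_samples=2)
        assert np.array_equal(a.values, b.values)

    def test_mismatched_schedule_rejected(self, rng):
        pairs, scaler, _, noisy = _toy_pairs(rng, 2)
        cfg = DiffusionConfig(T=10, iterations=0, channels=4, emb_dim=8)
        model = train_conditional_denoiser(pairs, cfg, seed=0, scaler=scaler)
        other = build_schedule(20, kind="cosine")
        with pytest.raises(ValueError, match="schedule"):
            denoise_profile(noisy[0], model, schedule=other, seed=0)


def test_model_save_load_round_trip(tmp_path, rng):
    pairs, scaler, _, noisy = _toy_pairs(rng, 2)
    cfg = DiffusionConfig(T=10, iterations=15, channels=4, emb_dim=8, batch_size=2)
    model = train_conditional_denoiser(pairs, cfg, seed=5, scaler=scaler)
    save_model(tmp_path / "m.npz", model)
    loaded = load_model(tmp_path / "m.npz")
    a = denoise_profile(noisy[0], model, seed=1, n_samples=1)
    b = denoise_profile(noisy[0], loaded, seed=1, n_samples=1)
    assert np.array_equal(a.values, b.values)
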