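"""Forward noising, score identities, and closed-form reverse sampling.

The Gaussian toy (analytic optimal denoiser for N(mu, Sigma) data) gives the
sampler exact targets: the standard reverse process must recover (mu, Sigma);
the score-tempered process at inverse temperature lambda must recover the
tempered Gaussian N(mu, Sigma/lambda).
"""

import numpy as np
import pytest

from bbdiff import (DenoiserContract, DiffusionSchedule, GaussianToyDenoiser,
                    IdentityPrior, PolymerPrior, SamplerSettings,
                    forward_marginal, reverse_sample_array,
                    score_from_denoiser)

MU = np.array([1.0, -2.0, 0.5])
SIGMA = np.array([[1.0, 0.5, 0.0], [0.5, 2.0, 0.3], [0.0, 0.3, 0.7]])


@pytest.fixture(scope="module")
def toy():
    sched = DiffusionSchedule(n_steps=300)
    return sched, GaussianToyDenoiser(MU, SIGMA, sched), IdentityPrior(1)


def _draw(toy, n_draws, lambda_, psi, seed, n_steps=300):
    sched, den, prior = toy
    settings = SamplerSettings(lambda_=lambda_, psi=psi, n_steps=n_steps, seed=seed)
    x = reverse_sample_array(prior, sched, den.contract(), settings, (n_draws, 1, 3))
    return x.reshape(n_draws, 3)


class TestSchedule:
    def test_variance_preserving_identity(self):
        sched = DiffusionSchedule()
        t = np.linspace(0, 1, 33)
        assert np.allclose(sched.alpha(t) ** 2 + sched.sigma(t) ** 2, 1.0)

    def test_alpha_strictly_decreasing_with_endpoints(self):
        sched = DiffusionSchedule()
        t = np.linspace(0, 1, 101)
        a = sched.alpha(t)
        assert np.all(np.diff(a) < 0)
        assert a[0] > 0.9999 and a[-1] < 0.01
        assert sched.sigma(0) < 0.01 and sched.sigma(1) > 0.9999

    def test_invalid_construction(self):
        with pytest.raises(ValueError):
            DiffusionSchedule(n_steps=1)
        with pytest.raises(ValueError):
            DiffusionSchedule(logsnr_max=-5, logsnr_min=5)


class TestForwardMarginal:
    def test_t_zero_returns_input_exactly(self):
        prior = PolymerPrior(20)
        sched = DiffusionSchedule()
        x0 = prior.sample(1, seed=0)[0]
        assert np.array_equal(forward_marginal(prior, sched, x0, 0.0, seed=1), x0)

    def test_t_out_of_range_rejected(self):
        prior = PolymerPrior(5)
        sched = DiffusionSchedule()
        with pytest.raises(ValueError):
            forward_marginal(prior, sched, np.zeros((5, 3)), 1.5)

    def test_terminal_marginal_matches_prior_rg(self):
        prior = PolymerPrior(50)
        sched = DiffusionSchedule()
        x0 = 30.0 * np.ones((50, 3))  # arbitrary, far from the prior
        rng = np.random.default_rng(2)
        draws = np.stack([forward_marginal(prior, sched, x0, 1.0, rng)
                          for _ in range(5000)])
        centered = draws - draws.mean(axis=1, keepdims=True)
        rg2 = (centered**2).sum(-1).mean(-1).mean()
        assert abs(rg2 / prior.mean_sq_rg - 1.0) < 0.03

    def test_whitened_residual_variance_is_sigma_squared(self):
        prior = PolymerPrior(30)
        sched = DiffusionSchedule()
        x0 = prior.sample(1, seed=3)[0]
        t = 0.6
        rng = np.random.default_rng(4)
        z = np.stack([
            prior.whiten(forward_marginal(prior, sched, x0, t, rng)
                         - sched.alpha(t) * x0)
            for _ in range(3000)])
        var = z[:, 1:, :].var()  # modeled latent dims
        assert abs(var / sched.sigma(t) ** 2 - 1.0) < 0.05


class TestScoreConversion:
    def test_standard_normal_data_gives_score_minus_x(self):
        # 1-D data N(0,1): the VP marginal stays N(0,1), so score(x) = -x
        sched = DiffusionSchedule()
        den = GaussianToyDenoiser(np.zeros(1), np.eye(1), sched)
        prior = IdentityPrior(1)
        x = np.array([[0.7], [-1.3], [2.0]])
        for t in (0.3, 0.8, 1.0):
            s = score_from_denoiser(prior, sched, den.contract(), x, t)
            assert np.allclose(s, -x, atol=1e-6)

    def test_denoiser_x_over_alpha_gives_zero_score(self):
        sched = DiffusionSchedule()
        prior = IdentityPrior(1)
        den = DenoiserContract(lambda x, t: x / sched.alpha(t))
        x = np.random.default_rng(0).standard_normal((4, 3))
        s = score_from_denoiser(prior, sched, den, x, 0.5)
        assert np.abs(s).max() < 1e-10

    def test_score_linear_in_x_for_linear_denoiser(self):
        sched = DiffusionSchedule()
        prior = IdentityPrior(1)
        den = DenoiserContract(lambda x, t: 0.3 * x + 1.0)
        x = np.random.default_rng(1).standard_normal((2, 3))
        s1 = score_from_denoiser(prior, sched, den, x, 0.4)
        s2 = score_from_denoiser(prior, sched, den, 2 * x, 0.4)
        s0 = score_from_denoiser(prior, sched, den, 0 * x, 0.4)
        assert np.allclose(s2 - s0, 2 * (s1 - s0), atol=1e-10)

    def test_score_undefined_at_t_zero(self):
        sched = DiffusionSchedule()
        den = DenoiserContract(lambda x, t: x)
        with pytest.raises(ValueError):
            score_from_denoiser(IdentityPrior(1), sched, den, np.zeros((2, 3)), 0.0)

    def test_polymer_prior_score_matches_whitened_identity(self):
        # C^+ (alpha xhat - x)/sigma^2 must agree with the whitened-space score
        prior = PolymerPrior(12)
        sched = DiffusionSchedule()
        den = DenoiserContract(lambda x, t: np.zeros_like(x))
        x = prior.sample(1, seed=5)[0]
        t = 0.5
        s = score_from_denoiser(prior, sched, den, x, t)
        expected = prior.whiten_transpose(-prior.whiten(x)) / sched.sigma(t) ** 2
        assert np.allclose(s, expected, atol=1e-10)


class TestReverseSampling:
    def test_standard_process_recovers_mean_and_covariance(self, toy):
        x = _draw(toy, 20_000, lambda_=1.0, psi=0, seed=1)
        assert np.abs(x.mean(0) - MU).max() < 0.05 * np.abs(MU).max()
        cov = np.cov(x.T)
        assert np.abs(cov - SIGMA).max() < 0.05 * np.abs(SIGMA).max()

    def test_low_temperature_recovers_tempered_covariance(self, toy):
        x = _draw(toy, 20_000, lambda_=4.0, psi=2, seed=2)
        cov = np.cov(x.T)
        assert np.abs(x.mean(0) - MU).max() < 0.1 * np.abs(MU).max()
        assert np.abs(cov - SIGMA / 4.0).max() < 0.10 * np.abs(SIGMA / 4.0).max()

    def test_variance_non_increasing_in_inverse_temperature(self, toy):
        total_var = []
        for lam in (1.0, 2.0, 4.0, 8.0):
            x = _draw(toy, 4000, lambda_=lam, psi=2, seed=3)
            total_var.append(np.trace(np.cov(x.T)))
        assert np.all(np.diff(total_var) < 0)

    def test_seeded_determinism(self, toy):
        a = _draw(toy, 10, lambda_=1.0, psi=0, seed=9)
        b = _draw(toy, 10, lambda_=1.0, psi=0, seed=9)
        assert np.array_equal(a, b)

    def test_step_doubling_changes_estimate_within_mc_error(self, toy):
        a = _draw(toy, 8000, lambda_=1.0, psi=0, seed=4, n_steps=150)
        b = _draw(toy, 8000, lambda_=1.0, psi=0, seed=5, n_steps=300)
        # MC error bar on each covariance entry ~ sigma^2 * sqrt(2/n)
        mc_err = 3.0 * np.abs(SIGMA).max() * np.sqrt(2.0 / 8000)
        assert np.abs(np.cov(a.T) - np.cov(b.T)).max() < mc_err

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            SamplerSettings(lambda_=0.5)
        with pytest.raises(ValueError):
            SamplerSettings(psi=-1)
        with pytest.raises(ValueError):
            SamplerSettings(n_steps=1)

    def test_nonfinite_denoiser_aborts_with_step_index(self, toy):
        sched, _, prior = toy
        bad = DenoiserContract(lambda x, t: np.full_like(x, np.nan))
        with pytest.raises(FloatingPointError, match="t="):
            reverse_sample_array(prior, sched, bad,
                                 SamplerSettings(n_steps=10, seed=0), (2, 3))
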