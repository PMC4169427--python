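"""Pulling-point laws, noise distributions and modulation energetics."""

import numpy as np
import pytest
from scipy import integrate, stats

from aspull.bias_analysis import VNoiseCurve
from aspull.protocols import (
    ChiInducingSampler,
    ProtocolSpec,
    amplitude_schedule,
    deterministic_position,
    fm_gate,
    injected_noise_energy,
    sample_pulling_noise_chi_inducing,
    sample_pulling_noise_gaussian,
    stochastic_offset,
)
from aspull.units import velocity_ms_to_Afs

K_SPRING = 12.07  # ~500 pN/A at 300 K, in k_BT/A^2


class TestDeterministicPosition:
    def test_start(self):
        assert deterministic_position(3.0, 1e-4, 2.0, 0) == 3.0

    def test_published_step_arithmetic(self):
        # 10 m/s = 1e-4 A/fs; 200 sub-steps of 2 fs advance the anchor 0.04 A
        v = velocity_ms_to_Afs(10.0)
        assert deterministic_position(0.0, v, 2.0, 200) == pytest.approx(0.04)

    def test_affine_in_substep(self):
        v, dt, x0 = 3e-4, 2.0, 1.0
        for j1, j2 in ((5, 11), (100, 3)):
            lhs = deterministic_position(x0, v, dt, j1 + j2) - deterministic_position(x0, v, dt, j2)
            rhs = deterministic_position(x0, v, dt, j1) - x0
            assert lhs == pytest.approx(rhs)


class TestGaussianNoise:
    def test_zero_sigma(self):
        rng = np.random.default_rng(0)
        assert sample_pulling_noise_gaussian(0.0, rng) == 0.0

    def test_moments_and_symmetry(self):
        rng = np.random.default_rng(1)
        draws = sample_pulling_noise_gaussian(2.5, rng, size=100_000)
        n = len(draws)
        assert abs(draws.mean()) < 3 * 2.5 / np.sqrt(n)
        assert abs(draws.std() - 2.5) < 3 * 2.5 / np.sqrt(2 * n)
        assert abs(stats.skew(draws)) < 3 * np.sqrt(6 / n)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            sample_pulling_noise_gaussian(-1.0, np.random.default_rng(0))


class TestChiInducingSampler:
    """The rejection sampler must reproduce the work-Gaussianising density."""

    def test_offsets_symmetric_zero_mean(self):
        rng = np.random.default_rng(2)
        draws = sample_pulling_noise_chi_inducing(5.0, K_SPRING, rng, size=100_000)
        sd = draws.std()
        assert abs(draws.mean()) < 3 * sd / np.sqrt(len(draws))

    def test_induced_work_matches_target_density(self):
        """KS test against the numerically normalised half-normal work density."""
        rng = np.random.default_rng(3)
        sampler = ChiInducingSampler(5.0, K_SPRING)
        n = 100_000
        work = sampler.work_of(sampler.sample(rng, n))
        # numerically normalised CDF, independent of the analytic constant
        grid = np.linspace(0, work.max() * 1.1, 4000)
        pdf = sampler.work_density(grid)
        cdf_grid = integrate.cumulative_trapezoid(pdf, grid, initial=0.0)
        cdf_grid /= cdf_grid[-1]
        ks = stats.kstest(work, lambda w: np.interp(w, grid, cdf_grid)).statistic
        assert ks < 1.628 / np.sqrt(n)  # 1% critical value

    def test_work_sd_scales_linearly_with_target(self):
        rng = np.random.default_rng(4)
        s1 = ChiInducingSampler(3.0, K_SPRING)
        s2 = ChiInducingSampler(6.0, K_SPRING)
        n = 100_000
        w1 = s1.work_of(s1.sample(rng, n))
        w2 = s2.work_of(s2.sample(rng, n))
        ratio = w2.std() / w1.std()
        assert ratio == pytest.approx(2.0, abs=3 * 2.0 * np.sqrt(2.0 / n) * 2)

    def test_rejection_matches_exact_transform_sampler(self):
        """Independent oracle: X = sign * sqrt(2 W / k) with half-normal W."""
        rng = np.random.default_rng(5)
        sampler = ChiInducingSampler(4.0, K_SPRING)
        rej = sampler.sample(rng, 60_000)
        w = np.abs(rng.normal(0.0, 4.0, 60_000))
        exact = np.sqrt(2.0 * w / K_SPRING) * rng.choice([-1.0, 1.0], 60_000)
        ks = stats.ks_2samp(rej, exact).statistic
        assert ks < 1.628 * np.sqrt(2 / 60_000)

    def test_acceptance_rate_reported(self):
        rng = np.random.default_rng(6)
        sampler = ChiInducingSampler(5.0, K_SPRING)
        sampler.sample(rng, 10_000)
        assert 0.1 < sampler.acceptance_rate <= 1.0

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ChiInducingSampler(0.0, K_SPRING)
        with pytest.raises(ValueError):
            ChiInducingSampler(1.0, -2.0)


def make_curve(values):
    vals = np.asarray(values, dtype=float)
    return VNoiseCurve(grid=np.arange(len(vals), dtype=float), values=vals)


class TestAmplitudeSchedule:
    def test_constant_one_recovers_constant_noise(self):
        curve = make_curve([0.0] + [1.0] * 9)
        sched = amplitude_schedule(curve, m=100.0, sigma_r_A=0.037)
        assert np.allclose(sched[1:], 100.0 * 0.037)

    def test_zero_curve_recovers_normal_pulling(self):
        curve = make_curve([0.0] + [1.0] + [0.0] * 8)
        sched = amplitude_schedule(curve, m=100.0, sigma_r_A=0.037)
        assert np.all(sched[2:] == 0.0)

    def test_out_of_range_curve_rejected(self):
        with pytest.raises(ValueError):
            make_curve([0.0, 0.5, 1.3])


class TestFmGate:
    def test_extremes(self):
        assert fm_gate(1.0, 0.999) is True
        assert fm_gate(0.0, 0.3) is False

    def test_acceptance_fraction(self):
        rng = np.random.default_rng(8)
        R = rng.random(100_000)
        frac = np.mean(fm_gate(0.3, R))
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 100_000)

    def test_range_validation(self):
        with pytest.raises(ValueError):
            fm_gate(1.5, 0.5)
        with pytest.raises(ValueError):
            fm_gate(0.5, -0.1)


class TestStochasticOffset:
    def setup_method(self):
        vals = np.zeros(11)
        vals[5] = 0.5
        vals[9] = 1.0  # interval values drop the final grid point
        self.curve = make_curve(vals)

    def test_sampling_moment_always_zero(self):
        rng = np.random.default_rng(9)
        for kind in ("normal", "constant_noise", "am", "fm"):
            p = ProtocolSpec(kind=kind, m=50.0,
                             v_noise=self.curve if kind in ("am", "fm") else None)
            off = stochastic_offset(p, 5, True, 0.037, rng, k_kbtA2=K_SPRING)
            assert off == 0.0

    def test_normal_kind_always_zero(self):
        rng = np.random.default_rng(10)
        p = ProtocolSpec(kind="normal")
        assert stochastic_offset(p, 3, False, 0.037, rng) == 0.0

    def test_am_amplitude_follows_curve(self):
        rng = np.random.default_rng(11)
        p = ProtocolSpec(kind="am", m=100.0, v_noise=self.curve)
        draws = stochastic_offset(p, 5, False, 0.037, rng, size=50_000)
        target = 100.0 * 0.037 * 0.5
        assert draws.std() == pytest.approx(target, rel=0.03)

    def test_fm_energy_linear_in_curve(self):
        """Mean injected energy at V=v equals v times the V=1 energy (3 SE)."""
        rng = np.random.default_rng(12)
        p = ProtocolSpec(kind="fm", m=100.0, v_noise=self.curve)
        n_draw = 40_000
        e_half = injected_noise_energy(
            stochastic_offset(p, 5, False, 0.037, rng, size=n_draw), K_SPRING) / n_draw
        e_full = injected_noise_energy(
            stochastic_offset(p, 9, False, 0.037, rng, size=n_draw), K_SPRING) / n_draw
        # per-draw energy is 0.5*k*eta^2; its SE at V=1 is ~sqrt(2/n)*mean
        se = 3 * np.sqrt(2.0 / n_draw) * e_full
        assert abs(e_half - 0.5 * e_full) < 3 * se

    def test_unknown_interval_rejected(self):
        rng = np.random.default_rng(13)
        p = ProtocolSpec(kind="am", m=10.0, v_noise=self.curve)
        with pytest.raises(ValueError):
            stochastic_offset(p, 99, False, 0.037, rng)


class TestModulationPower:
    def test_fm_transfers_at_least_am_energy(self):
        """Linear beats quadratic on (0,1): FM >= AM mean energy at equal m."""
        rng = np.random.default_rng(14)
        vals = np.linspace(0.0, 1.0, 11)
        curve = make_curve(vals)
        m, sr, n_draw = 100.0, 0.037, 20_000
        p_am = ProtocolSpec(kind="am", m=m, v_noise=curve)
        p_fm = ProtocolSpec(kind="fm", m=m, v_noise=curve)
        for j in (3, 5, 8):  # interior intervals, 0 < V < 1
            e_am = injected_noise_energy(
                stochastic_offset(p_am, j, False, sr, rng, size=n_draw), K_SPRING)
            e_fm = injected_noise_energy(
                stochastic_offset(p_fm, j, False, sr, rng, size=n_draw), K_SPRING)
            assert e_fm > e_am

    def test_effective_interval_sd_scales_inverse_sqrt_n(self):
        """Mean per-interval work SD over n sub-steps shrinks as 1/sqrt(n)."""
        rng = np.random.default_rng(15)
        sigma_x = 1.0
        k = K_SPRING

        def interval_mean_sd(n, reps=4000):
            draws = rng.normal(0.0, sigma_x, size=(reps, n))
            works = 0.5 * k * draws**2
            return works.mean(axis=1).std()

        sd_small = interval_mean_sd(25)
        sd_big = interval_mean_sd(100)
        assert sd_small / sd_big == pytest.approx(2.0, rel=0.12)


class TestProtocolSpecValidation:
    def test_modulated_kinds_require_curve(self):
        with pytest.raises(ValueError):
            ProtocolSpec(kind="am", m=10.0)
        with pytest.raises(ValueError):
            ProtocolSpec(kind="fm", m=10.0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            ProtocolSpec(kind="constant_noise", m=-1.0)
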