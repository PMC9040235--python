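import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, stats

from swrecur import (
    CensorCause,
    DesignSpec,
    EventGenConfig,
    GenModel,
    SwitchBasis,
    TerminalParam,
    invert_exponential_switch,
    invert_weibull_switch,
    simulate_trial,
)
from swrecur.simulate import (
    apply_observation_scheme,
    draw_terminal_time,
    generate_subject_poisson,
    generate_subject_weibull,
    import_records,
    terminal_survival,
)

RATES = dict(lam=0.003281, beta_t=-0.264)


def piecewise_exp_cumhaz(t, rate0, rate1, w):
    return rate0 * np.minimum(t, w) + rate1 * np.maximum(t - w, 0.0)


def piecewise_weibull_cumhaz(t, lam, nu, eta, beta_t, w):
    out = lam * eta * np.minimum(t, w) ** nu
    post = t > w
    out = out + np.exp(beta_t) * lam * eta * (
        np.maximum(t, w) ** nu - w**nu
    ) * post
    return out


class TestExponentialInversion:
    def test_branches_coincide_without_effect(self):
        u = np.linspace(0.05, 0.95, 19)
        t = invert_exponential_switch(u, 0.01, 0.01, w=50.0)
        np.testing.assert_allclose(t, -np.log(u) / 0.01)

    def test_continuous_at_threshold(self):
        for rate0 in (0.001, 0.01, 0.1):
            for w in (1.0, 50.0, 300.0):
                u = np.exp(-rate0 * w)  # exactly at the branch threshold
                rate1 = rate0 * np.exp(-0.264)
                for factor in (1.0, 1 + 1e-12, 1 - 1e-12):
                    t = invert_exponential_switch(u * factor, rate0, rate1, w)
                    assert t == pytest.approx(w, rel=1e-6)

    def test_matches_numerical_root_of_cumhaz(self):
        # reference-setting parameters, subject 100 days from the switch
        rate0 = RATES["lam"]
        rate1 = rate0 * np.exp(RATES["beta_t"])
        u, w = 0.5, 100.0
        t = float(invert_exponential_switch(u, rate0, rate1, w))
        root = optimize.brentq(
            lambda x: piecewise_exp_cumhaz(x, rate0, rate1, w) + np.log(u), 1e-9, 1e6
        )
        assert t == pytest.approx(root, rel=1e-10)
        assert t == pytest.approx(244.88, abs=0.01)

    @pytest.mark.parametrize("u", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_degenerate_uniforms(self, u):
        with pytest.raises(ValueError):
            invert_exponential_switch(u, 0.01, 0.01, 10.0)

    def test_distribution_matches_piecewise_survival(self):
        rate0, w = 0.003281, 120.0
        rate1 = rate0 * np.exp(-0.264)
        u = np.random.default_rng(10).uniform(size=100_000)
        draws = invert_exponential_switch(u, rate0, rate1, w)
        cdf = lambda t: 1.0 - np.exp(-piecewise_exp_cumhaz(t, rate0, rate1, w))
        assert stats.kstest(draws, cdf).pvalue > 0.001

    def test_protective_effect_lengthens_durations(self):
        u = np.linspace(0.01, 0.99, 99)
        base = invert_exponential_switch(u, 0.01, 0.01, w=30.0)
        protected = invert_exponential_switch(u, 0.01, 0.01 * np.exp(-0.264), w=30.0)
        assert np.all(protected >= base)

    @settings(derandomize=True, max_examples=100)
    @given(
        u=st.floats(1e-6, 1 - 1e-6),
        rate0=st.floats(1e-5, 1.0),
        beta=st.floats(-2.0, 2.0),
        w=st.floats(0.0, 1e3),
    )
    def test_inverse_recovers_uniform(self, u, rate0, beta, w):
        # the inversion is exact: the piecewise cumulative hazard evaluated
        # at the sampled duration returns -log(u)
        rate1 = rate0 * np.exp(beta)
        t = float(invert_exponential_switch(u, rate0, rate1, w))
        assert t > 0
        assert piecewise_exp_cumhaz(t, rate0, rate1, w) == pytest.approx(
            -np.log(u), rel=1e-9
        )


class TestWeibullInversion:
    def test_zero_distance_uses_intervention_hazard(self):
        u = np.linspace(0.05, 0.95, 19)
        lam, nu, bt = 0.004703, 1.1219, -0.264
        t = invert_weibull_switch(u, lam, nu, 1.0, bt, w=0.0)
        np.testing.assert_allclose(t, (-np.log(u) / (lam * np.exp(bt))) ** (1 / nu))

    def test_branches_coincide_without_effect(self):
        u = np.linspace(0.05, 0.95, 19)
        t = invert_weibull_switch(u, 0.0047, 1.12, 1.0, 0.0, w=50.0)
        np.testing.assert_allclose(t, (-np.log(u) / 0.0047) ** (1 / 1.12))

    def test_continuous_at_threshold(self):
        for nu in (0.9108, 1.1219, 1.5122):
            for w in (5.0, 50.0, 200.0):
                lam = 0.004703
                u = np.exp(-lam * w**nu)
                for eps in (0, 1e-13, -1e-13):
                    t = invert_weibull_switch(u + eps, lam, nu, 1.0, -0.264, w)
                    assert t == pytest.approx(w, rel=1e-5)

    def test_matches_numerical_root_of_cumhaz(self):
        lam, nu, bt, w, u = 0.004703, 1.1219, -0.264, 50.0, 0.3
        t = float(invert_weibull_switch(u, lam, nu, 1.0, bt, w))
        root = optimize.brentq(
            lambda x: piecewise_weibull_cumhaz(x, lam, nu, 1.0, bt, w) + np.log(u),
            1e-9,
            1e7,
        )
        assert t == pytest.approx(root, rel=1e-10)

    def test_distribution_matches_piecewise_survival(self):
        lam, nu, bt, w = 0.009910, 0.9108, -0.264, 80.0
        u = np.random.default_rng(11).uniform(size=100_000)
        draws = invert_weibull_switch(u, lam, nu, 1.0, bt, w)
        cdf = lambda t: 1.0 - np.exp(-piecewise_weibull_cumhaz(t, lam, nu, 1.0, bt, w))
        assert stats.kstest(draws, cdf).pvalue > 0.001


class TestConfigValidation:
    def test_study_constructors_carry_fitted_parameters(self):
        wc = EventGenConfig.weibull_change()
        assert wc.lambda_k == (0.003599, 0.009910, 0.009910)
        assert wc.nu_k == (1.5122, 0.9108, 0.9108)
        assert EventGenConfig.poisson().lambda_k[0] == 0.003281

    @pytest.mark.parametrize(
        "bad",
        [
            dict(model=GenModel.POISSON, lambda_k=(0.1, 0.1, 0.1), nu_k=(2.0, 2.0, 2.0)),
            dict(model=GenModel.POISSON, lambda_k=(0.1, 0.2, 0.1)),
            dict(model=GenModel.POISSON, lambda_k=(0.1, 0.1, 0.1), sigma2_subject=0.3),
            dict(model=GenModel.MIXED_POISSON, lambda_k=(0.1, 0.1, 0.1)),
            dict(
                model=GenModel.WEIBULL_CHANGE,
                lambda_k=(0.1, 0.2, 0.3),
                nu_k=(1.0, 1.0, 1.0),
            ),
            dict(model=GenModel.POISSON, lambda_k=(0.1, 0.1, 0.1), max_events=4),
            dict(model=GenModel.POISSON, lambda_k=(-0.1, -0.1, -0.1)),
        ],
    )
    def test_inconsistent_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            EventGenConfig(**bad)

    def test_subject_sd_readings(self):
        cfg = EventGenConfig.mixed_poisson()
        assert cfg.subject_sd == pytest.approx(0.3455)  # printed value is the SD
        var_reading = cfg.with_(subject_effect_is_sd=False)
        assert var_reading.subject_sd == pytest.approx(np.sqrt(0.3455))


class TestSubjectGenerators:
    def test_poisson_durations_are_sorted_order_statistics(self):
        cfg = EventGenConfig.poisson(beta_t=0.0)
        rng = np.random.default_rng(12)
        rate = cfg.lambda_k[0]
        mins = np.empty(20_000)
        for i in range(mins.size):
            t = generate_subject_poisson(cfg, d=30.0, W_i=60.0, tau_i=0.0, tau_j=0.0, rng=rng)
            assert t[0] < t[1] < t[2]
            mins[i] = t[0] - 30.0
        # first order statistic of three iid exponentials has mean 1/(3 rate)
        assert mins.mean() == pytest.approx(1 / (3 * rate), rel=0.03)

    def test_poisson_after_switch_uses_intervention_rate(self):
        cfg = EventGenConfig.poisson(beta_t=-1.5)
        rng = np.random.default_rng(13)
        draws = np.concatenate(
            [
                generate_subject_poisson(cfg, d=200.0, W_i=60.0, tau_i=0.0, tau_j=0.0, rng=rng)
                - 200.0
                for _ in range(4000)
            ]
        )
        rate1 = cfg.lambda_k[0] * np.exp(-1.5)
        assert stats.kstest(draws, stats.expon(scale=1 / rate1).cdf).pvalue > 0.001

    def test_weibull_shape_one_reduces_to_exponential_gaps(self):
        cfg = EventGenConfig.weibull_constant(beta_t=0.0, lam=0.003281, nu=1.0)
        rng = np.random.default_rng(14)
        gaps = np.array(
            [
                np.diff(
                    np.concatenate(
                        [[10.0], generate_subject_weibull(cfg, 10.0, 60.0, 0.0, rng)]
                    )
                )
                for _ in range(4000)
            ]
        ).ravel()
        assert stats.kstest(gaps, stats.expon(scale=1 / 0.003281).cdf).pvalue > 0.001

    def test_weibull_change_later_gaps_share_distribution(self):
        cfg = EventGenConfig.weibull_change(beta_t=0.0)
        rng = np.random.default_rng(15)
        times = np.array(
            [generate_subject_weibull(cfg, 0.0, 60.0, 0.0, rng) for _ in range(6000)]
        )
        g1 = times[:, 0]
        g2 = times[:, 1] - times[:, 0]
        g3 = times[:, 2] - times[:, 1]
        assert stats.ks_2samp(g2, g3).pvalue > 0.001
        assert stats.ks_2samp(g1, g2).pvalue < 0.001  # first recurrence differs


class TestTerminalEvent:
    def test_terminal_after_entry(self):
        cfg = EventGenConfig.poisson()
        c = draw_terminal_time(cfg, d=100.0, rng=np.random.default_rng(16), size=1000)
        assert np.all(c > 100.0)

    def test_shape_one_is_exponential(self):
        cfg = EventGenConfig.poisson().with_(nu_c=1.0, lambda_c=0.01)
        c = draw_terminal_time(cfg, 0.0, np.random.default_rng(17), size=100_000)
        assert stats.kstest(c, stats.expon(scale=100.0).cdf).pvalue > 0.001

    @pytest.mark.parametrize("param", list(TerminalParam))
    def test_distribution_matches_analytic_survival(self, param):
        cfg = EventGenConfig.poisson().with_(terminal_parameterization=param)
        c = draw_terminal_time(cfg, 0.0, np.random.default_rng(18), size=100_000)
        cdf = lambda t: 1.0 - terminal_survival(cfg, t)
        assert stats.kstest(c, cdf).pvalue > 0.001

    def test_default_parameterization_mortality_plausible(self):
        # uniform entry over a 360-day window should put the terminal-event
        # fraction near the observed one-year mortality of the source data
        cfg = EventGenConfig.poisson()
        rng = np.random.default_rng(19)
        d = rng.uniform(0, 360, size=200_000)
        c = draw_terminal_time(cfg, d, rng, size=d.size)
        frac = (c < 360.0).mean()
        assert 0.3 < frac < 0.45


class TestObservationScheme:
    def run(self, latent, terminal, end=360.0):
        latent = np.asarray(latent, dtype=float)[None, :]
        terminal = np.asarray([terminal], dtype=float)
        censor = np.empty(1)
        cause = np.empty(1, dtype=int)
        n = apply_observation_scheme(latent, terminal, censor, cause, end)
        return int(n[0]), float(censor[0]), CensorCause(int(cause[0]))

    def test_terminal_before_first_event(self):
        n, censor, cause = self.run([100, 200, 300], terminal=50.0)
        assert (n, censor, cause) == (0, 50.0, CensorCause.TERMINAL)

    def test_three_events_end_followup(self):
        n, censor, cause = self.run([100, 200, 300], terminal=1e9)
        assert (n, censor, cause) == (3, 300.0, CensorCause.THIRD_EVENT)

    def test_administrative_censoring(self):
        n, censor, cause = self.run([100, 400, 500], terminal=1e9)
        assert (n, censor, cause) == (1, 360.0, CensorCause.ADMIN_END)


class TestSimulateTrial:
    def test_deterministic_given_seed(self, small_design, poisson_config):
        a = simulate_trial(small_design, poisson_config, 42)
        b = simulate_trial(small_design, poisson_config, 42)
        c = simulate_trial(small_design, poisson_config, 43)
        np.testing.assert_array_equal(a.latent, b.latent)
        np.testing.assert_array_equal(a.censor_time, b.censor_time)
        assert not np.array_equal(a.latent, c.latent)

    def test_degenerate_random_effects_are_zero(self, small_design, poisson_config):
        data = simulate_trial(small_design, poisson_config, 0)
        assert np.all(data.tau_i == 0) and np.all(data.tau_j == 0)

    def test_observed_event_bounds(self, small_design):
        for gen in (EventGenConfig.poisson(-0.264), EventGenConfig.weibull_change(-0.264)):
            data = simulate_trial(small_design, gen, 7)
            assert data.n_observed.max() <= 3
            obs = data.observed
            horizon = np.minimum(data.terminal, data.schedule.t_F)
            assert np.all((obs <= horizon[:, None]) | np.isnan(obs))
            assert np.all(data.censor_time >= data.d)

    def test_null_effect_removes_switch_signature(self, small_design):
        # with beta_t=0 the first total-time duration is the minimum of three
        # iid exponentials regardless of the switch distance
        cfg = EventGenConfig.poisson(beta_t=0.0)
        data = simulate_trial(small_design.__class__(m=5, t_S=0, t_E=360, N=20000), cfg, 21)
        first = data.latent[:, 0] - data.d
        rate = 3 * cfg.lambda_k[0]
        assert stats.kstest(first, stats.expon(scale=1 / rate).cdf).pvalue > 0.001

    def test_switch_basis_changes_weibull_generation(self, small_design):
        cfg = EventGenConfig.weibull_change(beta_t=-1.0)
        entry = simulate_trial(small_design, cfg, 5)
        recur = simulate_trial(
            small_design, cfg.with_(switch_basis=SwitchBasis.RECURRENCE), 5
        )
        # same uniforms, different thresholds for later gaps
        np.testing.assert_allclose(entry.latent[:, 0], recur.latent[:, 0])
        assert not np.allclose(entry.latent[:, 2], recur.latent[:, 2])

    def test_roundtrip_through_long_format(self, small_design, poisson_config):
        data = simulate_trial(small_design, poisson_config, 9)
        buf = io.StringIO()
        data.export(buf)
        buf.seek(0)
        back = import_records(buf, small_design)
        np.testing.assert_array_equal(back.n_observed, data.n_observed)
        np.testing.assert_allclose(back.censor_time, data.censor_time)
        np.testing.assert_allclose(back.observed[back.n_observed > 0, 0],
                                   data.observed[data.n_observed > 0, 0])
        np.testing.assert_array_equal(back.censor_cause, data.censor_cause)
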