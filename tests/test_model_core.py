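"""Unit tests for the data model and the joint posterior's component
densities: pmfs, priors, exposure handling and support behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln
from scipy.stats import beta as beta_dist
from scipy.stats import halfnorm, norm

import bayescount as bc
from bayescount.model_core import (
    LOG_ZERO,
    ValidationError,
    log_prior_pi,
    log_rates,
    resolve_theta_location,
)


def _single_obs_table(count=4, area=1.0):
    df = pd.DataFrame(
        {"count": [count], "region": ["r"], "group": ["g"], "animal": ["a"],
         "area": [area]}
    )
    return bc.CellCountTable.from_frame(df)


class TestCellCountTable:
    def test_codes_are_dense_and_first_appearance_ordered(self):
        df = pd.DataFrame(
            {
                "count": [1, 2, 3, 4],
                "region": ["hip", "ctx", "hip", "thal"],
                "group": ["sham", "lesion", "lesion", "sham"],
                "animal": ["a2", "a1", "a2", "a3"],
                "area": [1.0, 2.0, 1.5, 1.0],
            }
        )
        t = bc.CellCountTable.from_frame(df)
        assert t.region_labels == ["hip", "ctx", "thal"]
        assert t.group_labels == ["sham", "lesion"]
        assert list(t.region_codes) == [0, 1, 0, 2]
        assert list(t.group_codes) == [0, 1, 1, 0]
        assert t.n_obs == 4 and t.n_regions == 3 and t.n_groups == 2

    @pytest.mark.parametrize(
        "bad",
        [
            {"count": [-1]},
            {"count": [1.5]},
            {"area": [0.0]},
            {"area": [-2.0]},
        ],
    )
    def test_invalid_rows_rejected(self, bad):
        base = {"count": [1], "region": ["r"], "group": ["g"],
                "animal": ["a"], "area": [1.0]}
        base.update(bad)
        with pytest.raises(ValidationError):
            bc.CellCountTable.from_frame(pd.DataFrame(base))

    def test_missing_required_column_reported(self):
        df = pd.DataFrame({"count": [1], "region": ["r"], "animal": ["a"]})
        with pytest.raises(ValidationError, match="group"):
            bc.CellCountTable.from_frame(df)

    def test_missing_area_defaults_to_unit_exposure(self, caplog):
        df = pd.DataFrame(
            {"count": [1], "region": ["r"], "group": ["g"], "animal": ["a"]}
        )
        t = bc.CellCountTable.from_frame(df)
        assert np.allclose(t.exposures, 0.0)

    def test_csv_round_trip(self, tmp_path, tiny_table):
        table, _ = tiny_table
        path = tmp_path / "t.csv"
        table.to_csv(path)
        back = bc.CellCountTable.from_csv(path)
        assert np.array_equal(back.counts, table.counts)
        assert np.allclose(back.areas, table.areas)
        assert back.region_labels == table.region_labels
        assert back.group_labels == table.group_labels


class TestLogRate:
    def test_identity_and_sum_cases(self):
        t = _single_obs_table(area=2.0)
        p = bc.ParameterState(theta=[[1.0]], gamma=[0.0], tau=[[0.1]])
        assert bc.log_rate(p, t, 0) == pytest.approx(1.0 + np.log(2.0))
        p2 = bc.ParameterState(theta=[[2.0]], gamma=[0.5], tau=[[0.1]])
        assert bc.log_rate(p2, t, 0) == pytest.approx(2.5 + np.log(2.0))
        cfg = bc.ModelConfig(use_exposure=False)
        assert bc.log_rate(p2, t, 0, cfg) == pytest.approx(2.5)

    def test_exposure_linearity_doubling_area(self):
        p = bc.ParameterState(theta=[[1.3]], gamma=[0.2], tau=[[0.1]])
        a = bc.log_rate(p, _single_obs_table(area=1.5), 0)
        b = bc.log_rate(p, _single_obs_table(area=3.0), 0)
        assert b - a == pytest.approx(np.log(2.0))

    def test_index_and_dimension_errors(self):
        t = _single_obs_table()
        p = bc.ParameterState(theta=[[1.0]], gamma=[0.0], tau=[[0.1]])
        with pytest.raises(IndexError):
            bc.log_rate(p, t, 5)
        bad = bc.ParameterState(theta=[[1.0, 2.0]], gamma=[0.0], tau=[[0.1]])
        with pytest.raises(ValidationError):
            bc.log_rate(bad, t, 0)


class TestPoissonPmf:
    def test_closed_form_values(self):
        assert bc.poisson_log_pmf(0, 1.0) == pytest.approx(-1.0)
        assert bc.poisson_log_pmf(3, 2.0) == pytest.approx(
            3 * np.log(2.0) - 2.0 - np.log(6.0)
        )

    @pytest.mark.parametrize("lam", [0.3, 1.0, 7.5, 40.0])
    def test_normalisation(self, lam):
        ys = np.arange(0, 400)
        total = np.exp(bc.poisson_log_pmf(ys, lam)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            bc.poisson_log_pmf(2, 0.0)
        with pytest.raises(ValidationError):
            bc.poisson_log_pmf(-1, 1.0)
        with pytest.raises(ValidationError):
            bc.poisson_log_pmf(1.5, 1.0)


class TestZipPmf:
    @pytest.mark.parametrize("y", [0, 1, 5, 20])
    @pytest.mark.parametrize("lam", [0.4, 3.0, 25.0])
    def test_pi_zero_reduces_to_poisson_exactly(self, y, lam):
        assert bc.zip_log_pmf(y, 0.0, lam) == bc.poisson_log_pmf(y, lam)

    def test_degenerate_pi_one(self):
        assert bc.zip_log_pmf(0, 1.0, 2.0) == pytest.approx(0.0)
        assert bc.zip_log_pmf(3, 1.0, 2.0) == LOG_ZERO

    def test_mixture_value_and_normalisation(self):
        val = bc.zip_log_pmf(0, 0.5, 1.0)
        assert val == pytest.approx(np.log(0.5 + 0.5 * np.exp(-1.0)))
        for pi in (0.0, 0.06, 0.5, 0.9):
            for lam in (0.5, 4.0, 30.0):
                ys = np.arange(0, 400)
                total = np.exp(bc.zip_log_pmf(ys, pi, lam)).sum()
                assert total == pytest.approx(1.0, abs=1e-10)

    @given(
        y=st.integers(min_value=0, max_value=50),
        pi=st.floats(min_value=0.0, max_value=1.0),
        lam=st.floats(min_value=1e-3, max_value=100.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_inflation_never_deflates_zero_mass(self, y, pi, lam):
        zip0 = bc.zip_log_pmf(0, pi, lam)
        assert zip0 >= bc.poisson_log_pmf(0, lam) - 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            bc.zip_log_pmf(0, 1.5, 1.0)
        with pytest.raises(ValidationError):
            bc.zip_log_pmf(0, 0.5, -1.0)


class TestGammaPrior:
    def _table(self, n):
        df = pd.DataFrame(
            {"count": [1] * n, "region": ["r"] * n, "group": ["g"] * n,
             "animal": [f"a{i}" for i in range(n)], "area": [1.0] * n}
        )
        return bc.CellCountTable.from_frame(df)

    def test_symmetric_zero_case(self):
        n, tval = 4, 0.3
        t = self._table(n)
        p = bc.ParameterState(
            theta=[[0.0]], gamma=np.zeros(n), tau=[[tval]]
        )
        expected = n * norm.logpdf(0.0, scale=tval)
        assert bc.log_prior_gamma(p, t, bc.ModelConfig()) == pytest.approx(expected)

    def test_horseshoe_kappa_one_reduces_to_normal_plus_halfnormal(self):
        n, tval = 3, 0.2
        t = self._table(n)
        cfg_n = bc.ModelConfig(random_effect_prior="normal")
        cfg_h = bc.ModelConfig(random_effect_prior="horseshoe")
        g = np.array([0.1, -0.2, 0.05])
        p_n = bc.ParameterState(theta=[[0.0]], gamma=g, tau=[[tval]])
        p_h = bc.ParameterState(
            theta=[[0.0]], gamma=g, tau=[[tval]], kappa=np.ones(n)
        )
        expected = bc.log_prior_gamma(p_n, t, cfg_n) + n * halfnorm.logpdf(
            1.0, scale=1.0
        )
        assert bc.log_prior_gamma(p_h, t, cfg_h) == pytest.approx(expected)

    def test_single_observation_closed_form(self):
        t = self._table(1)
        p = bc.ParameterState(theta=[[0.0]], gamma=[0.3], tau=[[0.1]])
        assert bc.log_prior_gamma(p, t, bc.ModelConfig()) == pytest.approx(
            norm.logpdf(0.3, scale=0.1)
        )

    def test_zero_tau_with_nonzero_gamma_is_log_zero(self):
        t = self._table(1)
        p = bc.ParameterState(theta=[[0.0]], gamma=[0.3], tau=[[0.0]])
        assert bc.log_prior_gamma(p, t, bc.ModelConfig()) == LOG_ZERO

    def test_horseshoe_without_kappa_raises(self):
        t = self._table(1)
        p = bc.ParameterState(theta=[[0.0]], gamma=[0.0], tau=[[0.1]])
        with pytest.raises(ValidationError):
            bc.log_prior_gamma(
                p, t, bc.ModelConfig(random_effect_prior="horseshoe")
            )


class TestTauPriorAndCalibration:
    def test_negative_tau_has_zero_density(self):
        assert bc.log_prior_tau(np.array([[0.1, -0.2]]), 1.05) == LOG_ZERO

    def test_density_at_zero_closed_form(self):
        s = 1.05
        tau = np.zeros((3, 2))
        expected = 6 * np.log(np.sqrt(2.0 / np.pi) / np.log(s))
        assert bc.log_prior_tau(tau, s) == pytest.approx(expected)

    def test_hyperprior_calibration_95_percent_below_log_1_1(self):
        mass = bc.halfnormal_mass(np.log(1.05), np.log(1.1))
        assert round(mass, 2) == 0.95

    def test_halfnormal_mass_limits_and_identity(self):
        assert bc.halfnormal_mass(0.5, 1e9) == pytest.approx(1.0)
        from scipy.special import erf

        assert bc.halfnormal_mass(1.0, 1.0) == pytest.approx(
            erf(1.0 / np.sqrt(2.0))
        )

    def test_invalid_s_raises(self):
        with pytest.raises(ValidationError):
            bc.log_prior_tau(np.array([[0.1]]), 1.0)


class TestThetaPrior:
    def test_mode_and_closed_form(self):
        cfg = bc.ModelConfig(theta_prior_location=0.0, theta_prior_scale=5.0)
        theta = np.zeros((2, 3))
        assert bc.log_prior_theta(theta, cfg) == pytest.approx(
            6 * np.log(1.0 / (5.0 * np.sqrt(2 * np.pi)))
        )

    def test_flat_limit_is_constant_offset(self):
        cfg = bc.ModelConfig(theta_prior_location=0.0, theta_prior_scale=1e8)
        a = bc.log_prior_theta(np.array([[0.0]]), cfg)
        b = bc.log_prior_theta(np.array([[10.0]]), cfg)
        assert a == pytest.approx(b, abs=1e-8)

    def test_default_location_is_exposure_adjusted_mean(self):
        df = pd.DataFrame(
            {"count": [10, 20], "region": ["r", "r"], "group": ["g", "g"],
             "animal": ["a", "b"], "area": [2.0, 4.0]}
        )
        t = bc.CellCountTable.from_frame(df)
        loc = resolve_theta_location(t, bc.ModelConfig())
        assert loc == pytest.approx(np.log((10 / 2 + 20 / 4) / 2))


class TestJointLogPosterior:
    def _setup(self, likelihood="poisson", prior="normal"):
        design = bc.SimulationDesign(
            n_regions=2, groups=["A", "B"], animals_per_group=2, seed=3,
            pi_truth=0.2 if likelihood == "zip" else 0.0,
        )
        table, _ = bc.simulate(design)
        cfg = bc.ModelConfig(
            likelihood=likelihood, random_effect_prior=prior,
            theta_prior_location=4.0,
        )
        rng = np.random.default_rng(1)
        p = bc.ParameterState(
            theta=4.0 + rng.normal(size=(2, 2)),
            gamma=0.1 * rng.normal(size=table.n_obs),
            tau=np.abs(rng.normal(0.0, 0.05, size=(2, 2))),
            kappa=np.abs(rng.normal(1.0, 0.2, size=table.n_obs))
            if prior == "horseshoe" else None,
            pi=0.1 if likelihood == "zip" else None,
        )
        return table, cfg, p

    @pytest.mark.parametrize("likelihood", ["poisson", "zip"])
    @pytest.mark.parametrize("prior", ["normal", "horseshoe"])
    def test_decomposes_into_independently_computed_parts(self, likelihood,
                                                          prior):
        table, cfg, p = self._setup(likelihood, prior)
        loglam = log_rates(p, table, cfg)
        lam = np.exp(loglam)
        if likelihood == "poisson":
            lik = sum(
                bc.poisson_log_pmf(int(y), la)
                for y, la in zip(table.counts, lam)
            )
        else:
            lik = sum(
                bc.zip_log_pmf(int(y), p.pi, la)
                for y, la in zip(table.counts, lam)
            )
        expected = (
            lik
            + bc.log_prior_gamma(p, table, cfg)
            + bc.log_prior_tau(p.tau, cfg.s)
            + bc.log_prior_theta(p.theta, cfg)
        )
        if likelihood == "zip":
            expected += log_prior_pi(p.pi, cfg)
        assert bc.joint_log_posterior(p, table, cfg) == pytest.approx(expected)

    def test_out_of_support_returns_log_zero_not_exception(self):
        table, cfg, p = self._setup()
        p.tau[0, 0] = -0.1
        assert bc.joint_log_posterior(p, table, cfg) == LOG_ZERO

    def test_theta_gamma_shift_changes_only_priors(self):
        """Adding c to every theta while subtracting c from every gamma leaves
        the likelihood untouched: the over-parameterisation of the log link."""
        table, cfg, p = self._setup()
        c = 0.37
        shifted = bc.ParameterState(
            theta=p.theta + c, gamma=p.gamma - c, tau=p.tau
        )
        base_lik = np.sum(
            table.counts * log_rates(p, table, cfg)
            - np.exp(log_rates(p, table, cfg))
            - gammaln(table.counts + 1.0)
        )
        shifted_lik = np.sum(
            table.counts * log_rates(shifted, table, cfg)
            - np.exp(log_rates(shifted, table, cfg))
            - gammaln(table.counts + 1.0)
        )
        assert shifted_lik == pytest.approx(base_lik)
        delta_joint = bc.joint_log_posterior(
            shifted, table, cfg
        ) - bc.joint_log_posterior(p, table, cfg)
        delta_priors = (
            bc.log_prior_theta(shifted.theta, cfg)
            - bc.log_prior_theta(p.theta, cfg)
            + bc.log_prior_gamma(shifted, table, cfg)
            - bc.log_prior_gamma(p, table, cfg)
        )
        assert delta_joint == pytest.approx(delta_priors)

    def test_pi_prior_matches_beta_density(self):
        cfg = bc.ModelConfig(likelihood="zip", pi_prior=(2.0, 5.0))
        assert log_prior_pi(0.3, cfg) == pytest.approx(
            beta_dist.logpdf(0.3, 2.0, 5.0)
        )
        assert log_prior_pi(-0.1, cfg) == LOG_ZERO


class TestModelConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"s": 1.0},
            {"s": 0.9},
            {"theta_prior_scale": 0.0},
            {"pi_prior": (0.0, 1.0)},
            {"likelihood": "hurdle"},
            {"random_effect_prior": "cauchy"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            bc.ModelConfig(**kwargs)

    def test_round_trip_dict(self):
        cfg = bc.ModelConfig(likelihood="zip", s=1.08, pi_prior=(2, 3))
        assert bc.ModelConfig.from_dict(cfg.to_dict()) == cfg
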