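import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit

from bbz.model import ModelSpec, ParameterState, PrevalenceModel, joint_log_posterior
from bbz.sampler import initialize_state
from bbz.simulate import SimConfig, generate_historical, generate_survey

from .conftest import single_cell_tables


def make_state(model, **overrides):
    st = initialize_state(model, seed=0)
    for k, v in overrides.items():
        setattr(st, k, v)
    return st


class TestModelSpec:
    @pytest.mark.parametrize(
        "name,flags",
        [
            ("BHBI", (False, False, False)),
            ("BZBI", (False, False, True)),
            ("BPLW", (True, True, False)),
            ("BBZ", (True, True, True)),
        ],
    )
    def test_variant_flag_mapping(self, name, flags):
        spec = ModelSpec.from_variant(name)
        assert (spec.use_weights, spec.use_power_prior, spec.use_zero_inflation) == flags
        assert spec.variant_name == name

    def test_invalid_alpha0(self):
        with pytest.raises(ValueError):
            ModelSpec(use_power_prior=True, alpha0=0.0)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            ModelSpec.from_variant("BOGUS")


class TestLinearPredictor:
    def test_all_zero_parameters_give_half(self):
        cells, _ = single_cell_tables(1, 10)
        m = PrevalenceModel(cells, spec=ModelSpec())
        st = ParameterState(
            beta=np.zeros(1), u_mu=np.zeros((1, 1)), u_v=np.zeros((1, 1)),
            log_sigma_mu=0.0, log_sigma_v=0.0,
        )
        assert m.cell_probs(st)[0, 0] == pytest.approx(0.5)

    def test_rare_disease_logit(self):
        cells, _ = single_cell_tables(1, 10)
        m = PrevalenceModel(cells, spec=ModelSpec())
        st = ParameterState(
            beta=np.array([-4.6]), u_mu=np.zeros((1, 1)), u_v=np.zeros((1, 1)),
            log_sigma_mu=0.0, log_sigma_v=0.0,
        )
        assert m.cell_probs(st)[0, 0] == pytest.approx(expit(-4.6), rel=1e-12)
        assert m.cell_probs(st)[0, 0] == pytest.approx(0.00995, abs=5e-5)

    def test_county_state_effect_tradeoff_is_invisible(self):
        cells, _ = single_cell_tables(1, 10)
        m = PrevalenceModel(cells, spec=ModelSpec())
        base = ParameterState(
            beta=np.array([-2.0]), u_mu=np.full((1, 1), 0.3), u_v=np.full((1, 1), -0.1),
            log_sigma_mu=0.0, log_sigma_v=0.0,
        )
        shifted = ParameterState(
            beta=np.array([-2.0]), u_mu=np.full((1, 1), 0.3 + 0.7),
            u_v=np.full((1, 1), -0.1 - 0.7), log_sigma_mu=0.0, log_sigma_v=0.0,
        )
        assert m.linear_predictor(base, 0, 0) == pytest.approx(
            m.linear_predictor(shifted, 0, 0), abs=1e-12
        )


class TestJointLogPosterior:
    def test_single_cell_mode_near_empirical_rate(self):
        # flat logit-scale prior: the posterior mode of p is y / n
        cells, _ = single_cell_tables(3, 20)
        spec = ModelSpec(include_county_re=False, include_state_re=False)
        m = PrevalenceModel(cells, spec=spec)

        def neg_post(b):
            st = ParameterState(
                beta=np.array([b]), u_mu=np.zeros((1, 1)), u_v=np.zeros((1, 1)),
                log_sigma_mu=0.0, log_sigma_v=0.0,
            )
            return -m.log_posterior(st)

        opt = minimize_scalar(neg_post, bounds=(-8, 2), method="bounded")
        assert expit(opt.x) == pytest.approx(3 / 20, abs=1e-3)

    def test_feature_flags_collapse_to_weighted_binomial(self):
        # BBZ with omega -> 0 and alpha0 -> 0 matches weights-only BHBI cell by cell
        cfg = SimConfig(n_states=2, counties_per_state=3, respondents_per_county=40, seed=9)
        rec, truth = generate_survey(cfg)
        hist = generate_historical(truth, cfg)
        bbz = PrevalenceModel.from_respondents(
            rec, spec=ModelSpec.from_variant("BBZ", alpha0=1e-12),
            historical_records=hist,
        )
        weighted_only = PrevalenceModel.from_respondents(
            rec, spec=ModelSpec(use_weights=True)
        )
        st = initialize_state(weighted_only, seed=0)
        eta = weighted_only.linear_predictor(st)
        omega_zero = np.zeros(bbz.C)
        np.testing.assert_allclose(
            bbz.cell_loglik(eta, omega_zero),
            weighted_only.cell_loglik(eta, None),
            atol=1e-9,
        )

    def test_conjugate_reduction_matches_beta_kernel(self):
        # with the Beta(a,b)-induced prior and no random effects, log-posterior
        # differences in beta equal Beta(a + y, b + n - y) log-density
        # differences on the logit scale
        a, b, y, n = 2.0, 3.0, 4.0, 30
        cells, _ = single_cell_tables(y, n)
        spec = ModelSpec(
            use_weights=True, include_county_re=False, include_state_re=False,
            beta_prior_beta=(a, b),
        )
        m = PrevalenceModel(cells, spec=spec)

        def lp(bval):
            st = ParameterState(
                beta=np.array([bval]), u_mu=np.zeros((1, 1)), u_v=np.zeros((1, 1)),
                log_sigma_mu=0.0, log_sigma_v=0.0,
            )
            return m.log_posterior(st)

        def beta_logit_logpdf(bval):
            p = expit(bval)
            # Beta(a + y, b + n - y) density on p times Jacobian p(1-p)
            return (a + y) * np.log(p) + (b + n - y) * np.log1p(-p)

        grid = np.linspace(-5, -1, 7)
        got = np.array([lp(g) for g in grid])
        want = np.array([beta_logit_logpdf(g) for g in grid])
        np.testing.assert_allclose(got - got[0], want - want[0], atol=1e-9)

    def test_finite_on_random_interior_states(self):
        cfg = SimConfig(n_states=2, counties_per_state=4, respondents_per_county=30, seed=5)
        rec, truth = generate_survey(cfg)
        hist = generate_historical(truth, cfg)
        m = PrevalenceModel.from_respondents(
            rec, spec=ModelSpec.from_variant("BBZ"), historical_records=hist
        )
        rng = np.random.default_rng(0)
        for _ in range(25):
            st = ParameterState(
                beta=rng.normal(-4, 2, m.J),
                u_mu=rng.standard_normal((m.C, m.J)),
                u_v=rng.standard_normal((m.S, m.J)),
                log_sigma_mu=float(rng.normal(-1, 1)),
                log_sigma_v=float(rng.normal(-1, 1)),
                logit_omega=rng.normal(0, 2, m.C),
            )
            assert np.isfinite(m.log_posterior(st))

    def test_functional_wrapper_agrees_with_method(self):
        cells, hist = single_cell_tables(2, 25, hist=[(4, 40)])
        spec = ModelSpec(
            use_weights=True, use_power_prior=True, alpha0=0.5,
            include_county_re=False, include_state_re=False,
        )
        m = PrevalenceModel(cells, spec=spec, historical=hist)
        st = make_state(m)
        assert joint_log_posterior(st, cells, hist, spec) == pytest.approx(
            m.log_posterior(st)
        )

    def test_historical_without_power_prior_rejected(self):
        cells, hist = single_cell_tables(2, 25, hist=[(4, 40)])
        with pytest.raises(ValueError):
            PrevalenceModel(cells, spec=ModelSpec(), historical=hist)

    def test_no_data_cells_contribute_nothing_to_likelihood(self):
        cells = pd.DataFrame(
            {
                "county": ["A", "A"],
                "state": ["S", "S"],
                "cluster": [1, 2],
                "n": [20, 0],
                "y": [3, 0],
                "y_eff": [3.0, 0.0],
                "no_data": [False, True],
            }
        )
        m = PrevalenceModel(cells, spec=ModelSpec())
        st = initialize_state(m, seed=0)
        eta = m.linear_predictor(st)
        ll = m.current_cell_loglik(eta, None)
        assert ll[0, 1] == 0.0
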