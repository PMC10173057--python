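"""Multivariate-Bernoulli occupancy: ψ construction, likelihood, fitting, AICc."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from guildniche import occupancy
from guildniche.detection_history import DetectionHistory
from guildniche.occupancy import (
    NaturalParameterSpec,
    aicc,
    conditional_occupancy,
    fit,
    loglik,
    marginal_occupancy,
    model_selection,
    param_names,
    prepare_covariates,
    psi_from_f,
)
from guildniche.synthetic_data import (
    SyntheticTruth,
    gen_covariates,
    gen_histories,
    gen_states,
    uniform_deployments,
)
from oracles import brute_force_loglik


def history_from(matrix, species="sp", site_prefix="S"):
    m = np.asarray(matrix, dtype=float)
    ids = [f"{site_prefix}{i}" for i in range(m.shape[0])]
    return DetectionHistory(species, ids, m, 7, {s: 7 * m.shape[1] for s in ids})


class TestPrepareCovariates:
    def test_sample_sd_standardization(self):
        cov = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=list("abc"))
        std, dropped = prepare_covariates(cov)
        assert np.allclose(std["x"], [-1.0, 0.0, 1.0])  # (n-1) sd convention
        assert dropped == []

    def test_duplicate_covariate_dropped_keeping_earlier(self):
        cov = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 6.0, 8.0]})
        std, dropped = prepare_covariates(cov)
        assert list(std.columns) == ["x"]
        assert dropped == ["y"]

    def test_independent_covariates_retained(self):
        rng = np.random.default_rng(0)
        cov = pd.DataFrame(rng.standard_normal((200, 3)), columns=list("abc"))
        std, dropped = prepare_covariates(cov)
        assert dropped == []
        assert np.allclose(std.mean(), 0, atol=1e-12)
        assert np.allclose(std.std(ddof=1), 1, atol=1e-12)

    def test_zero_variance_rejected_by_name(self):
        cov = pd.DataFrame({"flat": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="flat"):
            prepare_covariates(cov)


class TestPsiFromF:
    def test_all_zero_f_is_uniform(self):
        psi = psi_from_f([0.0, 0.0])
        assert np.allclose(psi.probs, 0.25)

    def test_positive_interaction_shifts_mass_to_joint_state(self):
        # potentials (1,1,1,2)/5 for states (00,10,01,11)
        psi = psi_from_f([0.0, 0.0], {(0, 1): math.log(2.0)})
        expect = {(0, 0): 0.2, (1, 0): 0.2, (0, 1): 0.2, (1, 1): 0.4}
        for state, p in expect.items():
            assert psi.prob(state) == pytest.approx(p)

    def test_extreme_positive_interaction_forces_agreement(self):
        psi = psi_from_f([0.0] * 4, {(0, 1): 60.0})
        mask = psi.states[:, 0] != psi.states[:, 1]
        assert psi.probs[mask].sum() < 1e-12

    def test_probabilities_sum_to_one_under_random_f(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            S = rng.integers(2, 5)
            f1 = rng.normal(0, 3, S)
            f2 = rng.normal(0, 3, S * (S - 1) // 2)
            psi = psi_from_f(f1, f2)
            assert psi.probs.sum() == pytest.approx(1.0, abs=1e-12)
            assert (psi.probs >= 0).all()

    def test_non_finite_f_rejected(self):
        with pytest.raises(ValueError):
            psi_from_f([np.nan, 0.0])

    def test_marginal_and_conditional_from_enumeration(self):
        psi = psi_from_f([0.0, 0.0], {(0, 1): math.log(2.0)}, species=("a", "b"))
        assert psi.marginal("a") == pytest.approx(0.6)
        assert psi.conditional("a", "b", 1) == pytest.approx(2.0 / 3.0)


class TestLoglik:
    def test_single_species_closed_form(self):
        # psi=0.5, p=0.5, history (0,0): L = 0.5*0.25 + 0.5 = 0.625
        spec = NaturalParameterSpec(("a",), {"a": []}, {}, {"a": []})
        hist = {"a": history_from([[0, 0]], "a")}
        ll = loglik(np.array([0.0, 0.0]), hist, None, spec)
        assert ll == pytest.approx(math.log(0.625), abs=1e-10)

    def test_detection_forces_occupied_states(self):
        # a site with a detection leaves only z=1 terms: L = psi * p(1-p)
        spec = NaturalParameterSpec(("a",), {"a": []}, {}, {"a": []})
        hist = {"a": history_from([[1, 0]], "a")}
        ll = loglik(np.array([0.0, 0.0]), hist, None, spec)
        assert ll == pytest.approx(math.log(0.5 * 0.25), abs=1e-10)

    @pytest.mark.parametrize("S,seed", [(2, 0), (2, 7), (3, 1), (3, 5)])
    def test_matches_brute_force_enumeration(self, S, seed):
        """Vectorized likelihood equals explicit latent-state enumeration."""
        rng = np.random.default_rng(seed)
        species = tuple(f"sp{k}" for k in range(S))
        n_sites, J = 8, 4
        hists, arrs = {}, {}
        for sp in species:
            m = rng.integers(0, 2, (n_sites, J)).astype(float)
            m[rng.random((n_sites, J)) < 0.2] = np.nan  # missing occasions
            hists[sp] = history_from(m, sp)
            arrs[sp] = m
        spec = NaturalParameterSpec.intercept_only(species)
        theta = rng.normal(0, 1, len(param_names(spec)))
        names = param_names(spec)
        f1 = {sp: theta[names.index(f"f[{sp}]:(Intercept)")] for sp in species}
        f2 = {
            (a, b): theta[names.index(f"f[{a}:{b}]:(Intercept)")]
            for a, b in itertools.combinations(species, 2)
        }
        p = {
            sp: 1 / (1 + math.exp(-theta[names.index(f"p[{sp}]:(Intercept)")]))
            for sp in species
        }
        expected = brute_force_loglik(arrs, f1, f2, p)
        assert loglik(theta, hists, None, spec) == pytest.approx(expected, abs=1e-10)

    def test_fully_missing_site_contributes_unit_detection_product(self):
        spec = NaturalParameterSpec(("a",), {"a": []}, {}, {"a": []})
        hist = {"a": history_from([[np.nan, np.nan]], "a")}
        ll = loglik(np.array([0.0, 0.0]), hist, None, spec)
        assert ll == pytest.approx(0.0, abs=1e-12)  # log(psi*1 + (1-psi)*1)


class TestFit:
    def test_single_species_matches_grid_search_mle(self):
        """Optimizer agrees with a brute-force grid over (psi, p) on S=1 data."""
        rng = np.random.default_rng(3)
        z = rng.random(300) < 0.6
        y = (rng.random((300, 6)) < 0.45) & z[:, None]
        spec = NaturalParameterSpec(("a",), {"a": []}, {}, {"a": []})
        hist = {"a": history_from(y.astype(float), "a")}
        res = fit(hist, None, spec, n_starts=3, seed=0)

        k1 = y.sum(axis=1)
        k0 = (~y).sum(axis=1)
        none = ~y.any(axis=1)

        def grid_best(psis, ps):
            det = ps[:, None] ** k1 * (1 - ps[:, None]) ** k0  # (B, n)
            best = (np.inf, None, None)
            for a in psis:
                nll = -np.log(a * det + (1 - a) * none).sum(axis=1)  # (B,)
                j = nll.argmin()
                if nll[j] < best[0]:
                    best = (nll[j], a, ps[j])
            return best

        coarse = grid_best(np.linspace(0.01, 0.99, 200), np.linspace(0.01, 0.99, 200))
        fine = grid_best(
            np.linspace(coarse[1] - 0.01, coarse[1] + 0.01, 201),
            np.linspace(coarse[2] - 0.01, coarse[2] + 0.01, 201),
        )
        psi_hat = 1 / (1 + math.exp(-res.estimates[0]))
        p_hat = 1 / (1 + math.exp(-res.estimates[1]))
        assert res.loglik == pytest.approx(-fine[0], abs=1e-4)
        assert psi_hat == pytest.approx(fine[1], abs=1e-3)
        assert p_hat == pytest.approx(fine[2], abs=1e-3)

    def test_independence_reduction_matches_single_species_fits(self):
        """With f_ab fixed at 0 the joint fit factorizes into per-species fits."""
        spec2 = NaturalParameterSpec.intercept_only(("a", "b"), pairwise=False)
        theta = np.array([0.3, -0.4, logit(0.5), logit(0.4)])
        truth = SyntheticTruth(
            spec=spec2,
            theta=theta,
            activity={"a": [(0.0, 1.0, 1.0)], "b": [(0.0, 1.0, 1.0)]},
            deployments=uniform_deployments(300, days=42),
        )
        cov = gen_covariates(300, 0, site_ids=[d.site_id for d in truth.deployments])
        states = gen_states(truth, cov, 11)
        hists, _ = gen_histories(states, truth, 12)
        joint = fit(hists, None, spec2, n_starts=2, seed=0)
        singles = []
        for sp in ("a", "b"):
            s1 = NaturalParameterSpec((sp,), {sp: []}, {}, {sp: []})
            singles.append(fit({sp: hists[sp]}, None, s1, n_starts=2, seed=0))
        assert joint.loglik == pytest.approx(sum(s.loglik for s in singles), abs=1e-5)
        single_params = np.concatenate(
            [[s.estimates[0] for s in singles], [s.estimates[1] for s in singles]]
        )
        assert np.allclose(joint.estimates, single_params, atol=1e-3)

    def test_recovers_generating_parameters_within_3_se(self):
        spec = NaturalParameterSpec.intercept_only(("a", "b"))
        names = param_names(spec)
        vals = {"f[a]:(Intercept)": 0.4, "f[b]:(Intercept)": -0.2,
                "f[a:b]:(Intercept)": 0.7,
                "p[a]:(Intercept)": logit(0.5), "p[b]:(Intercept)": logit(0.5)}
        theta = np.array([vals[n] for n in names])
        truth = SyntheticTruth(
            spec=spec, theta=theta,
            activity={"a": [(0.0, 1.0, 1.0)], "b": [(0.0, 1.0, 1.0)]},
            deployments=uniform_deployments(500, days=56),
        )
        cov = gen_covariates(500, 5, site_ids=[d.site_id for d in truth.deployments])
        states = gen_states(truth, cov, 6)
        hists, _ = gen_histories(states, truth, 7)
        res = fit(hists, None, spec, n_starts=3, seed=0)
        assert res.hessian_ok
        assert np.all(np.abs(res.estimates - theta) <= 3 * res.se)


class TestModelSelection:
    def test_aicc_identity_and_limits(self):
        assert aicc(-50.0, 3, 100) == pytest.approx(100 + 6 + 24 / 96)
        assert aicc(-50.0, 3, 100) > -2 * -50.0 + 2 * 3  # AICc > AIC
        assert aicc(-50.0, 3, 10**9) == pytest.approx(106.0, abs=1e-6)  # -> AIC

    def test_weights_closed_form(self):
        f = lambda a: occupancy.MultiOccuFit(
            spec=None, param_names=[], estimates=np.array([]), se=np.array([]),
            loglik=0.0, k=1, n_sites=50, aicc=a, converged=True, vcov=None,
            hessian_ok=False,
        )
        table = model_selection({"m1": f(100.0), "m2": f(102.0)})
        assert table["weight"].iloc[0] == pytest.approx(0.731, abs=5e-4)
        assert table["weight"].iloc[1] == pytest.approx(0.269, abs=5e-4)
        assert table["supported"].all()  # dAICc of exactly 2 is still "within 2"
        table3 = model_selection({"m1": f(100.0), "m3": f(104.0)})
        assert table3["supported"].tolist() == [True, False]

    def test_identical_models_share_weight(self):
        f = occupancy.MultiOccuFit(
            spec=None, param_names=[], estimates=np.array([]), se=np.array([]),
            loglik=-10.0, k=2, n_sites=50, aicc=25.0, converged=True, vcov=None,
            hessian_ok=False,
        )
        table = model_selection({"a": f, "b": f})
        assert np.allclose(table["weight"], 0.5)


class TestPrediction:
    def make_fit(self, theta, spec):
        return occupancy.MultiOccuFit(
            spec=spec, param_names=param_names(spec), estimates=np.asarray(theta),
            se=np.full(len(theta), np.nan), loglik=0.0, k=len(theta), n_sites=50,
            aicc=0.0, converged=True, vcov=None, hessian_ok=False,
        )

    def test_conditional_and_marginal_from_known_distribution(self):
        spec = NaturalParameterSpec.intercept_only(("a", "b"))
        theta = [0.0, 0.0, math.log(2.0), 0.0, 0.0]
        f = self.make_fit(theta, spec)
        assert marginal_occupancy(f, None, "a") == pytest.approx(0.6)
        point, ci = conditional_occupancy(f, None, "a", "b", 1, n_draws=0)
        assert point == pytest.approx(2.0 / 3.0)
        assert ci is None

    def test_independence_makes_conditional_equal_marginal(self):
        spec = NaturalParameterSpec.intercept_only(("a", "b"))
        theta = [0.7, -0.3, 0.0, 0.0, 0.0]
        f = self.make_fit(theta, spec)
        m = marginal_occupancy(f, None, "a")
        for state in (0, 1):
            point, _ = conditional_occupancy(f, None, "a", "b", state, n_draws=0)
            assert point == pytest.approx(m)

    def test_negative_interaction_orders_conditionals(self):
        spec = NaturalParameterSpec.intercept_only(("a", "b"))
        f = self.make_fit([0.2, 0.1, -1.5, 0.0, 0.0], spec)
        given_present, _ = conditional_occupancy(f, None, "a", "b", 1, n_draws=0)
        given_absent, _ = conditional_occupancy(f, None, "a", "b", 0, n_draws=0)
        assert given_present < given_absent
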