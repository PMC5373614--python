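"""EM machinery: responsibilities, closed-form pi update, GEM ascent, fit loop."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from elnnpaired import (
    FitConfig,
    MixtureModel,
    PairedDiffMatrix,
    e_step,
    expected_complete_loglik,
    fit,
    initialize,
    log_marginal_de,
    log_marginal_ne,
    m_step_pi,
    m_step_psi,
    natural_to_raw,
    observed_log_posterior,
    raw_to_natural,
)
from elnnpaired.em import Responsibilities, labels_from_resp
from elnnpaired.evaluate import agreement_indices
from elnnpaired.model import constraint_gap
from elnnpaired.simulate import g_scenario_model, simulate_elnn


def _default_model(pi=(1 / 3, 1 / 3, 1 / 3)):
    return MixtureModel(hyper=raw_to_natural(np.zeros(10)), pi=pi)


class TestEStep:
    def test_degenerate_prior_forces_hard_assignment(self, tiny_matrix):
        resp = e_step(tiny_matrix, _default_model(pi=(1.0, 0.0, 0.0)))
        assert np.allclose(resp.z_tilde, np.tile([1.0, 0.0, 0.0], (5, 1)))

    def test_mirrored_parameters_split_evenly_at_zero(self):
        d = PairedDiffMatrix(values=np.zeros((1, 2)) + 1e-300)
        resp = e_step(d, _default_model())
        z = resp.z_tilde[0]
        assert z[0] == pytest.approx(z[1], rel=1e-12)
        assert z.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_unlogged_bayes_ratio(self, rng):
        model = MixtureModel(hyper=raw_to_natural(rng.normal(size=10)),
                             pi=(0.2, 0.3, 0.5))
        d = PairedDiffMatrix(values=rng.normal(size=(5, 3)))
        resp = e_step(d, model)
        for g in range(5):
            fs = np.array([
                np.exp(log_marginal_de(d.values[g], model.hyper, 1)),
                np.exp(log_marginal_de(d.values[g], model.hyper, 2)),
                np.exp(log_marginal_ne(d.values[g], model.hyper)),
            ])
            direct = fs * np.array(model.pi)
            direct = direct / direct.sum()
            assert np.allclose(resp.z_tilde[g], direct, atol=1e-10)

    def test_rows_sum_to_one(self, g30_small):
        d, _ = g30_small
        resp = e_step(d, g_scenario_model())
        assert np.allclose(resp.z_tilde.sum(axis=1), 1.0, atol=1e-10)


class TestMStepPi:
    def test_all_mass_on_ne(self):
        G = 17
        z = np.tile([0.0, 0.0, 1.0], (G, 1))
        pi = m_step_pi(Responsibilities(z), b=2.0)
        assert pi == pytest.approx([1 / (G + 3), 1 / (G + 3), (G + 1) / (G + 3)])

    @pytest.mark.parametrize("b", [1.5, 2.0, 5.0])
    def test_uniform_responsibilities_give_thirds(self, b):
        z = np.full((9, 3), 1 / 3)
        assert m_step_pi(Responsibilities(z), b=b) == pytest.approx([1 / 3] * 3)

    def test_matches_simplex_optimizer(self, rng):
        z = rng.dirichlet([1, 1, 1], size=40)
        b = 2.0

        def neg_obj(pi):
            return -(np.sum(z.sum(axis=0) * np.log(pi)) + (b - 1) * np.log(pi).sum())

        res = minimize(neg_obj, np.array([1 / 3] * 3), method="SLSQP",
                       bounds=[(1e-9, 1)] * 3,
                       constraints={"type": "eq", "fun": lambda p: p.sum() - 1},
                       options={"ftol": 1e-14})
        closed = m_step_pi(Responsibilities(z), b=b)
        assert np.allclose(closed, res.x, atol=1e-6)
        assert closed.sum() == pytest.approx(1.0, abs=1e-12)


class TestExpectedCompleteLoglik:
    def test_single_gene_hand_expansion(self):
        model = _default_model()
        d = PairedDiffMatrix(values=np.array([[0.3, -0.1]]))
        resp = Responsibilities(np.array([[0.0, 0.0, 1.0]]))
        val = expected_complete_loglik(d, resp, model)
        expected = (
            log_marginal_ne(d.values[0], model.hyper)
            + np.log(1 / 3)
            + gammaln(6) - 3 * gammaln(2)
            + 3 * np.log(1 / 3)
        )
        assert val == pytest.approx(expected, rel=1e-12)

    def test_e_step_maximizes_the_entropy_augmented_bound(self, rng):
        # ELBO property: E_z[complete loglik] + H(z) peaks at the posterior
        def elbo(d, z, model):
            ent = -np.sum(np.where(z > 0, z * np.log(z), 0.0))
            return expected_complete_loglik(d, Responsibilities(z), model) + ent

        for _ in range(5):
            model = MixtureModel(hyper=raw_to_natural(rng.normal(size=10)),
                                 pi=(0.25, 0.25, 0.5))
            d = PairedDiffMatrix(values=rng.normal(size=(6, 3)))
            z_star = e_step(d, model).z_tilde
            best = elbo(d, z_star, model)
            for _ in range(10):
                other = rng.dirichlet([1, 1, 1], size=6)
                assert elbo(d, other, model) <= best + 1e-9

    def test_additive_over_gene_blocks(self, rng):
        model = _default_model()
        v = rng.normal(size=(8, 3))
        z = rng.dirichlet([1, 1, 1], size=8)
        whole = expected_complete_loglik(PairedDiffMatrix(values=v),
                                         Responsibilities(z), model)
        top = expected_complete_loglik(PairedDiffMatrix(values=v[:5]),
                                       Responsibilities(z[:5]), model)
        bottom = expected_complete_loglik(PairedDiffMatrix(values=v[5:]),
                                          Responsibilities(z[5:]), model)
        dirichlet = gammaln(6) - 3 * gammaln(2) + np.log(1 / 3) * 3
        assert whole == pytest.approx(top + bottom - dirichlet, rel=1e-10)


class TestMStepPsi:
    def _q_psi(self, d, z, theta):
        model = MixtureModel(hyper=raw_to_natural(theta.as_array()),
                             pi=(1 / 3, 1 / 3, 1 / 3))
        # psi-dependent part only
        from elnnpaired.model import log_marginals
        return float(np.sum(z * log_marginals(d.values, model.hyper)))

    def test_ascent_on_random_instances(self, rng):
        for _ in range(5):
            d = PairedDiffMatrix(values=rng.normal(size=(30, 5)))
            z = rng.dirichlet([1, 1, 1], size=30)
            theta0 = natural_to_raw(raw_to_natural(rng.normal(scale=0.5, size=10)))
            theta1 = m_step_psi(d, Responsibilities(z), theta0, rng=rng)
            assert self._q_psi(d, z, theta1) >= self._q_psi(d, z, theta0) - 1e-8

    def test_fixed_point_of_converged_fit(self, g30_small):
        d, _ = g30_small
        result = fit(d, FitConfig(seed=3))
        theta_star = natural_to_raw(result.model.hyper)
        z = result.resp.z_tilde
        theta_next = m_step_psi(d, Responsibilities(z), theta_star)
        q0 = self._q_psi(d, z, theta_star)
        q1 = self._q_psi(d, z, theta_next)
        assert q1 >= q0 - 1e-8
        assert abs(q1 - q0) <= max(1e-6 * abs(q0), 1e-4)

    def test_recovers_parameters_from_true_hard_labels(self):
        d, truth = simulate_elnn(10000, 100, seed=5)
        z = np.zeros((10000, 3))
        z[truth.labels == "OE", 0] = 1
        z[truth.labels == "UE", 1] = 1
        z[truth.labels == "NE", 2] = 1
        pi0, theta0 = initialize(d)
        theta = m_step_psi(d, Responsibilities(z), theta0)
        psi = raw_to_natural(theta.as_array())
        gen = g_scenario_model().hyper
        for name in ("mu1", "mu2", "alpha3", "beta3"):
            est, true = getattr(psi, name), getattr(gen, name)
            assert abs(est - true) / abs(true) < 0.10, (name, est, true)


class TestInitialize:
    def test_deterministic_and_feasible(self, g30_small):
        d, _ = g30_small
        pi_a, theta_a = initialize(d)
        pi_b, theta_b = initialize(d)
        assert np.array_equal(pi_a, pi_b)
        assert np.array_equal(theta_a.as_array(), theta_b.as_array())
        gaps = constraint_gap(raw_to_natural(theta_a.as_array()))
        assert min(gaps) > 0
        assert pi_a.sum() == pytest.approx(1.0) and np.all(pi_a >= 0.01 / 3)

    def test_provisional_labels_already_close_to_truth(self):
        d, truth = simulate_elnn(1000, 30, seed=13)
        pi0, theta0 = initialize(d)
        model = MixtureModel(hyper=raw_to_natural(theta0.as_array()), pi=tuple(pi0))
        labels0 = labels_from_resp(e_step(d, model))
        assert agreement_indices(truth.labels, labels0)["Rand"] > 0.9

    def test_sparse_cluster_falls_back_to_global_moments(self, rng, caplog):
        # pure-noise rows with tiny spread rarely cross the t cutoffs
        values = rng.normal(scale=0.01, size=(20, 10))
        pi0, theta0 = initialize(PairedDiffMatrix(values=values))
        assert np.all(np.isfinite(theta0.as_array()))


class TestFit:
    def test_objective_trace_non_decreasing(self, g30_small):
        d, _ = g30_small
        result = fit(d, FitConfig(seed=1))
        objs = [t["objective"] for t in result.trace]
        assert all(b >= a - 1e-6 for a, b in zip(objs, objs[1:]))
        assert result.converged

    def test_final_model_maximizes_observed_posterior_locally(self, g30_small):
        d, _ = g30_small
        result = fit(d, FitConfig(seed=1))
        assert observed_log_posterior(d, result.model) == pytest.approx(
            result.trace[-1]["objective"], rel=1e-9
        )

    def test_all_ne_data_keeps_dirichlet_floor(self):
        rngl = np.random.default_rng(4)
        tau = rngl.gamma(2.138, 1 / 0.131, size=600)
        values = rngl.normal(0.0, 1 / np.sqrt(tau)[:, None], size=(600, 30))
        result = fit(PairedDiffMatrix(values=values), FitConfig(seed=4))
        pi3 = result.model.pi[2]
        assert 0.95 < pi3 < 1.0
        assert min(result.model.pi) >= 1 / 603 - 1e-12

    def test_label_mirror_symmetry(self):
        d, _ = simulate_elnn(500, 20, seed=7)
        mirrored = PairedDiffMatrix(values=-d.values, gene_ids=d.gene_ids,
                                    pair_ids=d.pair_ids)
        r1 = fit(d, FitConfig(seed=7))
        r2 = fit(mirrored, FitConfig(seed=7))
        assert (r1.labels == "OE").sum() == (r2.labels == "UE").sum()
        assert (r1.labels == "UE").sum() == (r2.labels == "OE").sum()
        assert (r1.labels == "NE").sum() == (r2.labels == "NE").sum()

    def test_labels_are_argmax_with_ne_ties(self):
        z = np.array([[0.6, 0.3, 0.1], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6],
                      [0.5, 0.5, 0.0]])
        labels = labels_from_resp(Responsibilities(z))
        assert list(labels) == ["OE", "UE", "NE", "NE"]
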