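import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import gammaln

from bym2map.geometry import AreaPolygonSet, build_queen_adjacency
from bym2map.model import (
    HyperPriors,
    LatentState,
    PCMixingPrior,
    icar_precision,
    log_joint,
    make_spec,
    pc_prior_sigma_logpdf,
    pc_prior_sigma_rate,
    scaled_structure,
    scaling_factor,
)
from bym2map.synthetic import make_lattice
from shapely.geometry import box


def _pair_graph():
    return build_queen_adjacency(
        AreaPolygonSet(["L", "R"], [box(0, 0, 1, 1), box(1, 0, 2, 1)])
    )


def _path3_graph():
    return build_queen_adjacency(
        AreaPolygonSet(
            ["L", "C", "R"], [box(0, 0, 1, 1), box(1, 0, 2, 1), box(2, 0, 3, 1)]
        )
    )


class TestICARPrecision:
    def test_two_adjacent_areas(self):
        Q = icar_precision(_pair_graph()).toarray()
        np.testing.assert_allclose(Q, [[1, -1], [-1, 1]])

    def test_path_graph_diagonal_and_row_sums(self):
        Q = icar_precision(_path3_graph()).toarray()
        np.testing.assert_allclose(np.diag(Q), [1, 2, 1])
        np.testing.assert_allclose(Q.sum(axis=1), 0, atol=1e-12)

    @pytest.mark.parametrize("islands", [0, 2])
    def test_null_space_dimension_matches_components(self, islands):
        g = build_queen_adjacency(make_lattice(4, 4, islands))
        Q = icar_precision(g).toarray()
        lam = np.linalg.eigvalsh(Q)
        # zero eigenvalue multiplicity = number of components (lattice + each island)
        assert (np.abs(lam) < 1e-9).sum() == 1 + islands


class TestScalingFactor:
    def test_complete_graph_equal_variances(self):
        # K_4: all constrained marginal variances equal the common pinv diagonal
        n = 4
        Q = n * np.eye(n) - np.ones((n, n)) - (np.eye(n) * 0)
        Q = np.diag([n - 1.0] * n) - (np.ones((n, n)) - np.eye(n))
        lam, vec = np.linalg.eigh(Q)
        kappa = scaling_factor(lam, vec)
        diag = np.diag(np.linalg.pinv(Q))
        np.testing.assert_allclose(diag, diag[0])
        assert kappa == pytest.approx(diag[0])

    def test_path3_matches_explicit_pseudo_inverse(self):
        Q = icar_precision(_path3_graph()).toarray()
        lam, vec = np.linalg.eigh(Q)
        kappa = scaling_factor(lam, vec)
        diag = np.diag(np.linalg.pinv(Q))
        assert kappa == pytest.approx(np.exp(np.mean(np.log(diag))))

    def test_island_component_skipped(self):
        g = build_queen_adjacency(make_lattice(3, 3, 1))
        st = scaled_structure(g)
        assert len(st.components) == 1
        assert len(st.kappa) == 1
        assert st.islands.tolist() == [g.nodes.index("I0")]

    def test_scaled_structure_geometric_mean_variance_one(self, graph6):
        st = scaled_structure(graph6)
        (idx,), (lam,), (vec,), (kap,) = (
            st.components, st.eigvals, st.eigvecs, st.kappa,
        )
        pos = lam > 1e-9
        marg = (vec[:, pos] ** 2 / (kap * lam[pos])).sum(axis=1)
        assert np.exp(np.mean(np.log(marg))) == pytest.approx(1.0, abs=1e-6)


class TestPCPriorSigma:
    def test_tail_probability_exact(self):
        U = 0.2 / 0.31
        lam = pc_prior_sigma_rate(U, 0.01)
        assert math.exp(-lam * U) == pytest.approx(0.01, rel=1e-12)

    def test_density_normalizes(self):
        U, a = 0.2 / 0.31, 0.01
        total, _ = quad(lambda s: math.exp(pc_prior_sigma_logpdf(s, U, a)), 0, 50)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_rate_closed_form_vs_numeric_root(self):
        U, a = 0.2 / 0.31, 0.01
        lam_closed = -math.log(a) / U
        lam_numeric = brentq(lambda lam: math.exp(-lam * U) - a, 1e-6, 100)
        assert lam_closed == pytest.approx(lam_numeric, rel=1e-9)
        assert pc_prior_sigma_rate(U, a) == pytest.approx(lam_closed)

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            pc_prior_sigma_rate(-1.0, 0.01)
        with pytest.raises(ValueError):
            pc_prior_sigma_rate(1.0, 1.5)


class TestPCMixingPrior:
    def test_cdf_at_u_equals_alpha_on_6x6(self, graph6):
        pr = PCMixingPrior(scaled_structure(graph6), 0.5, 2 / 3)
        cdf_U, _ = quad(lambda p: math.exp(pr.logpdf(p)), 1e-9, 0.5, limit=200)
        assert cdf_U == pytest.approx(2 / 3, abs=1e-3)

    def test_density_normalizes_on_unit_interval(self, graph6):
        pr = PCMixingPrior(scaled_structure(graph6), 0.5, 2 / 3)
        total, _ = quad(lambda p: math.exp(pr.logpdf(p)), 1e-9, 1 - 1e-9, limit=200)
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_rate_monotone_in_alpha(self, graph6):
        # P(phi < U) = alpha asks for mass near the base model, so a larger
        # alpha needs a stronger pull toward phi = 0, i.e. a larger rate
        st = scaled_structure(graph6)
        rates = [PCMixingPrior(st, 0.5, a).rate for a in (0.6, 0.7, 0.8, 0.9)]
        assert all(r2 > r1 for r1, r2 in zip(rates, rates[1:]))

    def test_infeasible_alpha_raises_with_diagnostics(self, graph6):
        # below the rate->0 limit no positive rate meets the tail condition
        with pytest.raises(RuntimeError, match="rate"):
            PCMixingPrior(scaled_structure(graph6), 0.5, 0.2)

    def test_gradient_matches_finite_difference(self, graph6):
        pr = PCMixingPrior(scaled_structure(graph6), 0.5, 2 / 3)
        for phi in (0.05, 0.3, 0.7, 0.95):
            h = 1e-6
            num = (pr.logpdf(phi + h) - pr.logpdf(phi - h)) / (2 * h)
            assert pr.dlogpdf_dphi(phi) == pytest.approx(num, rel=1e-4)


class TestLogJoint:
    def _spec(self, graph):
        rng = np.random.default_rng(0)
        E = rng.uniform(5, 50, graph.n)
        O = rng.poisson(E)
        return make_spec(O, E, graph)

    def _zero_state(self, spec):
        return LatentState(
            mu=0.0, phi=0.4, sigma=0.3,
            v=np.zeros(spec.n), u_star=np.zeros(spec.n),
        )

    def test_zero_effects_poisson_closed_form(self, graph3):
        spec = self._spec(graph3)
        from bym2map.model import poisson_loglik

        ll = poisson_loglik(self._zero_state(spec), spec)
        expected = np.sum(
            spec.observed * np.log(spec.expected)
            - spec.expected
            - gammaln(spec.observed + 1)
        )
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_offset_doubling_identity(self, graph3):
        spec = self._spec(graph3)
        spec2 = make_spec(spec.observed, 2 * spec.expected, graph3)
        st = self._zero_state(spec)
        delta = log_joint(st, spec2) - log_joint(st, spec)
        expected = spec.observed.sum() * math.log(2) - spec.expected.sum()
        assert delta == pytest.approx(expected, rel=1e-10)

    def test_agrees_with_dense_reimplementation(self, graph3):
        """Naive dense-matrix evaluation of every term on a 3x3 lattice."""
        spec = self._spec(graph3)
        rng = np.random.default_rng(1)
        st_struct = spec.structure
        # constrained scaled-ICAR draw to satisfy the constraints exactly
        from bym2map.synthetic import sample_scaled_icar

        u_star = sample_scaled_icar(graph3, seed=2)
        state = LatentState(
            mu=0.13, phi=0.55, sigma=0.47,
            v=rng.normal(size=spec.n), u_star=u_star,
        )
        got = log_joint(state, spec)

        # independent dense computation
        b = state.sigma * (
            math.sqrt(1 - state.phi) * state.v + math.sqrt(state.phi) * u_star
        )
        lam = spec.expected * np.exp(state.mu + b)
        ll = np.sum(
            spec.observed * np.log(lam) - lam - gammaln(spec.observed + 1)
        )
        lp_v = np.sum(-0.5 * state.v**2 - 0.5 * math.log(2 * math.pi))
        Q = st_struct.Q.toarray()
        kap = st_struct.kappa[0]
        lam_e = np.linalg.eigvalsh(kap * Q)
        pos = lam_e > 1e-9
        lp_u = (
            0.5 * np.sum(np.log(lam_e[pos]))
            - 0.5 * pos.sum() * math.log(2 * math.pi)
            - 0.5 * kap * u_star @ Q @ u_star
        )
        hp = spec.hyperpriors
        lam_s = -math.log(hp.alpha_sigma) / hp.U_sigma
        lp_sigma = math.log(lam_s) - lam_s * state.sigma
        lp_phi = spec.phi_prior.logpdf(state.phi)
        lp_mu = (
            -0.5 * (state.mu / 5.0) ** 2 - math.log(5.0) - 0.5 * math.log(2 * math.pi)
        )
        assert got == pytest.approx(
            ll + lp_v + lp_u + lp_sigma + lp_phi + lp_mu, abs=1e-8
        )

    def test_constraint_violation_rejected(self, graph3):
        spec = self._spec(graph3)
        state = self._zero_state(spec)
        state.u_star = np.ones(spec.n)  # violates sum-to-zero
        with pytest.raises(ValueError, match="sum-to-zero"):
            log_joint(state, spec)

    def test_invariant_under_node_relabeling(self):
        areas = make_lattice(3, 3, 0)
        rng = np.random.default_rng(5)
        order = rng.permutation(len(areas))
        shuffled = AreaPolygonSet(
            [areas.area_ids[k] for k in order], [areas.geometries[k] for k in order]
        )
        g1 = build_queen_adjacency(areas)
        g2 = build_queen_adjacency(shuffled)
        E = rng.uniform(5, 50, g1.n)
        O = rng.poisson(E)
        from bym2map.synthetic import sample_scaled_icar

        u1 = sample_scaled_icar(g1, seed=3)
        v1 = rng.normal(size=g1.n)
        perm = [g2.nodes.index(a) for a in g1.nodes]  # g1 order -> g2 positions
        spec1 = make_spec(O, E, g1)
        O2, E2 = np.empty_like(O), np.empty_like(E)
        u2, v2 = np.empty_like(u1), np.empty_like(v1)
        O2[perm], E2[perm], u2[perm], v2[perm] = O, E, u1, v1
        spec2 = make_spec(O2, E2, g2)
        s1 = LatentState(0.1, 0.5, 0.4, v1, u1)
        s2 = LatentState(0.1, 0.5, 0.4, v2, u2)
        assert log_joint(s1, spec1) == pytest.approx(log_joint(s2, spec2), rel=1e-10)

    def test_zero_expected_rejected(self, graph3):
        E = np.ones(graph3.n)
        E[0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            make_spec(np.zeros(graph3.n), E, graph3)


def test_hyperprior_validation():
    with pytest.raises(ValueError):
        HyperPriors(U_phi=1.5)
    with pytest.raises(ValueError):
        HyperPriors(alpha_sigma=0.0)
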