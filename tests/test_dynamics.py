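"""Rate matrices, steady states, fluxes, relaxation, mutant prefactors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import onoffslide as oos
from onoffslide.dynamics import (
    ParameterVector,
    PrefactorVector,
    ReducibleChainError,
    prefactor_energy_bound,
    translocation_speed,
)


def _bare_params(ra=2.0, rd=1.0):
    return ParameterVector({"A": {s: ra for s in oos.STATES}, "D": rd})


def bare_model(reg="A"):
    return oos.ModelSpec.make(("A", "D"), (reg,))


from functools import lru_cache


@lru_cache(maxsize=4)
def _catalog(budget=6):
    return oos.enumerate_models(budget)


def random_model_and_params(rng, budget=6):
    models = _catalog(budget)
    m = models[rng.integers(len(models))]
    rates = {}
    for pid in m.processes:
        if pid in m.regulated:
            rates[pid] = {s: float(rng.uniform(0.05, 20)) for s in oos.STATES}
        else:
            rates[pid] = float(rng.uniform(0.05, 20))
    return m, ParameterVector(rates)


class TestRateMatrix:
    def test_best_model_sparsity_matches_governance(self, best_model):
        """Entries of the activated matrix for the five-process reference model."""
        asg = oos.resolve_governance(best_model)
        p = ParameterVector({
            "A": {"repressed": 3.0, "weakly_activated": 2.0, "activated": 1.0},
            "D": 0.5, "D1-4": 1.7, "S2*": 1.3, "S3-4": 0.9})
        Q = asg and oos.build_rate_matrix(asg, p, "activated")
        assert Q[0, 3] == 1.7            # 1->4 governed by D1-4
        assert Q[0, 1] == Q[0, 2] == 0.5  # remaining disassemblies from config 1
        assert Q[6, 5] == 0.0            # slide 7->6 uncovered: rate zero
        assert Q[5, 4] == Q[5, 6] == 1.3  # S2* slides out of N-2 from config 6
        assert Q[1, 2] == 1.3            # slide 2->3 also governed by S2*
        assert Q[2, 3] == 0.9            # S3-4
        assert Q[1, 0] == 1.0            # assembly at activated rate 1

    def test_rows_sum_to_zero(self, rng):
        for _ in range(5):
            m, p = random_model_and_params(rng)
            for state in oos.STATES:
                Q = oos.build_rate_matrix(oos.resolve_governance(m), p, state)
                assert np.abs(Q.sum(axis=1)).max() < 1e-14

    def test_bare_model_direct_construction(self):
        Q = oos.build_rate_matrix(oos.resolve_governance(bare_model()),
                                  _bare_params(2.0, 1.0), "activated")
        assert Q[7, 4] == Q[7, 5] == Q[7, 6] == 2.0  # assemblies out of empty
        assert Q[0, 1] == Q[0, 2] == Q[0, 3] == 1.0  # disassemblies out of full

    def test_regulated_rate_depends_on_state(self):
        p = ParameterVector({"A": {"repressed": 5.0, "weakly_activated": 2.0,
                                   "activated": 1.0}, "D": 1.0})
        asg = oos.resolve_governance(bare_model())
        assert oos.build_rate_matrix(asg, p, "repressed")[7, 4] == 5.0
        assert oos.build_rate_matrix(asg, p, "activated")[7, 4] == 1.0

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            oos.build_rate_matrix(oos.resolve_governance(bare_model()),
                                  ParameterVector({"A": {s: 1.0 for s in oos.STATES},
                                                   "D": 0.0}), "activated")


class TestSteadyState:
    def test_symmetric_bare_model_is_uniform(self):
        Q = oos.build_rate_matrix(oos.resolve_governance(bare_model()),
                                  _bare_params(1.0, 1.0), "activated")
        assert np.allclose(oos.steady_state(Q), 1 / 8, atol=1e-14)

    def test_bare_model_product_bernoulli_closed_form(self, space):
        Q = oos.build_rate_matrix(oos.resolve_governance(bare_model()),
                                  _bare_params(2.0, 1.0), "activated")
        p = oos.steady_state(Q)
        for cfg in space.configurations:
            k = sum(cfg.occupancy)
            assert p[cfg.index - 1] == pytest.approx(
                (2 / 3) ** k * (1 / 3) ** (3 - k), abs=1e-13)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_gth_matches_dense_nullspace(self, seed):
        rng = np.random.default_rng(seed)
        m, p = random_model_and_params(rng)
        state = oos.STATES[rng.integers(3)]
        Q = oos.build_rate_matrix(oos.resolve_governance(m), p, state)
        ss = oos.steady_state(Q)
        assert np.abs(ss - oos.steady_state_dense(Q)).max() < 1e-12
        assert np.abs(ss @ Q).max() < 1e-12
        assert ss.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reducible_chain_detected(self):
        Q = np.zeros((8, 8))
        Q[0, 1] = 1.0
        np.fill_diagonal(Q, -Q.sum(axis=1))
        with pytest.raises(ReducibleChainError):
            oos.steady_state(Q)


class TestAccessibility:
    def test_point_masses(self):
        p = np.zeros(8); p[0] = 1.0
        assert np.array_equal(oos.site_accessibility(p), [0, 0, 0])
        p = np.zeros(8); p[7] = 1.0
        assert np.array_equal(oos.site_accessibility(p), [1, 1, 1])

    def test_product_bernoulli_closed_form(self):
        Q = oos.build_rate_matrix(oos.resolve_governance(bare_model()),
                                  _bare_params(2.0, 1.0), "activated")
        acc = oos.site_accessibility(oos.steady_state(Q))
        assert np.allclose(acc, 1 / 3, atol=1e-13)


class TestFluxes:
    def test_equilibrium_model_has_zero_net_fluxes(self):
        Q = oos.build_rate_matrix(oos.resolve_governance(bare_model()),
                                  _bare_params(3.0, 0.7), "repressed")
        J = oos.net_fluxes(Q, oos.steady_state(Q))
        assert np.abs(J).max() < 1e-12

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_antisymmetry_and_kirchhoff_conservation(self, seed):
        rng = np.random.default_rng(seed)
        m, p = random_model_and_params(rng)
        Q = oos.build_rate_matrix(oos.resolve_governance(m), p, "repressed")
        J = oos.net_fluxes(Q, oos.steady_state(Q))
        assert np.abs(J + J.T).max() < 1e-14
        assert np.abs(J.sum(axis=1)).max() < 1e-10

    def test_site_centric_balance_at_steady_state(self, ground_truth):
        asg = oos.resolve_governance(ground_truth.model)
        for state in oos.STATES:
            Q = oos.build_rate_matrix(asg, ground_truth.params, state)
            J = oos.net_fluxes(Q, oos.steady_state(Q))
            sc = oos.site_centric_net_fluxes(J)
            assert np.abs(sc.site_balance()).max() < 1e-10

    def test_equilibrium_model_site_centric_all_zero(self):
        Q = oos.build_rate_matrix(oos.resolve_governance(bare_model()),
                                  _bare_params(3.0, 0.7), "activated")
        sc = oos.site_centric_net_fluxes(oos.net_fluxes(Q, oos.steady_state(Q)))
        assert np.abs(sc.as_array()).max() < 1e-12

    def test_time_scale_rescales_fluxes_linearly(self, ground_truth):
        asg = oos.resolve_governance(ground_truth.model)
        Q = oos.build_rate_matrix(asg, ground_truth.params, "repressed")
        p = oos.steady_state(Q)
        J1 = oos.net_fluxes(Q, p)
        J2 = oos.net_fluxes(3.0 * Q, oos.steady_state(3.0 * Q))
        assert np.allclose(J2, 3.0 * J1, atol=1e-12)


class TestRelaxation:
    def test_bare_model_rate_is_sum_of_site_rates(self):
        # independent sites: the spectrum is sums of single-site eigenvalues
        # {0, -(rA+rD)}, so the slowest nonzero mode is rA + rD
        Q = oos.build_rate_matrix(oos.resolve_governance(bare_model()),
                                  _bare_params(2.5, 0.5), "activated")
        assert oos.relaxation_rate(Q) == pytest.approx(3.0, rel=1e-12)
        assert oos.relaxation_rate(Q, time_scale=2.0) == pytest.approx(6.0)

    def test_slow_mode_decay_matches_eigenvalue(self, ground_truth):
        """Integrating a perturbation along the slowest eigenmode decays
        exponentially at exactly the reported relaxation rate."""
        asg = oos.resolve_governance(ground_truth.model)
        Q = oos.build_rate_matrix(asg, ground_truth.params, "activated")
        rate = oos.relaxation_rate(Q)
        p_inf = oos.steady_state(Q)
        ev, vecs = np.linalg.eig(Q.T)
        order = np.argsort(-ev.real)
        v2 = vecs[:, order[1]].real
        v2 /= np.abs(v2).max()
        eps = 0.5 * p_inf.min()
        p0 = p_inf + eps * (v2 - v2.sum() / 8)
        assert p0.min() > 0
        p0 /= p0.sum()
        t1, t2 = 1.0 / rate, 2.0 / rate
        traj = oos.distribution_dynamics(Q, p0, [t1, t2])
        d1 = np.linalg.norm(traj[0] - p_inf)
        d2 = np.linalg.norm(traj[1] - p_inf)
        fitted = -np.log(d2 / d1) / (t2 - t1)
        assert fitted == pytest.approx(rate, rel=0.01)


class TestDistributionDynamics:
    def test_steady_state_is_a_fixed_point(self, ground_truth):
        asg = oos.resolve_governance(ground_truth.model)
        Q = oos.build_rate_matrix(asg, ground_truth.params, "repressed")
        p = oos.steady_state(Q)
        traj = oos.distribution_dynamics(Q, p, [0.0, 1.0, 10.0])
        assert np.abs(traj - p).max() < 1e-9

    def test_matches_matrix_exponential(self, rng):
        for _ in range(3):
            m, p = random_model_and_params(rng)
            Q = oos.build_rate_matrix(oos.resolve_governance(m), p, "activated")
            p0 = rng.dirichlet(np.ones(8))
            times = [0.3, 1.1]
            traj = oos.distribution_dynamics(Q, p0, times, time_scale=0.7)
            for t, row in zip(times, traj):
                oracle = expm(0.7 * Q.T * t) @ p0
                assert np.abs(row - oracle).max() < 1e-8

    def test_opening_transient_maximum_for_config3(self, ground_truth):
        """Switching repressed -> activated overshoots configuration 3."""
        asg = oos.resolve_governance(ground_truth.model)
        Q_rep = oos.build_rate_matrix(asg, ground_truth.params, "repressed")
        Q_act = oos.build_rate_matrix(asg, ground_truth.params, "activated")
        p0 = oos.steady_state(Q_rep)
        p_inf = oos.steady_state(Q_act)
        times = np.linspace(0, 20, 200)
        traj = oos.distribution_dynamics(Q_act, p0, times)
        c3 = traj[:, 2]
        assert c3.max() > max(p0[2], p_inf[2])


class TestMutantPrefactors:
    def test_identity_prefactors_leave_matrix_unchanged(self, ground_truth):
        asg = oos.resolve_governance(ground_truth.model)
        Q = oos.build_rate_matrix(asg, ground_truth.params, "activated")
        assert np.array_equal(oos.apply_mutant_prefactors(Q, PrefactorVector()), Q)

    def test_prefactor_placement(self):
        Q = oos.build_rate_matrix(oos.resolve_governance(bare_model()),
                                  _bare_params(2.0, 1.0), "activated")
        kappa = PrefactorVector(a3=3.0, d3=0.5, s23=1.0, s32=1.0)
        W = oos.apply_mutant_prefactors(Q, kappa)
        # N-3 assemblies x3: 4->1, 5->3, 6->2, 8->7
        for (i, j) in ((4, 1), (5, 3), (6, 2), (8, 7)):
            assert W[i - 1, j - 1] == 3.0 * Q[i - 1, j - 1] != 0
        # N-3 disassemblies x0.5
        for (i, j) in ((1, 4), (3, 5), (2, 6), (7, 8)):
            assert W[i - 1, j - 1] == 0.5 * Q[i - 1, j - 1] != 0
        untouched = np.ones((8, 8), bool)
        for (i, j) in ((4, 1), (5, 3), (6, 2), (8, 7), (1, 4), (3, 5), (2, 6), (7, 8)):
            untouched[i - 1, j - 1] = False
        np.fill_diagonal(untouched, False)
        assert np.array_equal(W[untouched], Q[untouched])

    def test_bare_model_foldchange_closed_form(self):
        ra, rd = 2.0, 1.0
        asg = oos.resolve_governance(bare_model())
        Q = oos.build_rate_matrix(asg, _bare_params(ra, rd), "activated")
        W = oos.apply_mutant_prefactors(Q, PrefactorVector(d3=1 / 5))
        acc_wt = oos.site_accessibility(oos.steady_state(Q))
        acc_mut = oos.site_accessibility(oos.steady_state(W))
        expected = ((rd / 5) / (ra + rd / 5)) / (rd / (ra + rd))
        assert acc_mut[2] / acc_wt[2] == pytest.approx(expected, rel=1e-12)
        assert acc_mut[0] / acc_wt[0] == pytest.approx(1.0)  # N-1 untouched

    def test_prefactor_bounds_enforced(self):
        with pytest.raises(ValueError):
            PrefactorVector(a3=6.0)


class TestAnalyticBounds:
    def test_prefactor_energy_bound_is_ln25(self):
        assert prefactor_energy_bound() == pytest.approx(np.log(25.0))

    def test_translocation_speed(self):
        assert translocation_speed(5.0, 160.0) == pytest.approx(800 / 3600)
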