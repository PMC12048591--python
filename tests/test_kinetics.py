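"""Steady-state solvers: closed forms, cross-solver agreement, ODE oracle, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from gpdiv.kinetics import (
    AltTranscriptionSpec,
    DegenerateSystemError,
    KineticSystem,
    equilibrium_alt_transcription,
    equilibrium_branching,
    equilibrium_chain,
    equilibrium_general,
    equilibrium_multisite,
    equilibrium_two_isoform,
    modification_level,
)


def ode_equilibrium(alpha, beta_matrix, gammas, t_end=2e4):
    """Independent oracle: forward-integrate the rate equations to (near) steady state."""
    B = np.asarray(beta_matrix, float)
    g = np.asarray(gammas, float)
    n = g.size

    def rhs(_, p):
        inflow = B.T @ p
        outflow = (B.sum(axis=1) + g) * p
        src = np.zeros(n)
        src[0] = alpha
        return src + inflow - outflow

    sol = solve_ivp(rhs, (0, t_end), np.zeros(n), rtol=1e-11, atol=1e-12, method="LSODA")
    return sol.y[:, -1]


class TestTwoIsoform:
    @pytest.mark.parametrize(
        "alpha,beta,g0,g1,expected_p,expected_f",
        [
            (1.0, 0.0, 1.0, 1.0, (1.0, 0.0), 0.0),
            (1.0, 1.0, 1.0, 1.0, (0.5, 0.5), 0.5),
        ],
    )
    def test_closed_form(self, alpha, beta, g0, g1, expected_p, expected_f):
        state = equilibrium_two_isoform(alpha, beta, g0, g1)
        assert np.allclose(state.abundances, expected_p)
        assert state.level == pytest.approx(expected_f)

    def test_matches_ode_integration(self):
        state = equilibrium_two_isoform(2.0, 0.3, 1.0, 0.5)
        B = np.array([[0.0, 0.3], [0.0, 0.0]])
        oracle = ode_equilibrium(2.0, B, [1.0, 0.5])
        assert np.allclose(state.abundances, oracle, atol=1e-8)
        assert state.level == pytest.approx(0.3 / 0.8)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateSystemError):
            equilibrium_two_isoform(1.0, 0.0, 0.0, 1.0)  # no outflow from I0
        with pytest.raises(DegenerateSystemError):
            equilibrium_two_isoform(1.0, 1.0, 1.0, 0.0)  # I1 accumulates

    @given(
        beta=st.floats(0.01, 50), gamma1=st.floats(0.01, 50),
        beta2=st.floats(0.01, 50), gamma1b=st.floats(0.01, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_level_monotone_in_beta_and_gamma1(self, beta, gamma1, beta2, gamma1b):
        lo_b, hi_b = sorted({beta, beta2} | {beta + 0.1})[:2]
        f_lo = equilibrium_two_isoform(1.0, lo_b, 1.0, gamma1).level
        f_hi = equilibrium_two_isoform(1.0, hi_b, 1.0, gamma1).level
        assert f_hi > f_lo  # strictly increasing in beta
        lo_g, hi_g = sorted({gamma1, gamma1b} | {gamma1 + 0.1})[:2]
        assert (
            equilibrium_two_isoform(1.0, beta, 1.0, hi_g).level
            < equilibrium_two_isoform(1.0, beta, 1.0, lo_g).level
        )  # strictly decreasing in gamma1

    @given(alpha=st.floats(0.1, 100), k=st.floats(0.1, 100))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance_in_alpha(self, alpha, k):
        s1 = equilibrium_two_isoform(alpha, 0.7, 1.0, 2.0)
        s2 = equilibrium_two_isoform(k * alpha, 0.7, 1.0, 2.0)
        assert np.allclose(s2.abundances, k * s1.abundances, rtol=1e-12)
        assert s2.level == pytest.approx(s1.level)


class TestBranching:
    def test_splicing_default_precursor_fraction(self):
        # Q=100, C=1, eps=0, v_hat=1 => beta=(100, 0); gamma=(0, 1, 20)
        state = equilibrium_branching(1.0, np.array([100.0, 0.0]), np.array([0.0, 1.0, 20.0]))
        assert np.allclose(state.abundances, [0.01, 1.0, 0.0])
        assert state.abundances[0] / state.total == pytest.approx(1 / 101)

    def test_against_generic_linear_solver(self):
        # independent oracle: build the 3x3 system directly and solve it
        alpha, b1, b2, g = 1.0, 50.0, 50.0, (0.0, 1.0, 20.0)
        A = np.array([[b1 + b2 + g[0], 0, 0], [b1, -g[1], 0], [b2, 0, -g[2]]])
        oracle = np.linalg.solve(A, np.array([alpha, 0.0, 0.0]))
        state = equilibrium_branching(alpha, np.array([b1, b2]), np.array(g))
        assert np.allclose(state.abundances, oracle, atol=1e-12)
        assert state.level == pytest.approx(0.047619, abs=1e-6)

    def test_single_branch_reduces_to_two_isoform(self):
        a = equilibrium_branching(2.0, np.array([0.3]), np.array([1.0, 0.5]))
        b = equilibrium_two_isoform(2.0, 0.3, 1.0, 0.5)
        assert np.allclose(a.abundances, b.abundances, atol=1e-12)
        assert a.level == pytest.approx(b.level)


class TestChain:
    def test_closed_form_three_isoforms(self):
        state = equilibrium_chain(1.0, np.array([1.0, 1.0]), np.array([1.0, 1.0, 1.0]))
        assert np.allclose(state.abundances, [0.5, 0.25, 0.25], atol=1e-12)

    def test_zero_second_step_reduces_to_two_isoform(self):
        state = equilibrium_chain(1.0, np.array([0.7, 0.0]), np.array([1.0, 1.0, 1.0]))
        two = equilibrium_two_isoform(1.0, 0.7, 1.0, 1.0)
        assert np.allclose(state.abundances[:2], two.abundances, atol=1e-12)
        assert state.abundances[2] == 0.0

    def test_random_chain_matches_general_solver(self, rng):
        betas = rng.uniform(0.1, 3.0, size=4)
        gammas = rng.uniform(0.5, 2.0, size=5)
        B = np.zeros((5, 5))
        for i in range(4):
            B[i, i + 1] = betas[i]
        a = equilibrium_chain(1.0, betas, gammas)
        b = equilibrium_general(1.0, B, gammas)
        assert np.allclose(a.abundances, b.abundances, atol=1e-10)


class TestMultisite:
    def test_single_site_reduces_to_two_isoform(self):
        a = equilibrium_multisite(1.0, 0.4, 1, np.array([1.0, 2.0]))
        b = equilibrium_two_isoform(1.0, 0.4, 1.0, 2.0)
        assert np.allclose(a.abundances, b.abundances, atol=1e-12)

    def test_two_sites_symmetric_rates(self):
        state = equilibrium_multisite(1.0, 1.0, 2, np.array([1.0, 1.0, 1.0]))
        assert np.allclose(state.abundances, [1 / 3, 1 / 3, 1 / 3], atol=1e-12)

    def test_zero_rate_leaves_everything_unmodified(self):
        state = equilibrium_multisite(3.0, 0.0, 3, np.array([1.5, 1.0, 1.0, 1.0]))
        assert state.abundances[0] == pytest.approx(2.0)
        assert np.all(state.abundances[1:] == 0.0)


class TestGeneral:
    def test_first_row_only_equals_branching(self, rng):
        betas = rng.uniform(0.1, 2.0, size=3)
        gammas = rng.uniform(0.5, 2.0, size=4)
        B = np.zeros((4, 4))
        B[0, 1:] = betas
        a = equilibrium_general(1.0, B, gammas)
        b = equilibrium_branching(1.0, betas, gammas)
        assert np.allclose(a.abundances, b.abundances, atol=1e-12)

    def test_random_matrix_matches_ode_oracle(self, rng):
        B = rng.uniform(0.0, 1.0, size=(4, 4))
        np.fill_diagonal(B, 0.0)
        gammas = rng.uniform(0.5, 2.0, size=4)
        state = equilibrium_general(1.3, B, gammas)
        oracle = ode_equilibrium(1.3, B, gammas)
        assert np.allclose(state.abundances, oracle, atol=1e-6)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_flux_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        B = rng.uniform(0, 2, size=(n, n))
        np.fill_diagonal(B, 0.0)
        gammas = rng.uniform(0.2, 3.0, size=n)
        alpha = float(rng.uniform(0.1, 10))
        state = equilibrium_general(alpha, B, gammas)
        assert abs(alpha - float(gammas @ state.abundances)) < 1e-10 * max(1.0, alpha)

    def test_singular_matrix_raises(self):
        # I1 has inflow but neither decay nor outgoing conversion
        B = np.array([[0.0, 1.0], [0.0, 0.0]])
        with pytest.raises(DegenerateSystemError):
            equilibrium_general(1.0, B, np.array([1.0, 0.0]))


class TestKineticSystemDispatch:
    @pytest.mark.parametrize(
        "topology,conversion,gamma,kwargs",
        [
            ("single", 0.3, (1.0, 0.5), {}),
            ("branching", (0.5, 0.7), (1.0, 1.0, 2.0), {}),
            ("chain", (0.5, 0.7), (1.0, 1.0, 2.0), {}),
            ("multisite", 0.5, (1.0, 1.0, 2.0), {"n_sites": 2}),
        ],
    )
    def test_dispatch_matches_general(self, topology, conversion, gamma, kwargs):
        sys_ = KineticSystem(alpha=1.0, conversion=conversion, gamma=gamma,
                             topology=topology, **kwargs)
        state = sys_.solve()
        n = len(gamma)
        B = np.zeros((n, n))
        if topology == "single":
            B[0, 1] = conversion
        elif topology == "branching":
            B[0, 1:] = conversion
        elif topology == "chain":
            for i, b in enumerate(conversion):
                B[i, i + 1] = b
        else:
            for i in range(kwargs["n_sites"]):
                B[i, i + 1] = (kwargs["n_sites"] - i) * conversion
        oracle = equilibrium_general(1.0, B, np.array(gamma))
        assert np.allclose(state.abundances, oracle.abundances, atol=1e-10)


class TestAltTranscription:
    def test_error_rate_zero_means_no_alternative_isoform(self):
        state = equilibrium_alt_transcription(AltTranscriptionSpec(1.0, 0.0, 1.0, 1.0))
        assert state.abundances[1] == 0.0

    def test_symmetric_split(self):
        state = equilibrium_alt_transcription(AltTranscriptionSpec(2.0, 0.5, 1.0, 1.0))
        assert np.allclose(state.abundances, [1.0, 1.0])

    def test_all_transcription_goes_to_alternative(self):
        state = equilibrium_alt_transcription(AltTranscriptionSpec(3.0, 1.0, 1.0, 2.0))
        assert np.allclose(state.abundances, [0.0, 1.5])

    def test_zero_decay_raises(self):
        with pytest.raises(DegenerateSystemError):
            equilibrium_alt_transcription(AltTranscriptionSpec(1.0, 0.5, 0.0, 1.0))


class TestModificationLevel:
    def test_editing_ratio(self):
        assert modification_level(np.array([1.0, 1.0]), "editing") == pytest.approx(0.5)

    def test_rate_ratio_identity(self):
        # f computed from abundances equals beta/(beta+gamma1)
        state = equilibrium_two_isoform(1.0, 1.0, 1.0, 1.0)
        assert modification_level(state, "editing") == pytest.approx(1.0 / (1.0 + 1.0))

    def test_splicing_from_branching_example(self):
        assert modification_level(np.array([0.01, 0.5, 0.025]), "splicing") == pytest.approx(
            0.047619, abs=1e-6
        )

    def test_zero_denominator_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning):
            assert modification_level(np.array([0.0, 0.0]), "editing") == 0.0
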