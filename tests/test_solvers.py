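"""TAP / AMP / dynamical-TAP iterations and their stability structure."""

import numpy as np
import pytest
from scipy.optimize import brentq

from hopinfer.model import CouplingMatrix, generate_teacher, hebbian_coupling
from hopinfer.solvers import (
    AMPState,
    DMFTState,
    NumericalSingularityError,
    TAPState,
    amp_init,
    amp_parallel_step,
    amp_sequential_damped,
    convergence_probability,
    dmft_init,
    dmft_step,
    iterate,
    linear_stability_threshold,
    random_init,
    tap_iterate_batch,
    tap_parallel_step,
)


def scalar_fixed_point(beta: float) -> float:
    """Independent 1-D oracle: positive root of a = tanh(beta a)."""
    return brentq(lambda a: a - np.tanh(beta * a), 1e-12, 1.0, xtol=1e-14)


@pytest.fixture
def single_pattern(rng):
    teacher = generate_teacher(300, 1, 2.0, rng)
    return teacher, teacher.coupling()


class TestParamagneticFixedPoint:
    def test_all_schemes_keep_zero(self, single_pattern):
        _, J = single_pattern
        z = np.zeros(300)
        assert np.array_equal(tap_parallel_step(TAPState.from_m(z), J, 2.0, 0.01).m, z)
        assert np.array_equal(amp_parallel_step(amp_init(z, 2.0), J, 2.0, 0.01).m, z)
        assert np.array_equal(dmft_step(dmft_init(z, 2.0, 0.01), J, 2.0, 0.01).m, z)


class TestTAP:
    def test_step_along_pattern_is_scalar_map(self, single_pattern):
        """m = a*zeta maps to tanh(beta a)*zeta when alpha -> 0."""
        teacher, J = single_pattern
        zeta = teacher.patterns[0]
        state = TAPState.from_m(0.3 * zeta)
        out = tap_parallel_step(state, J, 2.0, alpha=0.0)
        assert np.allclose(out.m, np.tanh(2.0 * 0.3) * zeta, atol=1e-12)

    def test_fixed_point_matches_scalar_oracle(self, single_pattern):
        teacher, J = single_pattern
        zeta = teacher.patterns[0]
        res = iterate("tap", J, 2.0, 0.0, 0.3 * zeta, tol=1e-10, max_iter=5000)
        a_star = scalar_fixed_point(2.0)
        assert res.converged
        assert np.allclose(res.m_final, a_star * zeta, atol=1e-6)

    def test_retrieval_from_random_init(self, single_pattern, rng):
        teacher, J = single_pattern
        res = iterate("tap", J, 2.0, 1 / 300, random_init(300, 1.0, 1.0, rng))
        q = abs(res.m_final @ teacher.patterns[0]) / 300
        # plateau overlap equals the scalar fixed point a* = tanh(2 a*)
        assert res.converged and abs(q - scalar_fixed_point(2.0)) < 0.01

    def test_paramagnet_below_threshold(self, single_pattern, rng):
        _, J = single_pattern
        res = iterate("tap", J, 0.5, 1 / 300, random_init(300, 0.5, 1.0, rng))
        assert res.converged
        assert np.max(np.abs(res.m_final)) < 0.05

    def test_onsager_singularity_raises(self, single_pattern):
        _, J = single_pattern
        m = np.full(300, np.sqrt(0.5))  # 1 - beta(1-q) = 0 at beta=2
        with pytest.raises(NumericalSingularityError):
            tap_parallel_step(TAPState.from_m(m), J, 2.0, 0.1)

    def test_batch_matches_single(self, single_pattern, rng):
        _, J = single_pattern
        inits = np.stack([random_init(300, 0.1, 1.0, rng) for _ in range(4)])
        finals, conv, iters = tap_iterate_batch(J, 2.0, 1 / 300, inits)
        for k in range(4):
            res = iterate("tap", J, 2.0, 1 / 300, inits[k])
            assert np.allclose(finals[k], res.m_final, atol=1e-12)
            assert conv[k] == res.converged and iters[k] == res.iterations

    def test_fixed_point_magnetizations_vs_enumeration(self, boltzmann_oracle):
        """N=10, beta <= 0.8: TAP magnetizations within the mean-field band
        of the exact <s_i> (both vanish in the paramagnet)."""
        teacher = generate_teacher(10, 1, 0.8, seed=2)
        J = teacher.coupling()
        states, probs = boltzmann_oracle(J.J, 0.8)
        exact = probs @ states
        res = iterate("tap", J, 0.8, 0.1, random_init(10, 0.1, 0.3, 11),
                      tol=1e-8, max_iter=5000)
        assert np.max(np.abs(res.m_final - exact)) < 0.05


class TestAMP:
    def test_bootstrap_handles_magnitude_one(self, single_pattern, rng):
        _, J = single_pattern
        st = amp_init(random_init(300, 1.0, 1.0, rng), 2.0)
        out = amp_parallel_step(st, J, 2.0, 1 / 300)
        assert np.all(np.isfinite(out.m)) and np.all(np.isfinite(out.H))

    def test_instability_is_orthogonal_to_pattern(self, single_pattern, rng):
        """beta in (1/2, 1): AMP leaves the paramagnet along bulk modes."""
        teacher, J = single_pattern
        zeta = teacher.patterns[0]
        m0 = 1e-3 * random_init(300, 0.5, 1.0, rng)
        st = amp_init(m0, 0.7)
        for _ in range(25):
            st = amp_parallel_step(st, J, 0.7, 1 / 300)
        m = st.m
        para = abs(m @ zeta) / np.sqrt((m @ m) * 300 + 1e-30)
        assert np.linalg.norm(m) > 10 * np.linalg.norm(m0)  # grew
        assert para < 0.2  # but not toward the pattern

    def test_tap_growth_is_along_pattern(self, single_pattern, rng):
        """Contrast: TAP's first-step growth at beta > 1 is along zeta."""
        teacher, J = single_pattern
        zeta = teacher.patterns[0]
        m0 = 1e-3 * random_init(300, 0.5, 1.0, rng)
        st = TAPState.from_m(m0)
        for _ in range(25):
            st = tap_parallel_step(st, J, 1.5, 1 / 300)
        para = abs(st.m @ zeta) / np.sqrt((st.m @ st.m) * 300)
        assert para > 0.9

    def test_sequential_undamped_matches_reference_sweep(self):
        """d=0 sequential update on a 2-spin toy vs a literal reimplementation."""
        J = CouplingMatrix(np.array([[0.0, 0.4], [0.4, 0.0]]))
        beta, alpha = 0.8, 0.1  # u stays away from the singular shell u = 1
        m0 = np.array([0.3, -0.5])
        res = amp_sequential_damped(J, beta, alpha, d=0.0, init=m0, tol=1e-12,
                                    max_iter=1)
        # independent literal sweep of the fixed-point equations
        m = np.clip(m0, -1 + 1e-12, 1 - 1e-12).astype(float)
        u = beta * (1 - np.mean(m ** 2))
        ons = alpha * u / (1 - u)
        for i in range(2):
            H_i = J.J[i] @ m - J.J[i, i] * m[i] - ons * m[i]
            m[i] = np.tanh(beta * H_i)
        assert np.allclose(res.m_final, m, atol=1e-12)

    def test_sequential_damped_retrieves_pattern(self, rng):
        teacher = generate_teacher(100, 1, 2.0, rng)
        res = amp_sequential_damped(teacher.coupling(), 2.0, 0.01, d=0.95,
                                    init=random_init(100, 1.0, 1.0, rng),
                                    max_iter=3000)
        q = abs(res.m_final @ teacher.patterns[0]) / 100
        # 0.7 is the pattern-retrieval criterion that excludes mixtures
        assert res.converged and q > 0.7


class TestDMFT:
    def test_alpha_zero_reduces_to_naive_mean_field(self, rng):
        """With J_ii = 0 and alpha = 0: m' = tanh(beta J m) exactly."""
        Jm = rng.normal(size=(8, 8))
        Jm = (Jm + Jm.T) / 2
        np.fill_diagonal(Jm, 0.0)
        J = CouplingMatrix(Jm)
        m0 = rng.uniform(-0.5, 0.5, 8)
        out = dmft_step(dmft_init(m0, 1.3, 0.0), J, 1.3, 0.0)
        assert np.allclose(out.m, np.tanh(1.3 * Jm @ m0), atol=1e-12)

    def test_retrieves_pattern_with_small_init(self, rng):
        teacher = generate_teacher(200, 1, 2.0, rng)
        res = iterate("dmft", teacher.coupling(), 2.0, 1 / 200,
                      random_init(200, 0.1, 0.1, rng))
        q = abs(res.m_final @ teacher.patterns[0]) / 200
        assert res.converged and q > 0.9


class TestRandomInit:
    def test_magnitude_window(self, rng):
        m = random_init(500, 0.1, 1.0, rng)
        assert np.all((np.abs(m) >= 0.1) & (np.abs(m) <= 1.0))
        assert np.array_equal(np.abs(random_init(10, 1.0, 1.0, rng)), np.ones(10))

    def test_invalid_bounds(self, rng):
        with pytest.raises(ValueError):
            random_init(10, 0.0, 1.0, rng)
        with pytest.raises(ValueError):
            random_init(10, 0.5, 1.5, rng)


class TestIterate:
    def test_exact_fixed_point_converges_immediately(self, single_pattern):
        _, J = single_pattern
        res = iterate("tap", J, 0.5, 0.0, np.zeros(300))
        assert res.converged and res.iterations == 1 and res.residual == 0.0

    def test_nonconvergence_is_flagged_not_raised(self, single_pattern, rng):
        _, J = single_pattern
        res = iterate("amp", J, 0.7, 1 / 300, random_init(300, 0.5, 0.9, rng),
                      max_iter=50)
        assert not res.converged and res.iterations == 50


class TestLinearStability:
    def test_tap_threshold_single_pattern(self, rng):
        J = generate_teacher(200, 1, 1.0, rng).coupling()
        assert abs(linear_stability_threshold(J, "tap") - 1.0) < 1e-10

    def test_amp_threshold_is_half(self, rng):
        J = generate_teacher(200, 1, 1.0, rng).coupling()
        assert abs(linear_stability_threshold(J, "amp") - 0.5) < 1e-10

    def test_tap_threshold_scales_with_lambda_max(self, rng):
        J = generate_teacher(100, 1, 1.0, rng).coupling()
        J2 = CouplingMatrix(2.0 * J.J)  # lambda_max = 2 (strong dual signal)
        assert abs(linear_stability_threshold(J2, "tap") - 0.5) < 1e-10

    def test_tap_equals_inverse_lambda_max_for_random_J(self, rng):
        A = rng.normal(size=(40, 40))
        J = CouplingMatrix((A + A.T) / 2)
        lam = np.linalg.eigvalsh(J.J)[-1]
        assert abs(linear_stability_threshold(J, "tap") - 1 / lam) < 1e-10

    def test_no_instability_sentinel(self):
        J = CouplingMatrix(-np.eye(5))
        assert linear_stability_threshold(J, "tap") == np.inf

    def test_dmft_matches_tap(self, rng):
        J = generate_teacher(100, 2, 1.0, rng).coupling()
        assert linear_stability_threshold(J, "dmft") == \
            linear_stability_threshold(J, "tap")


class TestConvergenceProbability:
    def test_deep_paramagnet_never_retrieves(self, rng):
        pc = convergence_probability("tap", 100, 1, 0.2, n_trials=10, rng=rng)
        assert pc == 0.0

    def test_retrieval_phase_always_retrieves(self, rng):
        pc = convergence_probability("tap", 200, 1, 2.0, n_trials=10, rng=rng)
        assert pc == 1.0
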