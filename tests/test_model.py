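"""Regulatory functions, drift, diffusion tensor and Jacobian."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import switchwave as sw
from switchwave.model import activation_factor

REF = sw.REFERENCE_PARAMS


def direct_p_a(m, x_b, p):
    """Independent literal transcription of the p_A formula."""
    return (1 + p.rho_a * ((1 + m / p.k_m) / (1 + p.f * m / p.k_m)) ** 2
            * (1 + x_b / p.k_b) ** 2) ** -1


def direct_p_b(x_a, p):
    return (1 + p.rho_b * (1 + x_a / p.k_a) ** 2) ** -1


class TestBindingProbs:
    def test_basal_point(self):
        # both activation and repression factors are 1 at the origin
        assert sw.binding_prob_a(0.0, 0.0, REF) == pytest.approx(1 / (1 + REF.rho_a))

    def test_saturating_signal(self):
        # activation ratio tends to 1/f, so p_A -> 1/(1 + rho_a/f^2)
        val = sw.binding_prob_a(1e9, 0.0, REF)
        assert val == pytest.approx(1 / (1 + 1 / REF.f**2), rel=1e-6)

    def test_p_b_unrepressed_and_at_k_a(self):
        assert sw.binding_prob_b(0.0, REF) == pytest.approx(1 / (1 + REF.rho_b))
        assert sw.binding_prob_b(REF.k_a, REF) == pytest.approx(1 / (1 + 4 * REF.rho_b))

    def test_direct_formula_oracle(self, ref_params):
        # B steady state at M = 0.45 found independently of binding_prob_a's code path
        ss = sw.find_steady_states(0.45, ref_params)
        x_b_st = ss.states[0][0][1]  # B-like: lowest x_A, highest x_B
        expected = direct_p_a(0.45, x_b_st, ref_params)
        assert sw.binding_prob_a(0.45, x_b_st, ref_params) == pytest.approx(expected, rel=1e-12)
        assert sw.binding_prob_b(1.0, ref_params) == pytest.approx(
            direct_p_b(1.0, ref_params), rel=1e-12)

    @pytest.mark.parametrize("fn, args", [
        (sw.binding_prob_a, (-0.1, 0.0)),
        (sw.binding_prob_a, (0.0, -0.1)),
        (sw.binding_prob_b, (-0.1,)),
    ])
    def test_domain_errors(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args, REF)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(m=st.floats(0, 50), x_b=st.floats(0, 5), dm=st.floats(1e-6, 10),
           dx=st.floats(1e-6, 5))
    def test_bounds_and_monotonicity(self, m, x_b, dm, dx):
        v = sw.binding_prob_a(m, x_b, REF)
        assert 0 < v <= 1
        assert sw.binding_prob_a(m + dm, x_b, REF) > v  # increasing in signal
        assert sw.binding_prob_a(m, x_b + dx, REF) < v  # decreasing in repressor
        assert sw.binding_prob_b(x_b + dx, REF) < sw.binding_prob_b(x_b, REF)

    def test_activation_flat_at_f_near_one(self):
        p = REF.replace(f=1.0 + 1e-12)
        assert activation_factor(3.7, p) == pytest.approx(1.0, abs=1e-9)


class TestDriftAndDiffusion:
    def test_drift_at_origin(self):
        f_a, f_b = sw.drift_field(0.0, 0.0, 0.0, REF)
        assert f_a == pytest.approx(0.5)
        assert f_b == pytest.approx(1 / (1 + REF.rho_b))

    def test_drift_vanishes_at_fixed_points(self, ref_params):
        for s, _ in sw.find_steady_states(0.5, ref_params).states:
            f_a, f_b = sw.drift_field(s[0], s[1], 0.5, ref_params)
            assert abs(f_a) < 1e-8 and abs(f_b) < 1e-8

    def test_drift_sign_above_nullcline(self, ref_params):
        # above the x_A-nullcline (x_A > p_A) the A-drift points down
        p_a = sw.binding_prob_a(0.5, 0.3, ref_params)
        f_a, _ = sw.drift_field(p_a + 0.05, 0.3, 0.5, ref_params)
        assert f_a < 0

    def test_diffusion_origin_and_burst_linearity(self):
        n1 = sw.NoiseParams(omega=100, nu_a=1)
        d_aa, _ = sw.diffusion_tensor(0.0, 0.0, 0.0, REF, n1)
        assert d_aa == pytest.approx(0.5)  # nu_A * p_A(0,0) + 0
        d_aa2, _ = sw.diffusion_tensor(0.0, 0.0, 0.0, REF, n1.replace(nu_a=2))
        assert d_aa2 == pytest.approx(2 * d_aa)

    def test_diffusion_at_steady_state(self, ref_params, noise_unit):
        # p_A = x_A at a fixed point, so D_AA = (1 + nu_A) x_A
        for s, _ in sw.find_steady_states(0.5, ref_params).states:
            d_aa, d_bb = sw.diffusion_tensor(s[0], s[1], 0.5, ref_params, noise_unit)
            assert d_aa == pytest.approx((1 + noise_unit.nu_a) * s[0], rel=1e-6)
            assert d_aa > 0 and d_bb > 0


class TestJacobian:
    def test_diagonal_structure(self):
        p = REF.replace(delta=1.7)
        j = sw.jacobian(0.3, 0.4, 0.5, p)
        assert j[0, 0] == -1.0
        assert j[1, 1] == -1.7

    def test_matches_central_differences(self, ref_params):
        rng = np.random.default_rng(42)
        h = 1e-6
        for _ in range(100):
            x_a, x_b, m = rng.uniform(0.01, 1.0, 3)
            j = sw.jacobian(x_a, x_b, m, ref_params)
            num = np.empty((2, 2))
            for col, (da, db) in enumerate([(h, 0.0), (0.0, h)]):
                fp = sw.drift_field(x_a + da, x_b + db, m, ref_params)
                fm = sw.drift_field(x_a - da, x_b - db, m, ref_params)
                num[:, col] = (np.array(fp) - np.array(fm)) / (2 * h)
            assert np.allclose(j, num, rtol=1e-5, atol=1e-8)

    def test_stable_states_have_negative_eigenvalues(self, ref_params):
        ss = sw.find_steady_states(0.5, ref_params)
        for s, label in ss.states:
            eig = np.linalg.eigvals(sw.jacobian(s[0], s[1], 0.5, ref_params))
            if label == "stable":
                assert np.all(eig.real < 0)
            else:
                assert eig.real.min() < 0 < eig.real.max()


class TestParams:
    @pytest.mark.parametrize("kw", [
        {"f": 0.5}, {"f": 1.0}, {"alpha": -1.0}, {"rho_b": 0.0}, {"k_a": -1e-3},
    ])
    def test_invalid_toggle_params(self, kw):
        with pytest.raises(ValueError):
            sw.ToggleParams(**kw)

    @pytest.mark.parametrize("kw", [{"omega": 0.0}, {"nu_a": 0.5}])
    def test_invalid_noise_params(self, kw):
        with pytest.raises(ValueError):
            sw.NoiseParams(**kw)

    def test_steady_states_depend_only_on_rate_ratio(self, ref_params):
        # jointly scaling production and degradation of B leaves Eq-roots unchanged
        base = sorted(tuple(s) for s, _ in sw.find_steady_states(0.5, ref_params).states)
        scaled_p = ref_params.replace(alpha=3.0 * ref_params.alpha,
                                      delta=3.0 * ref_params.delta)
        scaled = sorted(tuple(s) for s, _ in sw.find_steady_states(0.5, scaled_p).states)
        assert np.allclose(np.array(base), np.array(scaled), atol=1e-6)

    def test_unit_conversion_roundtrip(self):
        x = np.array([0.25, 1.5])
        assert np.allclose(sw.concentrations(sw.molecule_counts(x, 120.0), 120.0), x)
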