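"""Action functional, minimum action paths and rate fitting."""

import numpy as np
import pytest

import switchwave as sw
from switchwave.map_action import Path, discrete_action
from switchwave.stochastic import FirstPassageEnsemble

REF = sw.REFERENCE_PARAMS


class TestActionFunctional:
    def test_deterministic_trajectory_has_zero_action(self, ref_params, noise_unit):
        traj = sw.integrate_ode((0.0, 1.0), 1.5, ref_params, t_end=30.0,
                                dt_out=0.002)
        s = sw.action_of_path(Path.from_trajectory(traj), 1.5, ref_params, noise_unit)
        assert 0 <= s <= 1e-6

    def test_1d_ornstein_uhlenbeck_closed_form(self):
        # uphill path of x' = -x with constant diffusion 2*D0 costs
        # S = (a^2 - x0^2)/(2 D0); realised by the time-reversed flow x(t) = x0 e^t
        d0, x0, a = 0.35, 1e-3, 1.2
        times = np.linspace(0.0, np.log(a / x0), 4001)
        nodes = (x0 * np.exp(times))[:, None]
        s = discrete_action(nodes, times,
                            drift_fn=lambda x: -x,
                            diffusion_fn=lambda x: 2 * d0 * np.ones_like(x))
        assert s == pytest.approx((a**2 - x0**2) / (2 * d0), rel=1e-3)

    def test_omega_does_not_enter_the_action(self, ref_params, coarse_profiles):
        path = coarse_profiles[0].paths[2]
        m = coarse_profiles[0].m[2]
        s1 = sw.action_of_path(path, m, ref_params, sw.NoiseParams(omega=10))
        s2 = sw.action_of_path(path, m, ref_params, sw.NoiseParams(omega=1e6))
        assert s1 == s2

    def test_degenerate_nodes_rejected(self):
        nodes = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="degenerate|repeated"):
            discrete_action(nodes, [0.0, 1.0, 2.0], lambda x: -x,
                            lambda x: np.ones_like(x))


class TestMinimizeAction:
    def test_map_passes_through_saddle_both_directions(self, ref_params, noise_unit):
        for direction in ("BA", "AB"):
            res = sw.minimize_action(direction, 0.45, ref_params, noise_unit,
                                     n_path=301, restarts=1)
            assert res.saddle_distance < 0.05
            assert res.s > 0

    def test_discretization_refinement(self, ref_params, noise_unit):
        coarse = sw.minimize_action("BA", 0.6, ref_params, noise_unit,
                                    n_path=401, restarts=1)
        fine = sw.minimize_action("BA", 0.6, ref_params, noise_unit,
                                  n_path=801, restarts=1,
                                  init=_upsample(coarse.path.nodes, 801))
        assert abs(fine.s - coarse.s) / fine.s < 0.005

    def test_optimal_times_reproduce_geometric_action(self, ref_params, noise_unit):
        # evaluating the time-parametrized functional on the MAP with its
        # reconstructed optimal time steps must reproduce the minimized value
        res = sw.minimize_action("BA", 0.5, ref_params, noise_unit,
                                 n_path=301, restarts=1)
        s_time = sw.action_of_path(res.path, 0.5, ref_params, noise_unit)
        assert s_time == pytest.approx(res.s, rel=1e-8)

    def test_outside_bistable_zone_rejected(self, ref_params, noise_unit):
        with pytest.raises(ValueError, match="bistable"):
            sw.minimize_action("BA", 1.5, ref_params, noise_unit)

    def test_bursts_reshape_the_map(self, ref_params):
        # the A->B path responds most strongly to the A burst size here
        base = sw.minimize_action("AB", 0.45, ref_params, sw.NoiseParams(),
                                  n_path=301, restarts=1)
        bursty = sw.minimize_action("AB", 0.45, ref_params,
                                    sw.NoiseParams(nu_a=10.0), n_path=301,
                                    restarts=1)
        assert bursty.s < base.s
        # geometry changes too, not just the value
        gap = _path_separation(base.path.nodes, bursty.path.nodes)
        assert gap > 0.02


class TestProfilesAndBalance:
    def test_opposite_monotonic_trends(self, coarse_profiles):
        ba, ab = coarse_profiles
        assert np.all(np.diff(ba.s) < 0)  # B->A barrier falls with signal
        assert np.all(np.diff(ab.s) > 0)  # A->B barrier rises with signal
        assert np.all(ba.converged) and np.all(ab.converged)
        assert np.all(ba.ds_dm < 0)

    def test_bursts_lower_both_profiles(self, ref_params, coarse_profiles):
        grid = np.array([0.3, 0.45, 0.6])
        bursty = sw.NoiseParams(nu_a=10.0)
        for direction, ref_prof in zip(("BA", "AB"), coarse_profiles):
            prof = sw.action_profile(direction, ref_params, bursty, grid, n_path=301)
            ref_interp = ref_prof.interpolator()(grid)
            assert np.all(prof.s < ref_interp)

    def test_balance_point_from_precomputed_profiles(self, ref_params, noise_unit,
                                                     coarse_profiles):
        res = sw.find_balance_point(ref_params, noise_unit,
                                    profiles=coarse_profiles)
        assert 0.2 < res.m_star < 0.4

    def test_no_crossing_raises(self, ref_params, noise_unit, coarse_profiles):
        ba, ab = coarse_profiles
        upper = slice(4, None)  # S_BA < S_AB everywhere on the upper grid
        trimmed = (
            sw.ActionProfile("BA", ba.m[upper], ba.s[upper], ba.converged[upper]),
            sw.ActionProfile("AB", ab.m[upper], ab.s[upper], ab.converged[upper]),
        )
        with pytest.raises(ValueError, match="sign"):
            sw.find_balance_point(ref_params, noise_unit, profiles=trimmed)


class TestPrefactor:
    def test_synthetic_recovery(self, ref_params, noise_unit, monkeypatch):
        # feed the fitter fake ensembles T = C0 exp(Omega S0) * lognormal noise
        c0, s0 = 12.0, 0.04
        rng = np.random.default_rng(0)

        def fake_ensemble(m, p, n, **kw):
            t = c0 * np.exp(n.omega * s0) * rng.lognormal(0.0, 0.05, 200)
            return FirstPassageEnsemble(passage_times=t, n_reps=200,
                                        threshold=0.9, t_max=np.inf, method="cle")

        monkeypatch.setattr("switchwave.map_action.first_passage_ensemble",
                            fake_ensemble)
        res = sw.fit_prefactor(0.6, ref_params, noise_unit,
                               omegas=[60, 80, 100, 120], action=s0)
        assert res.c > 0
        assert abs(np.log(res.c) - np.log(c0)) < 2 * max(res.fit_stderr, 0.01)
        assert res.free_slope == pytest.approx(s0, rel=0.1)

    def test_requires_two_omegas(self, ref_params, noise_unit):
        with pytest.raises(ValueError):
            sw.fit_prefactor(0.6, ref_params, noise_unit, omegas=[100])


def _upsample(nodes, n_new):
    t = np.arange(len(nodes))
    tf = np.linspace(0, len(nodes) - 1, n_new)
    return np.stack([np.interp(tf, t, nodes[:, i]) for i in range(2)], 1)


def _path_separation(nodes_a, nodes_b):
    """Max over one path's nodes of the min max-norm distance to the other."""
    d = np.abs(nodes_a[:, None, :] - nodes_b[None, :, :]).max(-1)
    return max(d.min(1).max(), d.min(0).max())
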