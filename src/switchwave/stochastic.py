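"""Stochastic simulation of the toggle switch.

Two simulators share one underlying kinetic picture:

* ``ssa_simulate`` — exact Gillespie simulation of the four-channel
  birth-death scheme. Production of A fires at propensity
  Omega * p_A / nu_A and jumps N_A by the burst size nu_A (likewise B with
  alpha * p_B / nu_B and nu_B); degradation removes single molecules at
  propensity N_A (resp. delta * N_B). The mean field of this scheme is the
  deterministic system and its diffusion approximation is exactly the
  diagonal tensor D = diag(nu_A p_A + x_A, nu_B alpha p_B + delta x_B).

* ``cle_simulate`` — Euler-Maruyama integration of the Chemical Langevin
  Equation dx = f dt + sqrt(D dt / Omega) eta, with states clipped at zero
  after each step. Weak (ensemble) accuracy is what first-passage statistics
  need, so a fixed step (default 1e-3 in units of the A degradation time)
  is used rather than a higher-order scheme.

First-passage ensembles report the patterning time: the first time the
target-gene concentration x_A exceeds a threshold (0.9 by default) from the
prepattern state (0, 1). Replicates draw independent streams derived from
one root seed via ``numpy.random.SeedSequence`` spawning, so ensembles are
reproducible and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import NoiseParams, ToggleParams
from .deterministic import Trajectory

__all__ = [
    "FirstPassageEnsemble",
    "ssa_simulate",
    "cle_simulate",
    "first_passage_ensemble",
    "passage_trajectories",
    "spawn_seeds",
]


def spawn_seeds(seed, n):
    """Derive ``n`` independent 31-bit child seeds from one root seed."""
    ss = np.random.SeedSequence(seed)
    return np.array(
        [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)], dtype=np.int64
    )


@dataclass
class FirstPassageEnsemble:
    """Per-replicate first-passage times with censoring bookkeeping.

    Statistics (mean/SEM/CV) are computed over uncensored replicates only;
    ``censored_count`` reports runs that had not crossed by t_max.
    """

    passage_times: np.ndarray
    n_reps: int
    threshold: float
    t_max: float
    method: str
    censored_count: int = 0

    @property
    def n_passed(self) -> int:
        return len(self.passage_times)

    @property
    def mean(self) -> float:
        return float(np.mean(self.passage_times))

    @property
    def sem(self) -> float:
        n = len(self.passage_times)
        return float(np.std(self.passage_times, ddof=1) / np.sqrt(n)) if n > 1 else np.nan

    @property
    def cv(self) -> float:
        return float(np.std(self.passage_times, ddof=1) / np.mean(self.passage_times))


# ---------------------------------------------------------------------------
# numba kernels (scalar parameters only; model formulas inlined)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _cle_kernel(m, omega, nu_a, nu_b, alpha, delta, rho_a, rho_b, k_a, k_b,
                k_m, f, xa0, xb0, thr, dt, t_max, seed, rec_t, rec_out,
                stop_at_threshold):
    np.random.seed(seed)
    u = m / k_m
    act = ((1.0 + u) / (1.0 + f * u)) ** 2
    xa = xa0
    xb = xb0
    t = 0.0
    sdt = np.sqrt(dt / omega)
    fpt = -1.0
    i_rec = 0
    n_rec = rec_t.shape[0]
    while i_rec < n_rec and rec_t[i_rec] <= t:
        rec_out[i_rec, 0] = xa
        rec_out[i_rec, 1] = xb
        i_rec += 1
    n_steps = int(np.ceil(t_max / dt))
    for _ in range(n_steps):
        p_a = 1.0 / (1.0 + rho_a * act * (1.0 + xb / k_b) ** 2)
        p_b = 1.0 / (1.0 + rho_b * (1.0 + xa / k_a) ** 2)
        xa += (p_a - xa) * dt + np.sqrt(nu_a * p_a + xa) * sdt * np.random.normal()
        xb += (alpha * p_b - delta * xb) * dt + np.sqrt(
            nu_b * alpha * p_b + delta * xb) * sdt * np.random.normal()
        if xa < 0.0:
            xa = 0.0
        if xb < 0.0:
            xb = 0.0
        if not (np.isfinite(xa) and np.isfinite(xb)):
            return np.nan, i_rec
        t += dt
        while i_rec < n_rec and rec_t[i_rec] <= t:
            rec_out[i_rec, 0] = xa
            rec_out[i_rec, 1] = xb
            i_rec += 1
        if fpt < 0.0 and xa > thr:
            fpt = t
            if stop_at_threshold:
                break
    return fpt, i_rec


@njit(cache=True)
def _ssa_kernel(m, omega, nu_a, nu_b, alpha, delta, rho_a, rho_b, k_a, k_b,
                k_m, f, na0, nb0, thr, t_max, seed, rec_t, rec_out,
                stop_at_threshold, ev_t, ev_state):
    """Direct-method Gillespie. Records the held state at sample times
    ``rec_t`` and, if ``ev_t`` is non-empty, every event up to its capacity.
    Returns (first-passage time of x_A > thr, events recorded)."""
    np.random.seed(seed)
    u = m / k_m
    act = ((1.0 + u) / (1.0 + f * u)) ** 2
    na = na0
    nb = nb0
    t = 0.0
    fpt = -1.0
    i_rec = 0
    n_rec = rec_t.shape[0]
    i_ev = 0
    n_ev = ev_t.shape[0]
    thr_n = thr * omega
    while True:
        xa = na / omega
        xb = nb / omega
        p_a = 1.0 / (1.0 + rho_a * act * (1.0 + xb / k_b) ** 2)
        p_b = 1.0 / (1.0 + rho_b * (1.0 + xa / k_a) ** 2)
        a1 = omega * p_a / nu_a
        a2 = float(na)
        a3 = omega * alpha * p_b / nu_b
        a4 = delta * nb
        a_tot = a1 + a2 + a3 + a4
        tau = -np.log(np.random.random()) / a_tot
        t_next = t + tau
        while i_rec < n_rec and rec_t[i_rec] < t_next:
            if rec_t[i_rec] > t_max:
                break
            rec_out[i_rec, 0] = na
            rec_out[i_rec, 1] = nb
            i_rec += 1
        if t_next > t_max:
            break
        t = t_next
        r = np.random.random() * a_tot
        if r < a1:
            na += int(nu_a)
        elif r < a1 + a2:
            na -= 1
        elif r < a1 + a2 + a3:
            nb += int(nu_b)
        else:
            nb -= 1
        if i_ev < n_ev:
            ev_t[i_ev] = t
            ev_state[i_ev, 0] = na
            ev_state[i_ev, 1] = nb
            i_ev += 1
        if fpt < 0.0 and na > thr_n:
            fpt = t
            if stop_at_threshold:
                break
        if i_ev >= n_ev and n_ev > 0:
            break
    while i_rec < n_rec and rec_t[i_rec] <= t_max:
        rec_out[i_rec, 0] = na
        rec_out[i_rec, 1] = nb
        i_rec += 1
    return fpt, i_ev


def _kernel_params(m, p: ToggleParams, n: NoiseParams):
    return (float(m), float(n.omega), float(n.nu_a), float(n.nu_b),
            float(p.alpha), float(p.delta), float(p.rho_a), float(p.rho_b),
            float(p.k_a), float(p.k_b), float(p.k_m), float(p.f))


_EMPTY_T = np.empty(0, dtype=np.float64)
_EMPTY_X = np.empty((0, 2), dtype=np.float64)
_EMPTY_N = np.empty((0, 2), dtype=np.int64)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def cle_simulate(s0, m, p: ToggleParams, n: NoiseParams, t_max, dt=1e-3,
                 seed=0, dt_out=None) -> Trajectory:
    """One Euler-Maruyama realisation of the CLE, sampled every ``dt_out``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    if dt_out is None:
        dt_out = max(dt, t_max / 2000.0)
    rec_t = np.arange(0.0, t_max + 0.5 * dt_out, dt_out)
    rec_out = np.empty((len(rec_t), 2))
    s0 = np.asarray(s0, dtype=float)
    fpt, n_rec = _cle_kernel(*_kernel_params(m, p, n), s0[0], s0[1], np.inf,
                             float(dt), float(t_max), int(seed), rec_t,
                             rec_out, 0)
    if np.isnan(fpt):
        raise FloatingPointError(
            f"CLE state became non-finite near step {n_rec}; reduce dt")
    return Trajectory(rec_t[:n_rec], rec_out[:n_rec])


def ssa_simulate(s0, m, p: ToggleParams, n: NoiseParams, t_max, seed=0,
                 dt_out=None, record_events=False, max_events=2_000_000
                 ) -> Trajectory:
    """One exact Gillespie realisation; returns molecule-count time series.

    ``s0`` are integer molecule counts (N_A, N_B). With ``record_events``
    every reaction event is recorded (up to ``max_events``); otherwise the
    held state is sampled every ``dt_out``.
    """
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    na0, nb0 = s0
    if na0 != int(na0) or nb0 != int(nb0) or na0 < 0 or nb0 < 0:
        raise ValueError("SSA initial counts must be non-negative integers")
    if record_events:
        ev_t = np.empty(max_events)
        ev_state = np.empty((max_events, 2), dtype=np.int64)
        rec_t, rec_out = _EMPTY_T, _EMPTY_X.copy()
    else:
        if dt_out is None:
            dt_out = t_max / 2000.0
        rec_t = np.arange(0.0, t_max + 0.5 * dt_out, dt_out)
        rec_out = np.empty((len(rec_t), 2))
        ev_t, ev_state = _EMPTY_T, _EMPTY_N
    _, n_ev = _ssa_kernel(*_kernel_params(m, p, n), int(na0), int(nb0),
                          np.inf, float(t_max), int(seed), rec_t, rec_out,
                          0, ev_t, ev_state)
    if record_events:
        return Trajectory(ev_t[:n_ev], ev_state[:n_ev].astype(float))
    return Trajectory(rec_t, rec_out)


def _one_fpt(method, m, p, n, threshold, s0, t_max, dt, seed):
    if method == "cle":
        fpt, _ = _cle_kernel(*_kernel_params(m, p, n), s0[0], s0[1],
                             float(threshold), float(dt), float(t_max),
                             int(seed), _EMPTY_T, _EMPTY_X, 1)
        if np.isnan(fpt):
            raise FloatingPointError("CLE state became non-finite; reduce dt")
    elif method == "ssa":
        na0 = int(round(s0[0] * n.omega))
        nb0 = int(round(s0[1] * n.omega))
        fpt, _ = _ssa_kernel(*_kernel_params(m, p, n), na0, nb0,
                             float(threshold), float(t_max), int(seed),
                             _EMPTY_T, _EMPTY_X.copy(), 1, _EMPTY_T, _EMPTY_N)
    else:
        raise ValueError(f"unknown method {method!r}")
    return fpt


def first_passage_ensemble(m, p: ToggleParams, n: NoiseParams, threshold=0.9,
                           s0=(0.0, 1.0), n_reps=100, t_max=1e4,
                           method="cle", seed=0, dt=1e-3
                           ) -> FirstPassageEnsemble:
    """Ensemble of patterning (first-passage) times x_A > threshold.

    Raises if every replicate is censored — either t_max is too small or
    the switching regime at this (M, Omega) is effectively unreachable.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    seeds = spawn_seeds(seed, n_reps)
    times = np.array([
        _one_fpt(method, m, p, n, threshold, np.asarray(s0, float), t_max, dt, s)
        for s in seeds
    ])
    passed = times[times > 0.0]
    censored = int(n_reps - len(passed))
    if len(passed) == 0:
        raise RuntimeError(
            f"all {n_reps} replicates censored at t_max={t_max}; increase "
            "t_max or note the super-exponential switching regime")
    return FirstPassageEnsemble(passage_times=passed, n_reps=n_reps,
                                threshold=float(threshold), t_max=float(t_max),
                                method=method, censored_count=censored)


def passage_trajectories(m, p: ToggleParams, n: NoiseParams, threshold=0.9,
                         s0=(0.0, 1.0), n_reps=50, t_max=1e4, method="cle",
                         seed=0, dt=1e-3, dt_out=0.1):
    """Switching realisations recorded up to (just past) first passage.

    Returns a list of concentration Trajectories, one per replicate that
    crossed the threshold within t_max (censored replicates are dropped).
    Used to compare stochastic switching paths with the minimum action path.
    """
    seeds = spawn_seeds(seed, n_reps)
    s0 = np.asarray(s0, dtype=float)
    out = []
    for sd in seeds:
        rec_t = np.arange(0.0, t_max + 0.5 * dt_out, dt_out)
        rec_out = np.empty((len(rec_t), 2))
        if method == "cle":
            fpt, n_rec = _cle_kernel(*_kernel_params(m, p, n), s0[0], s0[1],
                                     float(threshold), float(dt),
                                     float(t_max), int(sd), rec_t, rec_out, 1)
        elif method == "ssa":
            na0 = int(round(s0[0] * n.omega))
            nb0 = int(round(s0[1] * n.omega))
            fpt, _ = _ssa_kernel(*_kernel_params(m, p, n), na0, nb0,
                                 float(threshold), float(t_max), int(sd),
                                 rec_t, rec_out, 1, _EMPTY_T, _EMPTY_N)
            n_rec = np.searchsorted(rec_t, fpt if fpt > 0 else t_max, "right")
            rec_out = rec_out / n.omega
        else:
            raise ValueError(f"unknown method {method!r}")
        if fpt > 0 and n_rec > 1:
            out.append(Trajectory(rec_t[:n_rec], rec_out[:n_rec]))
    return out
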