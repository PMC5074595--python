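"""Freidlin-Wentzell minimum action paths and switching rates.

In the small-noise (large Omega) limit the probability of a fluctuation
path phi of duration tau is exponentially suppressed, P ~ exp(-Omega * S),
with the action

    S(phi) = 1/2 * integral_0^tau  (phidot - f)^T D^-1 (phidot - f) dt,

where f is the deterministic drift and D the diagonal diffusion tensor.
The mean switching (residence) time then obeys T = C * exp(Omega * S*)
with S* the action minimized over paths joining the two attractors and
over the duration tau. S* is independent of Omega but depends on the burst
sizes through D.

Minimization over the duration is performed analytically: writing the
discretized action per segment with increment dx, drift f and tensor D at
the segment midpoint,

    1/2 * [ (dx^T D^-1 dx)/dt - 2 dx^T D^-1 f + dt f^T D^-1 f ],

the optimal dt = sqrt((dx^T D^-1 dx) / (f^T D^-1 f)) turns the sum into the
"geometric" action  sum_k ( |dx|_D |f|_D - <dx, f>_D )  over node positions
only, which is minimized by L-BFGS-B with an analytic gradient. Nodes are
periodically redistributed to equal arclength in the D^-1 metric: the MAP
of this switch has a boundary layer near the B attractor on the K_A scale,
and the D-metric (small diffusion there) concentrates nodes exactly where
resolution is needed.

The two action profiles S_BA(M) (falling) and S_AB(M) (rising) cross at the
stochastic steady-state boundary M*, the signal level where the residence
times of the two states balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq, minimize

from .deterministic import Trajectory, find_steady_states
from .model import NoiseParams, ToggleParams, activation_factor
from .stochastic import first_passage_ensemble

__all__ = [
    "Path",
    "ActionResult",
    "ActionProfile",
    "RatePrefactor",
    "BalanceResult",
    "discrete_action",
    "action_of_path",
    "minimize_action",
    "action_profile",
    "find_balance_point",
    "fit_prefactor",
]


@dataclass
class Path:
    """Discretized transition path: ordered nodes plus per-node times."""

    nodes: np.ndarray  # (n, 2)
    times: np.ndarray | None = None  # (n,), strictly increasing if given

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2:
            raise ValueError("nodes must have shape (n, 2)")
        if len(self.nodes) < 3:
            raise ValueError("a path needs at least 3 nodes")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != len(self.nodes):
                raise ValueError("times and nodes length mismatch")

    @property
    def duration(self) -> float | None:
        return None if self.times is None else float(self.times[-1] - self.times[0])

    @classmethod
    def from_trajectory(cls, traj: Trajectory) -> "Path":
        return cls(nodes=traj.states.copy(), times=traj.t.copy())


@dataclass
class ActionResult:
    """Minimized action with its minimizer (the MAP) and diagnostics."""

    s: float
    path: Path
    direction: str  # "BA" or "AB"
    m: float
    converged: bool
    n_iterations: int
    saddle_distance: float  # max-norm distance of closest node to the saddle
    anchors: tuple = ()


@dataclass
class ActionProfile:
    """Action along the signal axis for one transition direction."""

    direction: str
    m: np.ndarray
    s: np.ndarray
    converged: np.ndarray
    paths: list = field(default_factory=list)

    @property
    def ds_dm(self) -> np.ndarray:
        """dS/dM by central differences on the grid."""
        return np.gradient(self.s, self.m)

    def interpolator(self) -> PchipInterpolator:
        return PchipInterpolator(self.m, self.s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "M": self.m, "S": self.s, "dS_dM": self.ds_dm,
            "converged": self.converged,
        })


@dataclass
class BalanceResult:
    """Stochastic steady-state boundary: M* where S_BA = S_AB."""

    m_star: float
    profile_ba: ActionProfile
    profile_ab: ActionProfile


@dataclass
class RatePrefactor:
    """Exponential prefactor C of T = C exp(Omega S), fitted from CLE MFPTs."""

    c: float
    fit_stderr: float  # standard error of ln C
    omegas_used: np.ndarray
    s_used: float
    free_slope: float  # unconstrained regression slope (consistency check)
    log_mfpt: np.ndarray

    def __post_init__(self):
        assert self.c > 0


# ---------------------------------------------------------------------------
# action evaluation
# ---------------------------------------------------------------------------


def discrete_action(nodes, times, drift_fn, diffusion_fn):
    """Midpoint-discretized Freidlin-Wentzell action for a generic system.

    ``drift_fn(x)`` and ``diffusion_fn(x)`` map (k, d) points to (k, d)
    drift vectors and (k, d) diagonal diffusion entries. Exposed separately
    from the toggle-switch wrapper so it can be validated against systems
    with closed-form actions.
    """
    nodes = np.asarray(nodes, dtype=float)
    times = np.asarray(times, dtype=float)
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    dx = np.diff(nodes, axis=0)
    if np.any(np.all(dx == 0.0, axis=1)):
        raise ValueError("path has repeated (degenerate) nodes")
    mid = 0.5 * (nodes[:-1] + nodes[1:])
    f = np.asarray(drift_fn(mid))
    d = np.asarray(diffusion_fn(mid))
    v = dx / dt[:, None]
    dev = v - f
    return float(0.5 * np.sum(dt[:, None] * dev * dev / d))


def _model_field_fns(m, p: ToggleParams, n: NoiseParams):
    act = float(activation_factor(m, p))

    def drift_fn(x):
        p_a = 1.0 / (1.0 + p.rho_a * act * (1.0 + x[:, 1] / p.k_b) ** 2)
        p_b = 1.0 / (1.0 + p.rho_b * (1.0 + x[:, 0] / p.k_a) ** 2)
        return np.stack([p_a - x[:, 0], p.alpha * p_b - p.delta * x[:, 1]], axis=1)

    def diffusion_fn(x):
        p_a = 1.0 / (1.0 + p.rho_a * act * (1.0 + x[:, 1] / p.k_b) ** 2)
        p_b = 1.0 / (1.0 + p.rho_b * (1.0 + x[:, 0] / p.k_a) ** 2)
        return np.stack([n.nu_a * p_a + x[:, 0],
                         n.nu_b * p.alpha * p_b + p.delta * x[:, 1]], axis=1)

    return drift_fn, diffusion_fn


def action_of_path(path: Path, m, p: ToggleParams, n: NoiseParams) -> float:
    """Action of an explicitly time-parametrized path under the switch model.

    Requires ``path.times``; the system size Omega does not enter (it only
    scales switching times, not the action).
    """
    if path.times is None:
        raise ValueError("action_of_path needs a time-parametrized path")
    drift_fn, diffusion_fn = _model_field_fns(m, p, n)
    return discrete_action(path.nodes, path.times, drift_fn, diffusion_fn)


# ---------------------------------------------------------------------------
# geometric minimization
# ---------------------------------------------------------------------------


def _fields_and_derivs(x, m, p: ToggleParams, n: NoiseParams):
    """Drift F, diffusion D, Jacobian J and dD/dx at points x (k, 2)."""
    xa, xb = x[:, 0], x[:, 1]
    act = float(activation_factor(m, p))
    p_a = 1.0 / (1.0 + p.rho_a * act * (1.0 + xb / p.k_b) ** 2)
    p_b = 1.0 / (1.0 + p.rho_b * (1.0 + xa / p.k_a) ** 2)
    dpa_dxb = -(p_a**2) * p.rho_a * act * 2.0 * (1.0 + xb / p.k_b) / p.k_b
    dpb_dxa = -(p_b**2) * p.rho_b * 2.0 * (1.0 + xa / p.k_a) / p.k_a
    f = np.stack([p_a - xa, p.alpha * p_b - p.delta * xb], 1)
    d = np.stack([n.nu_a * p_a + xa, n.nu_b * p.alpha * p_b + p.delta * xb], 1)
    k = len(xa)
    jac = np.empty((k, 2, 2))
    jac[:, 0, 0] = -1.0
    jac[:, 0, 1] = dpa_dxb
    jac[:, 1, 0] = p.alpha * dpb_dxa
    jac[:, 1, 1] = -p.delta
    dd = np.empty((k, 2, 2))  # dd[:, i, j] = dD_i/dx_j
    dd[:, 0, 0] = 1.0
    dd[:, 0, 1] = n.nu_a * dpa_dxb
    dd[:, 1, 0] = n.nu_b * p.alpha * dpb_dxa
    dd[:, 1, 1] = p.delta
    return f, d, jac, dd


def _geom_action_grad(nodes, m, p, n):
    """Geometric action sum_k (|dx|_D |f|_D - <dx, f>_D) and its gradient
    with respect to all node coordinates (midpoint rule)."""
    dx = np.diff(nodes, axis=0)
    mid = 0.5 * (nodes[:-1] + nodes[1:])
    f, d, jac, dd = _fields_and_derivs(mid, m, p, n)
    inv_d = 1.0 / d
    a = np.sum(dx * dx * inv_d, 1)
    b = np.sum(f * f * inv_d, 1)
    c = np.sum(dx * f * inv_d, 1)
    sab = np.sqrt(np.maximum(a * b, 1e-300))
    s = float(np.sum(sab - c))
    dxw = dx * inv_d
    fw = f * inv_d
    dl_ddx = (b[:, None] * dxw) / sab[:, None] - fw
    da_dm = -np.einsum("ki,ki,kij->kj", dxw, dxw, dd)
    db_dm = np.einsum("ki,kij->kj", 2.0 * fw, jac) - np.einsum(
        "ki,ki,kij->kj", fw, fw, dd)
    dc_dm = np.einsum("ki,kij->kj", dxw, jac) - np.einsum(
        "ki,ki,kij->kj", dxw, fw, dd)
    dl_dm = (b[:, None] * da_dm + a[:, None] * db_dm) / (2.0 * sab[:, None]) - dc_dm
    grad = np.zeros_like(nodes)
    grad[:-1] += -dl_ddx + 0.5 * dl_dm
    grad[1:] += dl_ddx + 0.5 * dl_dm
    return s, grad


def _redistribute(nodes, m, p, n):
    """Interpolate nodes to equal arclength in the D^-1 metric."""
    mid = 0.5 * (nodes[:-1] + nodes[1:])
    _, d, _, _ = _fields_and_derivs(mid, m, p, n)
    dx = np.diff(nodes, axis=0)
    seg = np.sqrt(np.sum(dx * dx / d, axis=1))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    u = np.linspace(0.0, s[-1], len(nodes))
    out = np.stack([np.interp(u, s, nodes[:, i]) for i in range(2)], 1)
    out[0], out[-1] = nodes[0], nodes[-1]
    return out


def _optimal_times(nodes, m, p, n):
    """Per-segment optimal time steps dt* = |dx|_D / |f|_D and node times."""
    dx = np.diff(nodes, axis=0)
    mid = 0.5 * (nodes[:-1] + nodes[1:])
    f, d, _, _ = _fields_and_derivs(mid, m, p, n)
    a = np.sum(dx * dx / d, 1)
    b = np.sum(f * f / d, 1)
    dt = np.sqrt(a / np.maximum(b, 1e-300))
    return np.concatenate([[0.0], np.cumsum(dt)])


def _default_inits(x0, x1, saddle, n_path):
    """Candidate starting paths: bowed toward the saddle, straight,
    and an elbow through the saddle."""
    t = np.linspace(0.0, 1.0, n_path)[:, None]
    straight = (1.0 - t) * x0 + t * x1
    bow = straight + np.sin(np.pi * t) * (saddle - 0.5 * (x0 + x1))
    half = n_path // 2
    t1 = np.linspace(0.0, 1.0, half + 1)[:, None]
    t2 = np.linspace(0.0, 1.0, n_path - half)[:, None]
    elbow = np.vstack([
        ((1.0 - t1) * x0 + t1 * saddle)[:-1],
        (1.0 - t2) * saddle + t2 * x1,
    ])
    return [np.maximum(bow, 0.0), np.maximum(straight, 0.0),
            np.maximum(elbow, 0.0)]


def minimize_action(direction, m, p: ToggleParams, n: NoiseParams,
                    n_path=401, init=None, restarts=3, max_outer=12,
                    s_rel_tol=1e-3, gtol=1e-9, maxiter=400) -> ActionResult:
    """Minimize the action between the two stable states at signal ``m``.

    ``direction`` is "BA" (escape from the B-like, prepattern state to the
    A-like state) or "AB". Endpoints are anchored at the stable fixed
    points; the minimizer alternates bound-constrained L-BFGS-B sweeps over
    interior node coordinates with D-metric node redistribution until the
    per-sweep action values plateau (relative change < ``s_rel_tol``; the sweep-to-sweep
    noise floor is a few 1e-4 relative).
    Redistribution is not cosmetic: without it the discrete geometric
    action is unbounded below its continuum value (nodes collapse into the
    boundary layer and exploit the signed midpoint-rule error), so the
    plateau tolerance is bounded below by the redistribution interpolation
    noise, ~1e-3 relative per sweep at the default resolution. With
    ``init`` given (warm start), a single restart from it is used;
    otherwise the best of ``restarts`` standard initializations is
    returned.
    """
    if direction not in ("BA", "AB"):
        raise ValueError("direction must be 'BA' or 'AB'")
    ss = find_steady_states(m, p)
    if ss.n_states != 3:
        raise ValueError(
            f"M={m} is outside the bistable zone ({ss.n_states} fixed points); "
            "both anchor states must exist")
    b_state, saddle, a_state = [s for s, _ in ss.states]
    x0, x1 = (b_state, a_state) if direction == "BA" else (a_state, b_state)

    if init is not None:
        init = np.asarray(init, dtype=float)
        guesses = [np.vstack([x0, init[1:-1], x1])]
    else:
        guesses = _default_inits(x0, x1, saddle, n_path)[:max(1, restarts)]

    def objective(z):
        full = np.vstack([x0, z.reshape(-1, 2), x1])
        s, g = _geom_action_grad(full, m, p, n)
        return s, g[1:-1].ravel()

    best = None
    for nodes in guesses:
        nodes = _redistribute(np.maximum(nodes, 0.0), m, p, n)
        s_prev = np.inf
        s_val = np.inf
        converged = False
        n_outer = 0
        for n_outer in range(1, max_outer + 1):
            z0 = nodes[1:-1].ravel()
            res = minimize(objective, z0, jac=True, method="L-BFGS-B",
                           bounds=[(0.0, None)] * len(z0),
                           options=dict(maxiter=maxiter, ftol=1e-14, gtol=gtol))
            opt_nodes = np.vstack([x0, res.x.reshape(-1, 2), x1])
            s_val = float(res.fun)
            if abs(s_prev - s_val) < s_rel_tol * max(abs(s_val), 1e-12):
                nodes = opt_nodes
                converged = True
                break
            s_prev = s_val
            nodes = _redistribute(opt_nodes, m, p, n)
        if best is None or s_val < best[0]:
            best = (s_val, nodes, converged, n_outer)

    s_val, nodes, converged, n_outer = best
    times = _optimal_times(nodes, m, p, n)
    sdist = float(np.min(np.max(np.abs(nodes - saddle), axis=1)))
    return ActionResult(s=s_val, path=Path(nodes=nodes, times=times),
                        direction=direction, m=float(m), converged=converged,
                        n_iterations=n_outer, saddle_distance=sdist,
                        anchors=(x0.copy(), x1.copy()))


def action_profile(direction, p: ToggleParams, n: NoiseParams, m_grid,
                   n_path=401, **kwargs) -> ActionProfile:
    """Action along an M grid with continuation (warm-started) minimization.

    The grid is traversed from the end where the barrier is smallest (the
    MAP is shortest and easiest to converge) and each solution seeds its
    neighbour.
    """
    m_grid = np.asarray(m_grid, dtype=float)
    order = np.argsort(m_grid)
    if direction == "BA":  # S_BA shrinks toward M_A: start from the top
        order = order[::-1]
    s_vals = np.empty(len(m_grid))
    conv = np.zeros(len(m_grid), dtype=bool)
    paths: list = [None] * len(m_grid)
    prev_nodes = None
    for i in order:
        res = minimize_action(direction, m_grid[i], p, n, n_path=n_path,
                              init=prev_nodes, **kwargs)
        s_vals[i] = res.s
        conv[i] = res.converged
        paths[i] = res.path
        prev_nodes = res.path.nodes
    return ActionProfile(direction=direction, m=m_grid, s=s_vals,
                         converged=conv, paths=paths)


_DEFAULT_BALANCE_GRID = np.round(np.arange(0.15, 0.551, 0.025), 4)


def find_balance_point(p: ToggleParams, n: NoiseParams, m_grid=None,
                       n_path=401, profiles=None) -> BalanceResult:
    """Signal level M* where the two switching actions are equal.

    This is the stochastic steady-state boundary: for M > M* the B -> A
    transition is faster (state A dominates), below it the reverse. M* does
    not depend on Omega (the action has no Omega) and is only weakly
    affected by burst sizes.
    """
    if m_grid is None:
        m_grid = _DEFAULT_BALANCE_GRID
    if profiles is None:
        prof_ba = action_profile("BA", p, n, m_grid, n_path=n_path)
        prof_ab = action_profile("AB", p, n, m_grid, n_path=n_path)
    else:
        prof_ba, prof_ab = profiles
    diff = prof_ba.s - prof_ab.s
    sign = np.sign(diff)
    crossings = np.where(sign[:-1] * sign[1:] < 0)[0]
    if len(crossings) == 0:
        raise ValueError(
            "S_BA - S_AB does not change sign on the grid; widen m_grid")
    interp = PchipInterpolator(prof_ba.m, diff)
    i = crossings[0]
    m_star = brentq(interp, prof_ba.m[i], prof_ba.m[i + 1], xtol=1e-8)
    return BalanceResult(m_star=float(m_star), profile_ba=prof_ba,
                         profile_ab=prof_ab)


def fit_prefactor(m, p: ToggleParams, n: NoiseParams, omegas, n_reps=200,
                  seed=0, t_max=1e5, dt=1e-3, threshold=0.9, s0=(0.0, 1.0),
                  action: float | None = None) -> RatePrefactor:
    """Fit the prefactor C of T = C exp(Omega S) from CLE first passages.

    Regresses ln(mean MFPT) on Omega with the slope *fixed* to the
    minimized action S (computed here if not supplied); the intercept gives
    ln C and its standard error comes from the scatter of the per-Omega
    intercept estimates. The unconstrained slope is also reported as a
    large-deviation consistency check.
    """
    omegas = np.asarray(omegas, dtype=float)
    if len(omegas) < 2:
        raise ValueError("need at least two Omega values")
    if action is None:
        action = minimize_action("BA", m, p, n).s
    log_t = np.empty(len(omegas))
    for i, om in enumerate(omegas):
        ens = first_passage_ensemble(
            m, p, n.replace(omega=float(om)), threshold=threshold, s0=s0,
            n_reps=n_reps, t_max=t_max, method="cle",
            seed=int(np.random.SeedSequence([int(seed), i]).generate_state(1)[0] % 2**31),
            dt=dt)
        if ens.censored_count > ens.n_reps // 2:
            raise RuntimeError(
                f"Omega={om}: {ens.censored_count}/{ens.n_reps} replicates "
                "censored; increase t_max")
        log_t[i] = np.log(ens.mean)
    intercepts = log_t - omegas * action
    ln_c = float(np.mean(intercepts))
    stderr = float(np.std(intercepts, ddof=1) / np.sqrt(len(intercepts)))
    free_slope = float(np.polyfit(omegas, log_t, 1)[0])
    return RatePrefactor(c=float(np.exp(ln_c)), fit_stderr=stderr,
                         omegas_used=omegas, s_used=float(action),
                         free_slope=free_slope, log_mfpt=log_t)
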