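"""Deterministic analysis: ODE integration, steady states, fold continuation,
and the deterministic patterning time.

The toggle switch has either one or three fixed points over the signal range
of interest. In the bistable window M_B < M < M_A there are two stable states
(B-like: x_A low / x_B high; A-like: x_A high / x_B low) separated by a
saddle. The folds M_A (loss of the B state) and M_B (loss of the A state)
are saddle-node bifurcations located by bisection on the fixed-point count.

The patterning time T(M) is the first time x_A exceeds a threshold starting
from the prepattern state (x_A, x_B) = (0, 1); deterministically this is
finite only in the upper monostable zone M > M_A, and diverges as M
approaches M_A from above (the "dynamical ghost" of the vanished fold).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import (
    NoiseParams,
    ToggleParams,
    binding_prob_a,
    binding_prob_b,
    jacobian,
    _binding_prob_derivs,
)

__all__ = [
    "Trajectory",
    "SteadyStateSet",
    "BifurcationResult",
    "integrate_ode",
    "find_steady_states",
    "continuation_scan",
    "patterning_time_det",
    "STABLE",
    "SADDLE",
]

STABLE = "stable"
SADDLE = "saddle"


@dataclass
class Trajectory:
    """Time series of (x_A, x_B); ``states`` has shape (len(t), 2).

    For molecule-count (SSA) trajectories the same container holds counts;
    use :func:`switchwave.model.concentrations` to rescale.
    """

    t: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[1] != 2:
            raise ValueError("states must have shape (n, 2)")
        if len(self.t) != len(self.states):
            raise ValueError("t and states length mismatch")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def x_a(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def x_b(self) -> np.ndarray:
        return self.states[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "x_A": self.x_a, "x_B": self.x_b})


@dataclass
class SteadyStateSet:
    """Fixed points at one signal level, each labelled stable/saddle."""

    m: float
    states: list = field(default_factory=list)  # [(np.ndarray(2), label), ...]

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def stable(self) -> list:
        return [s for s, lab in self.states if lab == STABLE]

    @property
    def saddle(self):
        for s, lab in self.states:
            if lab == SADDLE:
                return s
        return None

    def sorted_by_xa(self) -> "SteadyStateSet":
        order = np.argsort([s[0] for s, _ in self.states])
        return SteadyStateSet(self.m, [self.states[i] for i in order])


@dataclass
class BifurcationResult:
    """Fold locations and the sampled steady-state branches."""

    m_a: float  # upper fold: B-like state and saddle annihilate
    m_b: float  # lower fold: A-like state and saddle annihilate
    branches: pd.DataFrame  # columns M, x_A, x_B, stability

    @property
    def bistable_range(self):
        return (self.m_b, self.m_a)


def _rhs(t, y, m, p):
    return [
        binding_prob_a(m, y[1], p) - y[0],
        p.alpha * binding_prob_b(y[0], p) - p.delta * y[1],
    ]


def integrate_ode(s0, m, p: ToggleParams, t_end, dt_out=None,
                  rtol=1e-8, atol=1e-10) -> Trajectory:
    """Integrate the deterministic dynamics with adaptive error control.

    Samples the dense solution every ``dt_out`` (default t_end/500).
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    s0 = np.asarray(s0, dtype=float)
    if dt_out is None:
        dt_out = t_end / 500.0
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    t_eval[-1] = min(t_eval[-1], t_end)
    sol = solve_ivp(_rhs, (0.0, t_end), s0, args=(m, p), method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"ODE solver failed at t={sol.t[-1] if len(sol.t) else 0.0}: {sol.message}")
    return Trajectory(sol.t, sol.y.T)


def _newton_multistart(m, p: ToggleParams, grid_n=50, n_iter=60, tol=1e-12,
                       dedup=1e-6):
    """Vectorized damped Newton from a grid_n x grid_n grid of starts.

    The fixed-point box is x_A in [0,1], x_B in [0, alpha/delta] since
    p_i <= 1. Converged roots are deduplicated in max-norm.
    """
    xb_max = p.alpha / p.delta
    xa = np.linspace(0.0, 1.0, grid_n)
    xb = np.linspace(0.0, xb_max, grid_n)
    xa, xb = [a.ravel() for a in np.meshgrid(xa, xb)]
    for _ in range(n_iter):
        p_a, p_b, dpa, dpb = _binding_prob_derivs(xa, xb, m, p)
        fa = p_a - xa
        fb = p.alpha * p_b - p.delta * xb
        # solve J dx = -f with J = [[-1, dpa], [alpha*dpb, -delta]]
        det = p.delta - p.alpha * dpa * dpb
        dxa = (p.delta * fa + dpa * fb) / det
        dxb = (p.alpha * dpb * fa + fb) / det
        step = np.maximum(np.abs(dxa), np.abs(dxb))
        damp = np.minimum(1.0, 0.2 / np.maximum(step, 1e-30))
        xa = np.clip(xa + damp * dxa, 0.0, 1.0)
        xb = np.clip(xb + damp * dxb, 0.0, xb_max)
    p_a, p_b, _, _ = _binding_prob_derivs(xa, xb, m, p)
    res = np.maximum(np.abs(p_a - xa), np.abs(p.alpha * p_b - p.delta * xb))
    ok = res < 1e-9
    roots = []
    for x, y in zip(xa[ok], xb[ok]):
        if not any(max(abs(x - rx), abs(y - ry)) < dedup for rx, ry in roots):
            roots.append((x, y))
    return sorted(roots)


def find_steady_states(m, p: ToggleParams, grid_n=50) -> SteadyStateSet:
    """Locate and classify all fixed points at signal level ``m``.

    Multi-start Newton iteration over the bounding box, deduplicated, each
    root labelled stable (both Jacobian eigenvalues negative real part) or
    saddle (real eigenvalues of opposite sign).
    """
    if m < 0:
        raise ValueError("M must be non-negative")
    roots = _newton_multistart(m, p, grid_n=grid_n)
    if not roots:
        raise RuntimeError(f"no steady states found at M={m}; this signals a bug")
    out = SteadyStateSet(float(m))
    for x, y in roots:
        eig = np.linalg.eigvals(jacobian(x, y, m, p))
        label = STABLE if np.all(eig.real < 0) else SADDLE
        out.states.append((np.array([x, y]), label))
    return out.sorted_by_xa()


def _n_states(m, p, grid_n):
    return find_steady_states(m, p, grid_n=grid_n).n_states


def continuation_scan(p: ToggleParams, m_range=(0.0, 2.0), n_points=101,
                      fold_tol=1e-4, grid_n=50) -> BifurcationResult:
    """Scan the signal range, record branches, and refine the two folds.

    Folds are located by bisection on the change in the number of fixed
    points (3 inside the bistable window, 1 outside) to absolute tolerance
    ``fold_tol`` in M.
    """
    m_lo, m_hi = m_range
    ms = np.linspace(m_lo, m_hi, n_points)
    counts = []
    rows = []
    for m in ms:
        ss = find_steady_states(m, p, grid_n=grid_n)
        counts.append(ss.n_states)
        for s, lab in ss.states:
            rows.append((m, s[0], s[1], lab))
    counts = np.asarray(counts)
    branches = pd.DataFrame(rows, columns=["M", "x_A", "x_B", "stability"])
    if not np.any(counts == 3):
        raise ValueError(
            "no bistable window detected in m_range; widen the scan range")
    idx3 = np.where(counts == 3)[0]
    if idx3[0] == 0 or idx3[-1] == n_points - 1:
        raise ValueError(
            "bistable window touches the edge of m_range; widen the scan range")

    def bisect(lo, hi, lo_count):
        while hi - lo > fold_tol:
            mid = 0.5 * (lo + hi)
            if _n_states(mid, p, grid_n) == lo_count:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    m_b = bisect(ms[idx3[0] - 1], ms[idx3[0]], 1)
    m_a = bisect(ms[idx3[-1]], ms[idx3[-1] + 1], 3)
    return BifurcationResult(m_a=m_a, m_b=m_b, branches=branches)


def patterning_time_det(m, p: ToggleParams, threshold=0.9, s0=(0.0, 1.0),
                        t_max=1e5, rtol=1e-10, atol=1e-12,
                        allow_unreachable=False) -> float:
    """Deterministic patterning time: first t with x_A(t) > threshold.

    Defined for the monostable zone M > M_A, where the only attractor is
    A-like; located by event detection. For M inside or below the bistable
    window the state is deterministically unreachable from the prepattern
    initial condition: raises, or returns +inf if ``allow_unreachable``.
    """
    s0 = np.asarray(s0, dtype=float)
    if s0[0] > threshold:
        return 0.0
    ss = find_steady_states(m, p)
    reachable = ss.n_states == 1 and ss.states[0][0][0] > threshold
    if not reachable:
        if allow_unreachable:
            return np.inf
        raise ValueError(
            f"x_A > {threshold} is deterministically unreachable at M={m} "
            "(inside or below the bistable window)")

    def event(t, y, *_):
        return y[0] - threshold

    event.terminal = True
    event.direction = 1
    sol = solve_ivp(_rhs, (0.0, t_max), s0, args=(m, p), method="LSODA",
                    events=event, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    if len(sol.t_events[0]) == 0:
        raise RuntimeError(
            f"threshold not crossed by t_max={t_max} despite reachable attractor")
    return float(sol.t_events[0][0])
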