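"""Travelling gene-expression boundary along the morphogen axis.

Because the stochastic switching time T_B(M) = C exp(Omega S_BA(M)) varies
super-exponentially along the signal gradient, at any time t the tissue
splits into a switched region (T_B << t) and an unswitched one (T_B >> t).
The boundary sits at the signal level M_s(t) where the elapsed time equals
the local switching time,

    S_BA(M_s) = (1/Omega) * ln(t / C),

and advances toward lower M with velocity

    v(t) = dM_s/dt ~= [Omega * t * dS_BA/dM|_{M_s}]^-1,

negative in M-coordinates (away from the source), vanishing in the
deterministic limit Omega -> infinity and decelerating both through 1/t
and through the steepening of the action profile.

``tissue_simulate`` runs an independent CLE realisation per cell of a
rows x columns sheet (no cell-cell coupling; each column maps to one
signal level) and ``boundary_stats`` extracts the simulated boundary
position (column-mean x_A = 0.5) and width (span of elevated column
standard deviation) for comparison with the large-deviation prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .map_action import ActionProfile
from .model import NoiseParams, ToggleParams
from .stochastic import _cle_kernel, _kernel_params, spawn_seeds

__all__ = [
    "WavefrontResult",
    "TissueSnapshot",
    "boundary_position",
    "boundary_velocity",
    "wavefront_theory",
    "default_m_of_column",
    "tissue_simulate",
    "boundary_stats",
]


@dataclass
class WavefrontResult:
    """Predicted boundary signal level and velocity at the given times."""

    times: np.ndarray
    m_s: np.ndarray
    v: np.ndarray  # dM_s/dt, negative = advancing away from the source


@dataclass
class TissueSnapshot:
    """State of a rows x cols cell sheet at one time.

    ``grid`` has shape (rows, cols, 2) holding (x_A, x_B) per cell;
    ``m_values`` maps each column to its signal level.
    """

    t: float
    grid: np.ndarray
    m_values: np.ndarray

    @property
    def column_mean_xa(self) -> np.ndarray:
        return self.grid[:, :, 0].mean(axis=0)

    @property
    def column_std_xa(self) -> np.ndarray:
        return self.grid[:, :, 0].std(axis=0)


def _check_profile(profile: ActionProfile):
    if profile.direction != "BA":
        raise ValueError("boundary prediction needs the B->A action profile")
    if not np.all(np.diff(profile.s[np.argsort(profile.m)]) < 0):
        raise ValueError("S_BA(M) must be monotone decreasing on the grid")


def boundary_position(t, omega, profile: ActionProfile, c, m_upper=None) -> float:
    """Invert S_BA(M_s) = ln(t/C)/Omega for the boundary signal level.

    For ln(t/C) <= 0 the boundary has not yet entered the bistable zone and
    ``m_upper`` (default: the top of the profile grid, normally ~M_A) is
    returned. If the required action exceeds the profile maximum the
    boundary lies below the grid and an error flags it.
    """
    _check_profile(profile)
    if t <= 0:
        raise ValueError("t must be positive")
    rhs = np.log(t / c) / omega
    m_sorted = np.sort(profile.m)
    if m_upper is None:
        m_upper = float(m_sorted[-1])
    if rhs <= float(profile.interpolator()(m_sorted[-1])):
        return m_upper
    if rhs > float(profile.interpolator()(m_sorted[0])):
        raise ValueError(
            f"required action {rhs:.4g} exceeds the profile maximum; the "
            "boundary lies below the M grid — extend the profile")
    interp = profile.interpolator()
    return float(brentq(lambda mm: interp(mm) - rhs, m_sorted[0], m_sorted[-1],
                        xtol=1e-10))


def boundary_velocity(t, omega, profile: ActionProfile, c, m_upper=None,
                      dlnc_dm=None) -> float:
    """Boundary velocity dM_s/dt at time t (negative: moving to lower M).

    Large-Omega form 1/(Omega t dS/dM); if the local log-prefactor slope
    ``dlnc_dm`` is supplied the full form 1/(t (dlnC/dM + Omega dS/dM)) is
    used instead.
    """
    m_s = boundary_position(t, omega, profile, c, m_upper=m_upper)
    order = np.argsort(profile.m)
    slope = float(PchipInterpolator(profile.m[order], profile.ds_dm[order])(m_s))
    if slope == 0.0:
        raise ZeroDivisionError("dS_BA/dM vanishes at the boundary position")
    denom = omega * slope if dlnc_dm is None else dlnc_dm + omega * slope
    return float(1.0 / (t * denom))


def wavefront_theory(times, omega, profile: ActionProfile, c,
                     m_upper=None) -> WavefrontResult:
    """Boundary position and velocity over a time grid."""
    times = np.asarray(times, dtype=float)
    m_s = np.array([boundary_position(t, omega, profile, c, m_upper) for t in times])
    v = np.array([boundary_velocity(t, omega, profile, c, m_upper) for t in times])
    return WavefrontResult(times=times, m_s=m_s, v=v)


def default_m_of_column(cols, m_min=0.12, m_max=1.4) -> np.ndarray:
    """Linear column -> signal map spanning the bistable zone plus a
    monostable margin (abstract signal coordinates; no explicit space)."""
    return np.linspace(m_min, m_max, cols)


def tissue_simulate(rows, cols, m_of_column, p: ToggleParams, n: NoiseParams,
                    t_snapshots, seed=0, dt=1e-3, s0=(0.0, 1.0)):
    """Simulate a sheet of statistically independent cells.

    Each cell runs its own CLE realisation from the prepattern state and is
    recorded at the snapshot times (typically log-spaced: the boundary
    decelerates over orders of magnitude in time). Returns a list of
    :class:`TissueSnapshot`.
    """
    if m_of_column is None:
        m_of_column = default_m_of_column(cols)
    m_of_column = np.asarray(m_of_column, dtype=float)
    if len(m_of_column) != cols:
        raise ValueError("m_of_column length must equal cols")
    t_snapshots = np.asarray(t_snapshots, dtype=float)
    if np.any(t_snapshots <= 0) or not np.all(np.diff(t_snapshots) > 0):
        raise ValueError("snapshot times must be positive and increasing")
    t_max = float(t_snapshots[-1])
    seeds = spawn_seeds(seed, rows * cols).reshape(rows, cols)
    grids = np.empty((len(t_snapshots), rows, cols, 2))
    s0 = np.asarray(s0, dtype=float)
    for j in range(cols):
        kp = _kernel_params(m_of_column[j], p, n)
        for i in range(rows):
            rec = np.empty((len(t_snapshots), 2))
            fpt, n_rec = _cle_kernel(*kp, s0[0], s0[1], np.inf, float(dt),
                                     t_max * (1.0 + 1e-12), int(seeds[i, j]),
                                     t_snapshots, rec, 0)
            if np.isnan(fpt) or n_rec < len(t_snapshots):
                raise FloatingPointError(
                    f"CLE failure in cell ({i},{j}) at M={m_of_column[j]:.3g}")
            grids[:, i, j, :] = rec
    return [TissueSnapshot(t=float(t_snapshots[k]), grid=grids[k],
                           m_values=m_of_column) for k in range(len(t_snapshots))]


def boundary_stats(snapshots) -> pd.DataFrame:
    """Boundary position and width per snapshot.

    m_50: signal level where the column-mean x_A crosses 0.5 (interpolated;
    NaN and flagged=True when the tissue is uniformly switched/unswitched).
    width: signal span of the elevated-variability region — the contiguous
    band of columns around the std peak whose standard deviation of x_A
    exceeds the baseline by half the peak prominence. The baseline (median
    std of committed columns, |mean - 0.5| > 0.4) matters because bursty
    production raises within-state variability far from the boundary; a
    plain half-maximum span would count that as boundary imprecision.
    """
    if len(snapshots) == 0:
        raise ValueError("need at least one snapshot")
    rows = []
    for snap in snapshots:
        order = np.argsort(snap.m_values)
        m = snap.m_values[order]
        mean = snap.column_mean_xa[order]
        std = snap.column_std_xa[order]
        # 3-point smoothing guards against single-column sampling noise
        if len(mean) >= 3:
            sm = np.convolve(mean, np.ones(3) / 3.0, mode="same")
            sm[0], sm[-1] = mean[0], mean[-1]
        else:
            sm = mean
        sign = np.sign(sm - 0.5)
        crossing_idx = np.where(sign[:-1] * sign[1:] < 0)[0]
        if len(crossing_idx) == 0:
            rows.append((snap.t, np.nan, np.nan, True))
            continue
        m50s = []
        for i in crossing_idx:
            frac = (0.5 - sm[i]) / (sm[i + 1] - sm[i])
            m50s.append(m[i] + frac * (m[i + 1] - m[i]))
        m_50 = float(np.mean(m50s))
        peak = int(np.argmax(std))
        committed = np.abs(mean - 0.5) > 0.4
        baseline = float(np.median(std[committed])) if committed.any() else 0.0
        thr = baseline + 0.5 * (std[peak] - baseline)
        lo = peak
        while lo > 0 and std[lo - 1] >= thr:
            lo -= 1
        hi = peak
        while hi < len(std) - 1 and std[hi + 1] >= thr:
            hi += 1
        width = float(m[hi] - m[lo])
        rows.append((snap.t, m_50, width, False))
    return pd.DataFrame(rows, columns=["t", "m_50", "width", "flagged"])
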