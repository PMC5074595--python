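"""Core model of the morphogen-controlled genetic toggle switch.

Two genes A and B repress each other; a scalar morphogen signal M activates
gene A. In non-dimensional units (time in units of the inverse degradation
rate of A, concentration in units of the A production/degradation balance)
the deterministic dynamics are

    dx_A/dt = p_A(M, x_B) - x_A
    dx_B/dt = alpha * p_B(x_A) - delta * x_B

where p_A and p_B are RNA-polymerase binding probabilities derived from an
equilibrium statistical-mechanics description of the two enhancers (two
independent repressor sites each; two independent effector sites on the
A enhancer). Intrinsic noise enters through a diagonal diffusion tensor
whose entries sum the production and degradation propensities, with burst
sizes nu_A, nu_B amplifying the production contribution and the system size
Omega setting the overall noise scale (variance ~ D / Omega).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np

__all__ = [
    "ToggleParams",
    "NoiseParams",
    "REFERENCE_PARAMS",
    "binding_prob_a",
    "binding_prob_b",
    "drift_field",
    "diffusion_tensor",
    "jacobian",
    "molecule_counts",
    "concentrations",
]


@dataclass(frozen=True)
class ToggleParams:
    """Deterministic constants of the toggle switch.

    alpha, delta : relative production / degradation rate of gene B
        (gene A's rates are scaled to 1 by the non-dimensionalization).
    rho_a, rho_b : basal activation parameters; larger values mean a
        promoter that is mostly off in the absence of regulation.
    k_a, k_b : rescaled dissociation constants of repressors A and B for
        their binding sites on the opposing enhancer.
    k_m : dissociation constant of the morphogen effector on the A enhancer.
    f : activation strength of the signal (> 1; f = 1 means no activation).
    """

    alpha: float = 1.0
    delta: float = 1.0
    rho_a: float = 1.0
    rho_b: float = 1.75e-4
    k_a: float = 1e-3
    k_b: float = 3e-2
    k_m: float = 1.0
    f: float = 10.0

    def __post_init__(self):
        for name in ("alpha", "delta", "rho_a", "rho_b", "k_a", "k_b", "k_m", "f"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"ToggleParams.{name} must be strictly positive, got {v!r}")
        if not self.f > 1:
            raise ValueError(f"ToggleParams.f must be > 1, got {self.f!r}")

    def asdict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "ToggleParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class NoiseParams:
    """Stochastic constants: system size and production burst sizes.

    omega : volume parameter converting concentration to molecule number
        (N_i = x_i * omega); the deterministic limit is omega -> infinity.
    nu_a, nu_b : number of protein molecules made per production event
        (>= 1); bursts raise production noise without changing the mean.
    """

    omega: float = 100.0
    nu_a: float = 1.0
    nu_b: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.omega) and self.omega > 0):
            raise ValueError(f"NoiseParams.omega must be strictly positive, got {self.omega!r}")
        for name in ("nu_a", "nu_b"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 1):
                raise ValueError(f"NoiseParams.{name} must be >= 1, got {v!r}")

    def asdict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "NoiseParams":
        return replace(self, **kw)


#: The reference parameter set used throughout (bistable for 0.088 < M < 0.999).
REFERENCE_PARAMS = ToggleParams()


def _check_nonneg(name, value):
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be non-negative")


def activation_factor(m, p: ToggleParams = REFERENCE_PARAMS):
    """Squared effector occupancy ratio ((1+M/K_M)/(1+fM/K_M))^2.

    Decreases from 1 (at M=0) to 1/f^2 (saturating signal); multiplying
    rho_a by it *increases* p_A with M for f > 1.
    """
    m = np.asarray(m, dtype=float)
    u = m / p.k_m
    return ((1.0 + u) / (1.0 + p.f * u)) ** 2


def binding_prob_a(m, x_b, p: ToggleParams = REFERENCE_PARAMS):
    """Probability that RNA polymerase is bound to the promoter of gene A.

    p_A = [1 + rho_a * ((1+M/K_M)/(1+fM/K_M))^2 * (1+x_B/K_B)^2]^-1

    Monotone increasing in the signal M (for f > 1) and decreasing in the
    repressor level x_B; always in (0, 1].
    """
    _check_nonneg("M", m)
    _check_nonneg("x_B", x_b)
    x_b = np.asarray(x_b, dtype=float)
    rep = (1.0 + x_b / p.k_b) ** 2
    return 1.0 / (1.0 + p.rho_a * activation_factor(m, p) * rep)


def binding_prob_b(x_a, p: ToggleParams = REFERENCE_PARAMS):
    """Probability that RNA polymerase is bound to the promoter of gene B.

    p_B = [1 + rho_b * (1+x_A/K_A)^2]^-1, monotone decreasing in x_A.
    """
    _check_nonneg("x_A", x_a)
    x_a = np.asarray(x_a, dtype=float)
    return 1.0 / (1.0 + p.rho_b * (1.0 + x_a / p.k_a) ** 2)


def drift_field(x_a, x_b, m, p: ToggleParams = REFERENCE_PARAMS):
    """Deterministic vector field (f_A, f_B) = (p_A - x_A, alpha p_B - delta x_B)."""
    f_a = binding_prob_a(m, x_b, p) - np.asarray(x_a, dtype=float)
    f_b = p.alpha * binding_prob_b(x_a, p) - p.delta * np.asarray(x_b, dtype=float)
    return f_a, f_b


def diffusion_tensor(x_a, x_b, m, p: ToggleParams, n: NoiseParams):
    """Diagonal entries (D_AA, D_BB) of the diffusion tensor.

    D = diag(nu_A p_A + x_A, nu_B alpha p_B + delta x_B): production and
    degradation propensities add; bursts multiply only the production term.
    Both entries are strictly positive for x >= 0 since p_i > 0.
    """
    d_aa = n.nu_a * binding_prob_a(m, x_b, p) + np.asarray(x_a, dtype=float)
    d_bb = n.nu_b * p.alpha * binding_prob_b(x_a, p) + p.delta * np.asarray(x_b, dtype=float)
    return d_aa, d_bb


def _binding_prob_derivs(x_a, x_b, m, p: ToggleParams):
    """dp_A/dx_B and dp_B/dx_A (both <= 0), used by the Jacobian and the
    gradient of the action functional."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    act = activation_factor(m, p)
    p_a = 1.0 / (1.0 + p.rho_a * act * (1.0 + x_b / p.k_b) ** 2)
    p_b = 1.0 / (1.0 + p.rho_b * (1.0 + x_a / p.k_a) ** 2)
    dpa_dxb = -(p_a**2) * p.rho_a * act * 2.0 * (1.0 + x_b / p.k_b) / p.k_b
    dpb_dxa = -(p_b**2) * p.rho_b * 2.0 * (1.0 + x_a / p.k_a) / p.k_a
    return p_a, p_b, dpa_dxb, dpb_dxa


def jacobian(x_a, x_b, m, p: ToggleParams = REFERENCE_PARAMS):
    """Analytic Jacobian of the drift field at a single state.

    [[-1,            dp_A/dx_B],
     [alpha dp_B/dx_A,   -delta]]
    """
    _check_nonneg("x_A", x_a)
    _check_nonneg("x_B", x_b)
    _, _, dpa_dxb, dpb_dxa = _binding_prob_derivs(x_a, x_b, m, p)
    return np.array([[-1.0, float(dpa_dxb)], [p.alpha * float(dpb_dxa), -p.delta]])


def molecule_counts(x, omega):
    """Convert non-dimensional concentration(s) to molecule numbers N = x * Omega."""
    return np.asarray(x, dtype=float) * float(omega)


def concentrations(n_molecules, omega):
    """Convert molecule numbers to non-dimensional concentrations x = N / Omega."""
    return np.asarray(n_molecules, dtype=float) / float(omega)
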