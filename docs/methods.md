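# Methods

## Model

Two genes, A and B, repress each other transcriptionally; an abstract
scalar morphogen signal M activates A. Protein production is assumed slow
compared with transcription-factor/enhancer binding, polymerase binding,
transcription and mRNA turnover, so production is proportional to the
equilibrium probability that RNA polymerase occupies the promoter. Each
enhancer carries two independent, non-overlapping repressor sites; the A
enhancer additionally carries two independent effector sites through
which the signal lowers the polymerase recruiting energy. This gives

    p_A(M, x_B) = [1 + ρ_A ((1 + M/K_M)/(1 + f M/K_M))² (1 + x_B/K_B)²]⁻¹
    p_B(x_A)    = [1 + ρ_B (1 + x_A/K_A)²]⁻¹

and the deterministic dynamics dx_A/dt = p_A − x_A, dx_B/dt = α p_B − δ x_B
in units of the A degradation time, with concentrations scaled so the
A production/degradation balance is 1. The steady-state structure depends
on α, δ only through α/δ; all fixed points live in the box
x_A ∈ [0, 1], x_B ∈ [0, α/δ] since p_i ≤ 1.

Intrinsic noise enters through the Chemical Langevin Equation

    dx = f(x) dt + sqrt(D(x)/Ω) dW,
    D = diag(ν_A p_A + x_A,  ν_B α p_B + δ x_B),

where Ω converts concentration to molecule number (N = xΩ) and ν_i are
production burst sizes. In D the burst size multiplies only the
production propensity: a burst channel firing at rate (rate/ν) with jump
ν leaves the mean unchanged and scales the production variance by ν.
The matching jump process (used by the exact SSA) has four channels:

| channel | propensity | jump |
|---|---|---|
| produce A | Ω p_A / ν_A | N_A += ν_A |
| degrade A | N_A | N_A −= 1 |
| produce B | Ω α p_B / ν_B | N_B += ν_B |
| degrade B | δ N_B | N_B −= 1 |

Its mean field is the deterministic system and its diffusion
approximation is exactly D above. This is a first-moment surrogate for
geometric bursting; full burst-size distributions, mRNA intermediates and
promoter states are out of scope.

## Parameters

Reference set (bundled as `figure2.cfg`): α = δ = ρ_A = 1,
ρ_B = 1.75·10⁻⁴, K_A = 10⁻³, K_B = 3·10⁻², K_M = 1, f = 10; stochastic
defaults Ω = 100, ν_A = ν_B = 1. All parameters are dimensionless; f > 1
is required (f = 1 removes the signal dependence entirely). With this
set the switch is bistable for 0.088 < M < 0.999. Patterning times are
measured as the first passage of x_A above a threshold (default 0.9) from
the prepattern state (x_A, x_B) = (0, 1); both are config-exposed.

## Deterministic analysis

Fixed points are found by damped Newton iteration vectorized over a
50×50 grid of starts in the bounding box, deduplicated at 10⁻⁶ max-norm
and classified by the eigenvalues of the analytic Jacobian. Saddle-node
folds are refined by bisection on the fixed-point count to 10⁻⁴ in M;
this is simpler than eigenvalue continuation and sufficient in 2D, where
the count goes 1 → 3 → 1 along the scan. ODE trajectories use LSODA with
rtol 10⁻⁸; the deterministic patterning time uses terminal event
detection on the threshold crossing. Just above the upper fold the
dynamics slow dramatically (the saddle-node "ghost"); the patterning time
diverges as M ↓ M_A and saturates at a minimal value at strong signal.

## Stochastic simulation

Both simulators are compiled numba kernels. The CLE uses fixed-step
Euler–Maruyama (default dt = 10⁻³ degradation times) with states clipped
at zero after each step; with the reference parameters p_i > 0, so drift
immediately re-enters the domain. Weak (ensemble-mean) accuracy is what
first-passage statistics require, which a fixed-step first-order scheme
provides; a step-refinement check (dt = 10⁻³ vs 5·10⁻⁴) is part of the
suite. Note the clipped boundary makes the scheme's bias decay like
√dt near x ≈ 0, which is why the refinement check uses the finer pair.
First-passage ensembles draw per-replicate streams from one root seed via
`numpy.random.SeedSequence` spawning (reproducible, order-independent);
statistics are reported over uncensored replicates with the censored
count alongside.

## Minimum action paths

The Freidlin–Wentzell action
S = ½ ∫ (φ̇ − f)ᵀ D⁻¹ (φ̇ − f) dt is minimized over paths joining the two
stable states (the saddle is not imposed; converged paths pass within
0.05 of it, and the downhill segment contributes essentially nothing).
Minimization over the path duration is done analytically per segment
(optimal Δt = |Δx|_D / |f|_D), reducing the problem to the geometric
action over node positions only — algebraically identical to jointly
optimizing nodes and time steps at the optimum. The reconstructed optimal
times are attached to the returned path, so evaluating the
time-parametrized functional on the result reproduces the minimized
value.

Numerics that matter:

* **Resolution.** The MAP has a boundary layer near the B attractor where
  x_A varies on the K_A = 10⁻³ scale. 401 nodes with redistribution to
  equal arclength in the D⁻¹ metric (which concentrates nodes where
  diffusion is small, i.e. exactly in that layer) gives ~0.3%
  discretization error; halving the node count roughly triples it.
* **Redistribution is a regularizer, not cosmetics.** Without it the
  discrete geometric action is minimized by collapsing segments into the
  layer and exploiting the signed midpoint-rule error (the "optimum"
  re-evaluates *higher* on a refined grid). The minimizer therefore
  alternates L-BFGS-B sweeps (analytic gradient, non-negativity bounds)
  with redistribution and stops when the per-sweep action plateaus at
  10⁻³ relative — the plateau cannot be pushed to machine precision
  because each redistribution injects ~10⁻³ relative interpolation noise.
* **Initialization.** Cold starts take the best of three guesses
  (straight line, line bowed toward the saddle, elbow through the
  saddle); profiles in M warm-start each point from its neighbour,
  traversing the grid from the direction's low-barrier end.

Action profiles S_BA(M) (falling) and S_AB(M) (rising) cross at the
stochastic steady-state boundary M*, located by monotone (PCHIP)
interpolation of the difference. M* is independent of Ω (the action
contains no Ω) and only weakly sensitive to burst sizes, which lower both
profiles nearly uniformly near the crossing.

The switching-time prefactor C in T = C e^{ΩS} is not accessible to
action minimization; it is fitted by regressing ln(mean first-passage
time) on Ω with the slope fixed to the minimized action, the intercept
giving ln C and its standard error coming from the per-Ω intercept
scatter. The unconstrained slope is reported as a large-deviation
consistency check; because ln T = ln C + ΩS holds asymptotically in ΩS,
the fit should use the largest system sizes whose switching times remain
simulable (ΩS ≈ 3–5 with the defaults).

## Travelling boundary

At time t the boundary sits where the local switching time equals the
elapsed time: S_BA(M_s) = ln(t/C)/Ω, inverted on the monotone profile by
interpolation; before ln(t/C) > 0 the boundary is pinned at the top of
the profile (≈ M_A). The velocity uses the large-Ω form
v = [Ω t ∂S_BA/∂M]⁻¹ (negative: advancing toward lower signal); the full
form with ∂lnC/∂M is available when a prefactor profile is supplied. C is
treated as M-independent by default, fitted once near the profile
midpoint — consistent with the large-Ω limit in which the prediction is
insensitive to C.

Tissue simulations run one independent CLE realisation per cell of a
rows × cols sheet from the prepattern state; columns map linearly to
M ∈ [0.12, 1.4] (bistable zone plus monostable margin). The boundary
position is the interpolated 50% crossing of the column-mean x_A
(3-point smoothed); the width is the contiguous band around the peak of
the column standard deviation exceeding the baseline by half the peak
prominence. The baseline (median std over committed columns) matters:
bursty production raises within-state variability far from the boundary,
and a plain half-maximum span would misread that as boundary imprecision.

What the tissue generator emulates — and does not. Cells are
statistically independent: there is no cell–cell coupling, no cell
division or movement, no explicit spatial morphogen profile or signalling
dynamics, and no extrinsic noise; the signal axis is abstract M, not
microns. Passing tests therefore validate the intrinsic-noise switching
theory, not predictions about tissues where coupling or morphogen
dynamics are first-order effects.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen to keep
each statistical check comfortably above its sampling error: fold scans
with 61–101 grid points; action profiles on ΔM = 0.025–0.1 grids with
301–401 path nodes; first-passage ensembles of 50–200 replicates;
large-deviation slopes over Ω ∈ {80, 100, 120} at M = 0.6; tissue sheets
of 10×40 cells over three decades of log-spaced time (40×60 for the
Ω-sharpness contrast, whose effect size of ~0.04 signal units needs the
deeper column averaging).

## Known limitations

* The burst model is a first-moment surrogate; exact geometric burst
  statistics and tau-leaping are not implemented.
* The clipped Euler–Maruyama boundary treatment biases first-passage
  means at O(√dt) when trajectories dwell near x ≈ 0; use the dt
  refinement check when changing parameters that shrink the B state.
* Fold continuation handles only saddle-node bifurcations of this
  two-gene system; there is no general continuation (Hopf, etc.).
* The prefactor fit assumes C varies slowly with Ω; at small Ω (ΩS ≲ 1)
  the Eikonal scaling itself degrades and the fitted slope
  underestimates the action by ~15–20%.
* The boundary-width estimator is resolution-limited by the column
  spacing and row count; contrasts smaller than ~one column span need
  larger sheets.
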