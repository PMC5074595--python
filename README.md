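# switchwave

Stochastic dynamics of morphogen-controlled bistable genetic toggle
switches: deterministic bifurcation analysis, exact (Gillespie) and
Chemical-Langevin simulation, Freidlin–Wentzell minimum action paths, and
the travelling gene-expression boundary they predict in a model tissue.

## The problem

During tissue patterning, a graded extracellular signal — a morphogen
*M* — is converted into sharp domains of gene expression by toggle
switches: pairs of cross-repressing transcription factors *A* and *B*. In
non-dimensional units the deterministic switch reads

    dx_A/dt = p_A(M, x_B) − x_A
    dx_B/dt = α p_B(x_A) − δ x_B

with RNA-polymerase binding probabilities

    p_A = [1 + ρ_A ((1 + M/K_M)/(1 + f M/K_M))² (1 + x_B/K_B)²]⁻¹
    p_B = [1 + ρ_B (1 + x_A/K_A)²]⁻¹.

For intermediate signal (M_B < M < M_A) the switch is bistable; the folds
M_A and M_B are saddle-node bifurcations. Gene expression is noisy,
however: production happens in bursts of ν molecules and the copy number
scale is set by a system size Ω (N = xΩ). Intrinsic noise lets cells hop
between the two states, with mean switching time

    T = C · exp(Ω S),

where S is the Freidlin–Wentzell action of the minimum action path (MAP)
between the attractors. Because S_BA(M) falls and S_AB(M) rises with the
signal, the two residence times balance at a signal level M* *inside* the
bistable zone — the stochastic steady-state boundary, distinct from the
deterministic boundary at M_A — and the switching front travels away from
the morphogen source at velocity v ≈ [Ω t ∂S_BA/∂M]⁻¹.

The package is for quantitative/developmental systems biologists who want
to go beyond steady-state bifurcation diagrams and ask how intrinsic
noise reshapes patterning time, boundary position, and boundary precision.

## Worked example

```python
import switchwave as sw

p = sw.REFERENCE_PARAMS               # α=δ=ρ_A=1, ρ_B=1.75e-4, K_A=1e-3,
noise = sw.NoiseParams(omega=100)     # K_B=3e-2, K_M=1, f=10; ν_A=ν_B=1

bif = sw.continuation_scan(p)
print(f"bistable window: M_B = {bif.m_b:.4f}, M_A = {bif.m_a:.4f}")

ens = sw.first_passage_ensemble(1.05, p, noise, n_reps=100, t_max=2e3, seed=1)
print(f"T_det(M=1.05) = {sw.patterning_time_det(1.05, p):.2f}  vs stochastic "
      f"{ens.mean:.2f} +/- {ens.sem:.2f} (Omega=100)")

res = sw.minimize_action("BA", 0.5, p, noise)
print(f"S_BA(M=0.5) = {res.s:.4f}, MAP passes {res.saddle_distance:.4f} from the saddle")

bal = sw.find_balance_point(p, noise)
print(f"stochastic steady-state boundary M* = {bal.m_star:.4f}")
```

prints

```
bistable window: M_B = 0.0881, M_A = 0.9993
T_det(M=1.05) = 39.85  vs stochastic 25.13 +/- 1.29 (Omega=100)
S_BA(M=0.5) = 0.0575, MAP passes 0.0250 from the saddle
stochastic steady-state boundary M* = 0.2990
```

Reading: the switch is bistable for 0.088 < M < 0.999. Just past the
upper fold the deterministic dynamics crawl through the saddle-node
"ghost" (T ≈ 40 time units at M = 1.05), but intrinsic fluctuations at
Ω = 100 cut that time by a third. Deep in the bistable zone, escape from
the prepattern state B costs action S_BA = 0.058 — a mean switching time
of order C·e^{ΩS} — along a path that threads the saddle point. The two
switching directions balance at M* ≈ 0.30: noise moves the final
expression boundary from M = 1.0 to deep inside the bistable zone.

The same analyses are exposed as a CLI (`switchwave bifurcation`,
`pattern-time`, `mfpt`, `map`, `action-profile`, `balance`, `prefactor`,
`wave`), each writing provenance-stamped CSV/JSON. Parameters come from a
flat YAML config; the bundled reference set is
`src/switchwave/data/figure2.cfg`.

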