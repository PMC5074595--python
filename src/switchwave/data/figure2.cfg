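# Reference parameter set of the morphogen-controlled toggle switch
# (bistable for 0.088 < M < 0.999).
alpha: 1.0
delta: 1.0
rho_A: 1.0
rho_B: 1.75e-4
K_A: 1.0e-3
K_B: 3.0e-2
K_M: 1.0
f: 10.0
omega: 100.0
nu_A: 1.0
nu_B: 1.0
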