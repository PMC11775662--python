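# Nominal consortium parameter fixture.
#
# Provenance: every value below is a documented PLACEHOLDER — the published
# nominal table for this consortium is not distributed with the package.
# The set was derived once, in closed form, so that:
#   * the timescale-separation assumptions behind the reduced model hold
#     (eta >> gamma; gamma_e << 4*N*gamma; gamma_z fast),
#   * the reference gain triple below (beta_P, beta_I, beta_D) satisfies the
#     equilibrium-existence condition for PI/PID, approximately satisfies the
#     unitary-static-gain identity for P/PD, and keeps the closed loop
#     Routh–Hurwitz stable,
#   * all four architectures meet the performance requirements
#     (e_inf <= 0.1, ts10 <= 1440 min, o% <= 20).
# See docs/methods.md for the derivation.
#
# Units: rates min^-1 unless noted; concentrations nM.

gamma: 0.02      # placeholder | dilution; doubling time ~35 min
beta_u: 0.5      # placeholder | Qu -> X1 activation
beta_c: 0.0062   # placeholder | X1 -> Xc activation
beta_x: 0.5      # placeholder | Xc -> Qx activation
mu: 1.0          # placeholder | reference scaling (set point mu*Yd, nM/min)
theta: 0.02      # placeholder | output scaling (measured signal theta*Qx)
beta_a: 0.5    # placeholder | derivative module, M -> A activation
beta_m: 0.5    # placeholder | derivative module, Yd -> M activation
gamma_a: 0.5   # placeholder | active degradation of A by Qx
gamma_m: 2.0   # placeholder | active degradation of M by A
gamma_z: 1.0     # placeholder | annihilation Z1+Z2, nM^-1 min^-1 (fast vs gamma)
gamma_e: 0.02    # placeholder | external QS degradation (= gamma; << 4*N*gamma)
eta: 20.0        # placeholder | QS membrane diffusion (1000x gamma)
K_a: 1.0         # placeholder | Michaelis constant of the A branch, nM
K_m: 1.0         # placeholder | Michaelis constant of the M branch, nM
N: 30            # placeholder | cells per population (120 total / 4)
Yd: 60.0         # reference signal, nM

# Reference control gains (min^-1), shared across P/PD/PI/PID:
beta_P: 0.0414
beta_D: 0.0933
beta_I: 0.0002
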