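"""Per-cell heterogeneity (growth + division redraws) and imbalance sweeps.

First runs a small heterogeneous PID consortium in which every division
redraws the daughter cells' activation parameters and gains at CV=0.1,
then sweeps the controller fraction rho_c at N=20 with growth off.  Both
are scaled-down versions of the agent-based robustness experiments.
"""

import numpy as np

import mcpid as m
from mcpid.hetero import (ChamberConfig, make_consortium, run_hetero,
                          run_imbalance, TARGET_ACTIVATION,
                          CONTROLLER_ACTIVATION)
from mcpid.metrics import moving_average, evaluate_run

params = m.nominal_params()
gains = m.nominal_gains()
arch = m.ARCHITECTURES["PID"]
rng = np.random.default_rng(5)
subset = TARGET_ACTIVATION + CONTROLLER_ACTIVATION

chamber = ChamberConfig(capacity=40, growth=True, division_step=10.0)
cells = make_consortium(arch, 40, params, gains, cv=0.1, rng=rng,
                        subset=subset, perturb_gains=True, chamber=chamber)
res = run_hetero(cells, chamber, params, gains, 2400.0, rng, cv=0.1,
                 subset=subset, perturb_gains=True, dt_out=5.0)
y = moving_average(res.output(params), 12)  # W = 60 min at dt = 5
rep = evaluate_run(res.times, y, params.mu * params.Yd)
print(f"heterogeneous PID (40 cells, CV=0.1): e_inf = {rep.e_inf*100:.2f}% "
      f"ts10 = {rep.ts:.0f} min  o = {rep.o:.2f}%")
print("counts per population at the end:",
      {pop: int(res.counts[pop][-1]) for pop in sorted(res.counts)})

print("\ncontroller-fraction sweep (N = 20, growth off):")
out = run_imbalance(arch, [0.2, 0.4, 0.6, 0.8], params, gains,
                    n_total=20, t_end=2880.0, rng=rng)
for rec in out:
    r = rec["report"]
    print(f"rho_c = {rec['rho_c']:.1f}: e_inf = {r.e_inf*100:5.2f}%  "
          f"ts10 = {r.ts:6.0f}  o = {r.o:5.2f}%  success = {rec['success']}")
print("\nThe integral cells keep regulation tight over a wide band of"
      "\nconsortium compositions; performance degrades only when targets"
      "\nor controllers become too scarce.")
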