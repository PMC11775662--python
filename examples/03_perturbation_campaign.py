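"""Robustness to target-parameter uncertainty (deterministic campaign).

Ten replicate simulations per architecture with the target activation
rates redrawn from Normal(nominal, 0.1*nominal), mirroring biological
parameter uncertainty.  Prints box-plot statistics of the percentage
steady-state error: only the integral-containing architectures keep the
error pinned near zero under perturbation.
"""

import mcpid as m
from mcpid.campaigns import perturbation_campaign

params = m.nominal_params()
gains = m.nominal_gains()

res = perturbation_campaign(params, gains, n=10, cv=0.10, seed=42,
                            t_end=2880.0)
print("percentage steady-state error over 10 perturbed runs:")
for lab in ("P", "PD", "PI", "PID"):
    s = res.summary[lab]["e_pct"]
    print(f"{lab:>4}: median = {s['median']:6.3f}%   "
          f"whiskers = [{s['whisker_low']:.3f}, {s['whisker_high']:.3f}]%   "
          f"outliers = {len(s['outliers'])}")
print("\nP/PD medians scatter with the perturbed parameters; PI/PID stay"
      "\nbelow a fraction of a percent (robust perfect adaptation).")
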