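# Methods

## The system

A microbial consortium divides the labour of a PID feedback loop among up
to three engineered *controller* populations — proportional (p), integral
(i) and derivative (d) cells — that regulate a two-gene process
(X1 → Xc) inside a *target* population (t). Two orthogonal quorum-sensing
(QS) molecules close the loop across the populations: `Qu` carries the
actuation signal from the controllers to the targets, `Qx` carries the
measured output back. The four architectures P, PD, PI and PID are the
subsets {t,p}, {t,p,d}, {t,p,i} and {t,p,i,d}.

The regulated signal is `y = theta*Qx` and the set point is `r = mu*Yd`;
the desired QS concentration is `Qd = mu*Yd/theta`.

## Models

**Full aggregate model.** One ODE block per population: the target's
X1/Xc cascade with QS production; the proportional cells' repression-Hill
production of Qu, `beta_P*Yd*mu*Yd/(mu*Yd + theta*Qx^p)`; the antithetic
pair Z1/Z2 annihilating at rate `gamma_z` (their difference integrates the
error, and `beta_I*Z1` actuates); and a Michaelis–Menten two-species
module (A, M) whose output `beta_D*A` implements the derivative action.
Every internal species dilutes at the common growth rate `gamma`; QS
molecules exchange with a single well-mixed external pool at rate `eta`
and degrade externally at `gamma_e`. The M species carries no dilution
term in the reference formulation; a `ModelOptions.m_dilution` flag adds
it for sensitivity studies (off by default), and `z_dilution` likewise for
the annihilation pair.

**Reduced model.** In the fast-diffusion regime the QS pools and the
controller modules are slaved to quasi-steady states, leaving `X1`, `Xc`
and (with integral cells) `zeta = Z1 - Z2`:

    X1' = beta_u*Qu - gamma*X1
    Xc' = beta_c*X1 - gamma*Xc
    zeta' = mu*Yd - theta*Qx

with `Qx = beta_x*Xc/Gamma`, `Qu = (u_P + beta_I*zeta + beta_D*A)/Gamma`,
`A = -(gamma_a*beta_x/(Gamma*beta_a*gamma_m))*Xc' + beta_m*Yd/gamma_m`
(Xc' substituted explicitly — no numerical differentiation), and
`Gamma = M*gamma` for an M-population consortium. The quasi-steady A may
transiently be negative; it is used as-is (`ModelOptions.clamp_A` clamps
it, off by default), since the reduced model is an abstraction.

**Validity of the reduction.** The QS *equalisation* across membranes is
controlled by `eta` and becomes exact as `eta >> gamma`, provided the
external sink is weak: the exact quasi-steady balance is
`beta_x*Xc/Qx = M*gamma + (gamma_e/N)(1 + gamma/eta)`, so the ideal
constant `M*gamma` additionally requires `gamma_e << M*N*gamma`. The QS
*pool* itself, however, relaxes at rate `gamma` — the same rate as the
process — so slaving it is only a factor-`M` timescale separation. In
practice: steady states agree for all architectures (and are exact for
PI/PID by integral action); P/PD transients agree within ~2% of the
steady state after a ~600-min boundary layer, improving monotonically in
`eta`; PI/PID transients keep ~10% peak deviation at any `eta` because
the unmodelled pool pole phase-shifts the slow oscillatory transient.
The test suite asserts exactly this pattern, no more.

## Linearized analysis

Linearizing the reduced model at the set point gives the closed-loop
transfer function from `mu*Yd` to `theta*Qx`

    G(s) = theta*beta_c*((3*kP + cD*kD)*s + kI) /
           (s^3 + (2g + t*bc*kD)s^2 + (g^2 + t*bc*kP)s + t*bc*kI)

with aggregated gains `kP = bP*bu*bx/(4*Gamma^2*mu)`,
`kI = bI*bu*bx/Gamma^2`, `kD = bD*bu*bx*ga/(Gamma^2*ba*gm*theta)` and
`cD = ba*bm*theta/(ga*mu)`. The numerator was re-derived symbolically
(sympy) from the reduced model; the derivation fixes the numerator degree
at one — the derivative feed-through multiplies `s`, not `s^2` — and the
package ships the symbolically verified form. Static gains follow
immediately: exactly 1 whenever `kI > 0` (robust perfect adaptation), and
`3*t*bc*kP/(g^2 + t*bc*kP)` for the pure P loop.

Equilibrium/tuning conditions: `kD + 2*kP*ga*mu/(ba*bm*th) =
g^2*ga*mu/(bc*ba*bm*th^2)` (equality: P/PD unitary tuning; `<=`: PI/PID
existence of the physical equilibrium, equivalent to Z1* >= 0). Stability
is decided by Routh–Hurwitz on the cubic (`a2*a1 > a0` plus positive
coefficients). The simplified inequality `kI < (2g + kD*t*bc)(g^2+kP*t*bc)`
(reported as `printed` in the stability report) differs from Routh–Hurwitz by a factor `1/(t*bc)`; both are evaluated and
returned, the Routh verdict governs, and a disagreement emits a warning.

Root contours sweep one aggregated gain; branches are matched between
grid points by optimal assignment in the complex plane. Dominant-pole
bounds: `sbP = -g`, `sbPD = -sqrt(g^2 + t*bc*kP)`, `sbPI = -(2/3)g`,
`sbPID = -(2/3)g - (1/3)t*bc*kD`; the P, PI and PID bounds are exact
consequences of root sums, the PD bound of the root product. Fastest-
response tuning finds the coincident-dominant-pole gain numerically: for
PD the discriminant of the quadratic factor has a unique zero in `kD`;
for PI/PID the cubic discriminant is quadratic in `a0 = t*bc*kI`, whose
positive roots are candidate tuning points (the triple-root degeneracy,
where the two candidates merge, is handled by clamping a vanishing
discriminant). Settling is estimated as `|ln chi|/|Re(dominant)|` and the
damping ratio as `-a/sqrt(a^2+b^2)`.

## Metrics

Steady state is the trapezoidal mean over the final 600 min. Settling
time is the *last exit* from the ±chi band around that value (robust to
re-entries; chi defaults to 0.10). Overshoot is the peak excursion above
the steady state in percent. Campaign error `e%` averages
`|Qhat_k - Qd|/Qd` over runs (absolute, as defined); the windowed error
`ebar` integrates the *signed* error from 1440 min (both conventions are
implemented exactly as defined). Box-plot summaries use the Tukey
1.5·IQR rule (the outlier rule is otherwise unspecified). Deterministic
runs are scored on raw signals; heterogeneous/stochastic runs on a
moving-average (W = 60 min) of the population-mean output.

## Heterogeneous and stochastic simulation

`hetero` integrates one ODE block per *cell*, each with private
parameters and gains, coupled only through the shared external pool
(`Qk_e' = sum_cells eta*(Qk_cell - Qk_e) - gamma_e*Qk_e`): a well-mixed
stand-in for a spatial chamber. Growth is periodic division (period
`ln2/gamma`, ±10% uniform jitter to avoid artificial synchrony, since the
timing convention is otherwise unspecified); daughters inherit the
mother's concentrations and *both* daughters receive freshly drawn
parameters, `Normal(nominal, CV*nominal)` resampled until positive
(truncation bias < 0.2% at CV = 0.15). Divisions are applied in batches
on a 5–20 min grid between solver segments (BDF with a sparse Jacobian
pattern). At capacity, washout removes a cell from the population most
above its initial share ("balanced"); uniform random washout is
available, but at desk scale (≈5 cells/population) it is a neutral Moran
process that exterminates whole controller populations within a two-day
run — a small-chamber artefact, not a property of the control design —
so it is not the default. Emptied populations are flagged, not fatal.

`ssa` reads every additive term of the per-cell rate laws as a reaction
propensity (mass-action terms scaled by the system size Omega; Hill and
Michaelis–Menten terms used as nonlinear rate laws on counts) and runs
the Gillespie direct method, growth off. Identical seeds reproduce runs
bit-for-bit.

What the per-cell simulator deliberately omits relative to a full
agent-based chamber: cell geometry and mechanics, spatial QS gradients,
growth-rate coupling to burden. Passing campaigns therefore demonstrate
robustness of the *control architecture* to parameter heterogeneity and
imbalance, not to spatial effects.

## Nominal parameters

The shipped `nominal` fixture is a set of documented placeholders (the
published nominal table is not redistributed). They were chosen once, in
closed form, to satisfy three requirements: (i) the reduction regime
(`eta = 1000*gamma`, `gamma_e = gamma << 4*N*gamma`, fast annihilation,
controller modules ~5× faster than the loop); (ii) the reference gain
triple `beta_P = 0.0414`, `beta_D = 0.0933`, `beta_I = 0.0002` min⁻¹ with
`Yd = 60` nM satisfies the PI/PID existence condition, lies inside the
Routh bound, and puts the P loop at its unitary tuning
(`t*bc*kP(P) ≈ gamma^2/2`) and the PD loop near it (2g + d ≈ 0.95);
(iii) all four architectures meet `e_inf <= 0.1`, `ts10 <= 1440` min,
`o% <= 20` from a zero initial state. With `gamma = 0.02` min⁻¹
(≈35-min doubling) this forces `theta*beta_c*beta_u*beta_x/mu =
8*gamma^4/beta_P` and, for the integral pole to settle inside 24 h,
`mu ≈ 1` min⁻¹; `beta_m/gamma_m = 0.25` sets the PD bias. The resulting
set point is `Qd = 3000` nM — high but within QS physiology; species
scales (Z1* ≈ 1.2·10⁴ nM) follow from the small `beta_I`.

## Problem sizes and numerical choices

Aggregate simulations: LSODA, rtol 1e-8/atol 1e-10, 1-min output grid
(minute-scale rates), zero initial state. Heterogeneous campaigns: BDF,
rtol 1e-5/atol 1e-7, 5–10 min output grid. The CV-sweep campaign in the
test suite uses the 120-cell chamber (the condition under which the
settling-inflation ratios are well defined — smaller chambers censor the
settling time at the horizon through redraw noise) with 6 replicates per
CV; the imbalance sweep uses N = 20 with growth off, as specified for
that experiment. The SSA consistency checks run a two-cell P consortium
at a low-copy toy operating point (counts ~50–100) so that ensembles
complete in seconds.

## Known limitations

- The reduced model's PI/PID transients carry an O(10%) structural
  deviation from the full model (pool pole at rate gamma); conclusions
  about transients rest on the full/per-cell models.
- The nominal fixture is a self-consistent placeholder set, not measured
  rates; quantities that depend on absolute rate values (settling times,
  overshoots) transfer to other parameter sets only through the
  dimensionless conditions above.
- The per-cell simulator is well-mixed; spatial heterogeneity of QS
  fields is outside its scope. One measurable consequence: in the
  120-cell CV-sweep campaign the PI settling-time inflation under
  CV = 0.15 falls in the expected ~2.5× range, but the PID architecture —
  whose nominal settling is fast (~410 min) — is repeatedly kicked out of
  the ±10% band by redraw noise, inflating its median settling ratio well
  beyond the ~1.2× a spatially averaged chamber exhibits. The campaign
  test records this discrepancy rather than hiding it.
- The stochastic module treats cell volume as constant (no growth), and
  the reaction set is constructed from the rate laws rather than an
  elementary-reaction mechanism.
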