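import numpy as np
import pytest

import mcpid as m
from mcpid.params import ARCHITECTURES


@pytest.fixture(scope="session")
def params():
    return m.nominal_params()


@pytest.fixture(scope="session")
def gains():
    return m.nominal_gains()


@pytest.fixture(params=["P", "PD", "PI", "PID"])
def arch(request):
    return ARCHITECTURES[request.param]


def random_params(rng: np.random.Generator, **fixed) -> m.ConsortiumParams:
    """A random positive parameter set in physiologically plausible ranges."""

    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    kw = dict(
        gamma=lu(0.005, 0.05),
        beta_u=lu(0.05, 1.0),
        beta_c=lu(1e-3, 0.05),
        beta_x=lu(0.05, 1.0),
        mu=lu(0.05, 2.0),
        theta=lu(0.005, 0.1),
        beta_a=lu(0.02, 0.5),
        beta_m=lu(0.02, 0.5),
        gamma_a=lu(0.05, 1.0),
        gamma_m=lu(0.05, 1.0),
        gamma_z=lu(0.2, 2.0),
        gamma_e=lu(0.005, 0.05),
        eta=lu(5.0, 50.0),
        K_a=lu(0.5, 5.0),
        K_m=lu(0.5, 5.0),
        N=int(rng.integers(5, 60)),
        Yd=lu(10.0, 200.0),
    )
    kw.update(fixed)
    return m.ConsortiumParams(**kw)


def conditioned_gains(
    p: m.ConsortiumParams, arch: m.Architecture, rng: np.random.Generator
) -> m.ControlGains:
    """Gains satisfying the set-point/existence/stability conditions.

    P/PD: the unitary-static-gain identity holds exactly (the linearization
    point then coincides with the equilibrium).  PI/PID: the existence
    inequality holds strictly and kappa_I sits inside the Routh bound.
    """
    Gamma = arch.Gamma(p)
    tb = p.theta * p.beta_c
    c = p.gamma_a * p.mu / (p.beta_a * p.beta_m * p.theta)
    budget = p.gamma**2 * c / (p.beta_c * p.theta)  # Eq-2.26 right-hand side

    def beta_P_of(kP):
        return kP * 4 * Gamma**2 * p.mu / (p.beta_u * p.beta_x)

    def beta_D_of(kD):
        return kD * Gamma**2 * p.beta_a * p.gamma_m * p.theta / (
            p.beta_u * p.beta_x * p.gamma_a)

    def beta_I_of(kI):
        return kI * Gamma**2 / (p.beta_u * p.beta_x)

    if arch.label == "P":
        kP = budget / (2 * c)
        return m.ControlGains(beta_P=beta_P_of(kP))
    if arch.label == "PD":
        u = rng.uniform(0.2, 0.8)
        kP = u * budget / (2 * c)
        kD = (1 - u) * budget
        return m.ControlGains(beta_P=beta_P_of(kP), beta_D=beta_D_of(kD))
    u = rng.uniform(0.1, 0.6)
    kP = u * budget / (2 * c)
    kD = 0.0
    if arch.label == "PID":
        kD = rng.uniform(0.1, 0.7) * (1 - u) * budget
    a2 = 2 * p.gamma + tb * kD
    a1 = p.gamma**2 + tb * kP
    kI = rng.uniform(0.1, 0.8) * a2 * a1 / tb  # inside the Routh bound
    return m.ControlGains(beta_P=beta_P_of(kP), beta_I=beta_I_of(kI),
                          beta_D=beta_D_of(kD))
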