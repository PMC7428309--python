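import numpy as np
import pytest

from promsprt.embryo import BoundaryProblem, EmbryoGradient, NucleiCensus
from promsprt.promoter import PromoterArchitecture


@pytest.fixture(scope="session")
def gradient():
    return EmbryoGradient()


@pytest.fixture(scope="session")
def boundary_problem(gradient):
    """The 2 %EL / 10 % concentration discrimination problem at e = 0.32."""
    return BoundaryProblem.from_gradient(gradient, delta_x=2.0, error_rate=0.32)


@pytest.fixture(scope="session")
def baseline_arch():
    """Six identical independent sites at the diffusion limit, half-active
    at the boundary (per-site on 0.124 s^-1, off 0.0154 s^-1)."""
    return PromoterArchitecture.independent_sites(6, 0.124, 0.0154, L_ref=5.6)


@pytest.fixture(scope="session")
def bursty_arch():
    """Six identical independent sites with fast per-site kinetics
    (per-site on 0.07 s^-1 at L = 5.88, off 0.08 s^-1)."""
    return PromoterArchitecture.independent_sites(6, 0.07, 0.08, L_ref=5.88)


@pytest.fixture(scope="session")
def single_site_arch():
    """One diffusion-limited site, on-rate 0.124 s^-1 at the boundary."""
    return PromoterArchitecture([0.124 / 5.6], [0.08])


def random_architecture(rng, N=6):
    """A random feasible N-site architecture with rates spanning decades."""
    mu = np.exp(rng.uniform(np.log(1e-3), np.log(0.02), N))
    nu = np.exp(rng.uniform(np.log(1e-2), np.log(1.0), N))
    return PromoterArchitecture(mu, nu)


@pytest.fixture(scope="session")
def census11():
    return NucleiCensus(cycle=11)
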