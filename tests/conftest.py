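import numpy as np
import pytest

from actonet import reference_parameters
from actonet.network import (ACTIVE, KIND_ACP, KIND_MOTOR, Arm,
                             DomainBoundary, Filament, Linker, NetworkState)
from actonet.params import drag_coefficient


@pytest.fixture(scope="session")
def p():
    return reference_parameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def quasi_continuum_params(p):
    """Soft motor arms + fine time step: the force gained per 140-nm step is
    a small fraction of the stall force, so stall plateaus resolve the rate
    law rather than the step quantization.  Viscosity only rescales time."""
    mu = 0.344
    return p.replace(mu=mu,
                     zeta_per_segment=drag_coefficient(mu, p.r0_A),
                     dt=4e-6, kappa_s_M=1.0e-5,
                     k0_u_M=0.0, k0_u_ACP=0.0)


@pytest.fixture(scope="session")
def soft_p(p):
    return quasi_continuum_params(p)


def kinematic_params(p):
    """Low-drag regime for free-sliding kinematics: viscous drag at the
    unloaded sliding speed stays far below the stall force, and spring
    relaxation is much faster than the stepping interval."""
    mu = 3.44e-3
    return p.replace(mu=mu,
                     zeta_per_segment=drag_coefficient(mu, p.r0_A),
                     dt=1.5e-6, n_kinetic=100,
                     kappa_s_A=2.5e-4, kappa_r=2.5e-4, kappa_s_M=2.0e-4,
                     kappa_s_ACP=2.0e-4, k0_u_M=0.0, k0_u_ACP=0.0)


def crooked_state(p, seed=0, n_fil=3, n_nodes=5, with_linkers=True):
    """A small hand-built state with curved filaments and ACTIVE linkers,
    positions jittered so no force term is at its minimum.  Hinge lengths
    stay above the degenerate-sliver guard."""
    rng = np.random.default_rng(seed)
    fils = {}
    for f in range(n_fil):
        t = np.linspace(0, (n_nodes - 1) * p.r0_A, n_nodes)
        base = np.column_stack([t, np.full(n_nodes, 160.0 * f),
                                np.zeros(n_nodes)])
        base += rng.normal(0.0, 8.0, base.shape)
        fils[f] = Filament(base)
    linkers = {}
    if with_linkers and n_fil >= 2:
        # one ACP and one motor bridging neighbouring filaments
        for lid, (kind, r0, fa, fb, na, nb) in enumerate(
                [(KIND_ACP, p.r0_ACP, 0, 1, 1, 2),
                 (KIND_MOTOR, p.r0_M, 1, 2, 3, 3)][: n_fil - 1]):
            x0 = fils[fa].nodes[na]
            x1 = fils[fb].nodes[nb]
            d = (x1 - x0) / np.linalg.norm(x1 - x0)
            bp = np.vstack([x0 + d * r0, x1 - d * r0])
            bp += rng.normal(0.0, 3.0, bp.shape)
            lk = Linker(kind, ACTIVE, [Arm(fa, na), Arm(fb, nb)], bp)
            lk.backbone_r0 = 0.6 * float(np.linalg.norm(bp[1] - bp[0]))
            linkers[lid] = lk
    W = 40 * p.r0_A
    return NetworkState(fils, linkers, DomainBoundary.cube(W, p.E, False))
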