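"""Deterministic synthetic configurations for testing every mechanism
without a full-scale assembly.

* a single straight filament (force-field and thermal-statistics checks),
* a two-filament antiparallel "sarcomere" bridged by one motor
  (polarity, sliding and stall),
* a desk-scale percolated mini-network in a clamped domain
  (substrate-stiffness trend runs).
"""

from __future__ import annotations

import numpy as np

from .assembly import (AssemblyError, assemble_network, percolation_fraction,
                       spans_all_axes)
from .boundary import sever_and_clamp, sticky_capture
from .network import (ACTIVE, KIND_MOTOR, Arm, DomainBoundary, Filament,
                      Linker, NetworkState, Tether)
from .params import reference_parameters


def make_single_filament(n_nodes: int, seed: int = 0, p=None,
                         W0_factor: float = 4.0) -> NetworkState:
    """A straight filament at rest along x, centred in a quiet open domain."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    p = p or reference_parameters()
    L = (n_nodes - 1) * p.r0_A
    x = np.linspace(-L / 2, L / 2, n_nodes)
    nodes = np.column_stack([x, np.zeros(n_nodes), np.zeros(n_nodes)])
    W = max(W0_factor * L, 2 * L + 4 * p.sticky_capture_nm)
    domain = DomainBoundary.cube(W, p.E, periodic=False)
    return NetworkState({0: Filament(nodes)}, {}, domain)


def make_motor_sarcomere(overlap_nm: float = 700.0,
                         tether_stiffness: float = 1.0e-2,
                         n_segments: int = 14, p=None) -> NetworkState:
    """Two antiparallel filaments bridged by one ACTIVE motor, ends held by
    tether springs (``tether_stiffness`` in N/m; the default is effectively
    rigid on the motor force scale).

    Barbed ends point outward, so walking separates the two attachment
    sites and develops contractile tension in the motor, as in a sarcomere.
    """
    p = p or reference_parameters()
    if overlap_nm < p.r0_A:
        raise ValueError("overlap must be at least one segment")
    r0, ov = p.r0_A, overlap_nm
    L = n_segments * r0
    y = 2 * p.r0_M / 2.0        # filaments separated by the motor span

    # filament 0: x in [ov/2 - L, ov/2], barbed end at index 0 (-x side)
    x0 = np.linspace(ov / 2 - L, ov / 2, n_segments + 1)
    f0 = Filament(np.column_stack([x0, np.full_like(x0, +y),
                                   np.zeros_like(x0)]), barbed_at_end=False)
    # filament 1: x in [-ov/2, -ov/2 + L], barbed end at last index (+x side)
    x1 = np.linspace(-ov / 2, -ov / 2 + L, n_segments + 1)
    f1 = Filament(np.column_stack([x1, np.full_like(x1, -y),
                                   np.zeros_like(x1)]), barbed_at_end=True)

    n0 = int(np.argmin(np.abs(x0)))
    n1 = int(np.argmin(np.abs(x1)))
    a = f0.nodes[n0]
    b = f1.nodes[n1]
    d = b - a
    dhat = d / np.linalg.norm(d)
    bp = np.vstack([a + dhat * p.r0_M, b - dhat * p.r0_M])
    motor = Linker(KIND_MOTOR, ACTIVE, [Arm(0, n0), Arm(1, n1)], bp,
                   backbone_r0=float(np.linalg.norm(bp[1] - bp[0])))

    k_int = tether_stiffness * 1e3          # N/m -> pN/nm
    tethers = [Tether(0, 0, f0.nodes[0].copy(), k_int),
               Tether(0, n_segments, f0.nodes[-1].copy(), k_int),
               Tether(1, 0, f1.nodes[0].copy(), k_int),
               Tether(1, n_segments, f1.nodes[-1].copy(), k_int)]

    W = 2 * (L + ov) + 1000.0
    domain = DomainBoundary.cube(W, p.E, periodic=False)
    return NetworkState({0: f0, 1: f1}, {0: motor}, domain, tethers=tethers)


def make_mini_network(n_filaments: int = 30, box_um: float = 1.5,
                      R_ACP: float = 0.01, R_M: float = 0.02,
                      seed: int = 1, p=None, E: float | None = None
                      ) -> NetworkState:
    """Desk-scale stand-in for the 5-um reference network: a percolated,
    severed-and-clamped mini-domain ready for a contraction run.

    Filaments keep the reference mean length (2 um): wall-clamped filaments
    are the stress-bearing skeleton, and 30 such filaments in a 1.5-um box
    reproduce the reference actin concentration (~11 uM).
    """
    base = p or reference_parameters()
    p2 = base.replace(W0=box_um, R_ACP=R_ACP, R_M=R_M,
                      **({"E": E} if E is not None else {}))
    st = assemble_network(p2, seed, n_filaments=n_filaments)
    st = sever_and_clamp(st, p2)
    st = sticky_capture(st, p2)
    if not spans_all_axes(st):
        raise AssemblyError(
            "mini-network does not span the clamped domain on every axis "
            f"(percolating fraction {percolation_fraction(st):.0%})")
    return st
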