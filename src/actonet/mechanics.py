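"""Deterministic and thermal forces, and overdamped Euler integration.

The force field has three conservative terms, each a simple quadratic
potential whose force is the exact analytic gradient:

* extension  U_s = 1/2 kappa_s (r - r0)^2 on every filament segment and
  linker arm/backbone bond;
* bending    U_b = 1/2 kappa_b (theta - theta0)^2 on filament hinges
  (theta0 = pi), linker arm-arm hinges (theta0 = 0, parallel arms) and
  arm-filament hinges (theta0 = pi/2);
* repulsion  U_r = 1/2 kappa_r (r12 - r_c)^2 for actin segment pairs whose
  minimum distance r12 falls below the segment diameter r_c, distributed to
  the four segment endpoints by the lever rule.

The thermal force obeys the fluctuation-dissipation theorem: independent
zero-mean kicks with per-component variance 2 kBT zeta / dt.  Positions are
updated with the explicit Euler scheme x += (F/zeta) dt; inertia is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .engine import Engine, InstabilityError
from .network import NetworkState

__all__ = [
    "ForceAccumulator", "extension_forces", "bending_forces",
    "repulsive_forces", "thermal_forces", "total_forces", "euler_step",
    "min_distance", "segment_distance", "InstabilityError",
]


@dataclass
class ForceAccumulator:
    """Per-node forces (pN) plus per-category potential energies (pN nm)."""
    force: np.ndarray                  # (N, 3)
    energy_extension: float = 0.0
    energy_bending: float = 0.0
    energy_repulsion: float = 0.0

    def check_finite(self) -> None:
        if not np.all(np.isfinite(self.force)):
            raise FloatingPointError("non-finite force entries")


def _engine(state: NetworkState, p) -> Engine:
    return Engine(state, p, noise=False)


def extension_forces(state: NetworkState, p, engine: Engine | None = None
                     ) -> ForceAccumulator:
    """Hookean forces of all bonds (filament segments, linker arms/backbones)."""
    en = engine or _engine(state, p)
    F = np.zeros_like(en.pos)
    e = K.bond_forces(en.pos, en.b_i, en.b_j, en.b_k, en.b_r0, F)
    if np.isnan(e):
        raise ZeroDivisionError("zero-length bond with finite rest length")
    acc = ForceAccumulator(F, energy_extension=float(e))
    acc.check_finite()
    return acc


def bending_forces(state: NetworkState, p, engine: Engine | None = None
                   ) -> ForceAccumulator:
    """Hinge forces at filament triplets and linker angle constraints."""
    en = engine or _engine(state, p)
    F = np.zeros_like(en.pos)
    e = K.angle_forces(en.pos, en.a_i, en.a_j, en.a_k, en.a_l,
                       en.a_kap, en.a_t0, F)
    acc = ForceAccumulator(F, energy_bending=float(e))
    acc.check_finite()
    return acc


def repulsive_forces(state: NetworkState, p, engine: Engine | None = None
                     ) -> ForceAccumulator:
    """Excluded-volume forces between overlapping actin segments."""
    en = engine or _engine(state, p)
    F = np.zeros_like(en.pos)
    e = K.repulsion_forces(en.pos, en.pair_s1, en.pair_s2, en.seg_a,
                           en.seg_b, en.ip.kr, en.ip.rc, F)
    acc = ForceAccumulator(F, energy_repulsion=float(e))
    acc.check_finite()
    return acc


def thermal_forces(state: NetworkState, p, rng: np.random.Generator,
                   engine: Engine | None = None) -> ForceAccumulator:
    """Gaussian thermal kicks, per-component variance 2 kBT zeta / dt."""
    en = engine or _engine(state, p)
    ip = en.ip
    var = 2.0 * ip.kBT * ip.zeta / ip.dt
    F = rng.normal(0.0, np.sqrt(var), size=en.pos.shape) if var > 0 \
        else np.zeros_like(en.pos)
    F *= en.free_mask[:, None]
    return ForceAccumulator(F)


def total_forces(state: NetworkState, p, engine: Engine | None = None
                 ) -> ForceAccumulator:
    """Sum of the three conservative contributions."""
    en = engine or _engine(state, p)
    F, (e_ext, e_bend, e_rep) = en.compute_forces()
    acc = ForceAccumulator(F, float(e_ext), float(e_bend), float(e_rep))
    acc.check_finite()
    return acc


def euler_step(state: NetworkState, p, rng: np.random.Generator | None = None,
               n_steps: int = 1, seed: int | None = None) -> NetworkState:
    """Advance the state by ``n_steps`` explicit Euler steps (in place).

    Clamped nodes do not move; time advances by n_steps * dt.  Raises
    :class:`InstabilityError` when the deterministic displacement of any
    node exceeds 0.1 r_c in one step.
    """
    en = _engine(state, p)
    en.noise = rng is not None or seed is not None
    if seed is None:
        seed = int(rng.integers(2 ** 31)) if rng is not None else 0
    en.window(n_steps, seed)
    return en.sync_to_state()


# ---------------------------------------------------------------------------
# segment geometry
# ---------------------------------------------------------------------------

def segment_distance(a1, b1, a2, b2):
    """Minimum distance between segments [a1,b1] and [a2,b2].

    Returns (distance, s, t) where the closest points are a1 + s (b1-a1)
    and a2 + t (b2-a2), s and t in [0, 1].
    """
    d, s, t = K.segment_distance_jit(np.asarray(a1, float),
                                     np.asarray(b1, float),
                                     np.asarray(a2, float),
                                     np.asarray(b2, float))
    return float(d), float(s), float(t)


def min_distance(segA, segB):
    """Spec-shaped wrapper: ((a1, b1), (a2, b2)) -> (distance, (s, t))."""
    d, s, t = segment_distance(segA[0], segA[1], segB[0], segB[1])
    return d, (s, t)
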