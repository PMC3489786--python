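"""Derived observables of a contraction run.

* stress/strain time series and their summary metrics (plateau stress
  sigma_p, initial stress rate sigma_dot0 over t < 10 s, initial strain
  rate eps_dot0 = sigma_dot0/E, plateau strain eps_p, mechanical power
  P = sigma_0 eps_dot0 V),
* a census of why motors are stalled (load, blocking, barbed-end arrest),
* the distribution of motor arm tensions,
* a Hill force-velocity fit (sigma_0 + a)(eps_dot0 + b) = c across a
  substrate-stiffness sweep.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import walk_rate
from .network import ACTIVE, INACTIVE, KIND_MOTOR, NetworkState, occupancy_map

__all__ = [
    "MeasurementSeries", "SummaryMetrics", "StallCensus", "HillFit",
    "summarize", "stall_census", "motor_force_distribution", "hill_fit",
    "mechanical_power",
]


@dataclass
class MeasurementSeries:
    """Time-stamped records of a run plus its reproducibility metadata."""
    records: pd.DataFrame          # t_s, sigma_Pa, sigma_raw_Pa, per-face
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = self.records["t_s"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time stamps must be strictly increasing")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(self.metadata) + "\n")
            self.records.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasurementSeries":
        with open(path) as fh:
            first = fh.readline()
            meta = json.loads(first[1:]) if first.startswith("#") else {}
            df = pd.read_csv(fh)
        return cls(df, meta)


@dataclass
class SummaryMetrics:
    sigma_p_Pa: float        # stress at the horizon ("plateau stress")
    sigma_dot0_Pa_s: float   # OLS slope of sigma over t < 10 s
    eps_dot0_per_s: float    # = sigma_dot0 / E
    eps_p: float             # strain at the horizon (contraction positive)
    sigma_0_Pa: float        # stress at t = 10 s
    P_W: float               # sigma_0 * eps_dot0 * V
    E_n_Pa: float = np.nan   # probe stiffness, filled in separately

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StallCensus:
    force: float
    blocked: float
    barbed: float
    not_stalled: float
    n_motors: int

    def fractions(self) -> np.ndarray:
        return np.array([self.force, self.blocked, self.barbed,
                         self.not_stalled])


@dataclass
class HillFit:
    a_Pa: float
    b_per_s: float
    c_Pa_s: float
    shape_factor: float       # a / sigma_0_max with sigma_0_max = c/b - a
    rms_residual: float


# ---------------------------------------------------------------------------

def summarize(series: MeasurementSeries, p, early_window_s: float = 10.0
              ) -> SummaryMetrics:
    """Summary metrics of a contraction run.

    Stress is the mean over the six faces, strain the mean over the three
    axes; the plateau is read at the recorded horizon.
    """
    df = series.records
    t = df["t_s"].to_numpy()
    if t[-1] < early_window_s:
        raise ValueError(
            f"series horizon {t[-1]:g} s is shorter than the "
            f"{early_window_s:g} s early-slope window")
    sigma = df["sigma_Pa"].to_numpy()
    eps = df["eps"].to_numpy()
    early = t < early_window_s
    A = np.column_stack([t[early], np.ones(early.sum())])
    slope, _ = np.linalg.lstsq(A, sigma[early], rcond=None)[0]
    sigma_dot0 = float(slope)
    eps_dot0 = sigma_dot0 / p.E
    i10 = int(np.argmin(np.abs(t - early_window_s)))
    sigma_0 = float(sigma[i10])
    V_um3 = float(df["V_um3"].iloc[i10]) if "V_um3" in df else \
        (p.W0 * 1e3) ** 3 * 1e-9
    return SummaryMetrics(
        sigma_p_Pa=float(sigma[-1]),
        sigma_dot0_Pa_s=sigma_dot0,
        eps_dot0_per_s=eps_dot0,
        eps_p=float(eps[-1]),
        sigma_0_Pa=sigma_0,
        P_W=mechanical_power(sigma_0, eps_dot0, V_um3),
    )


def mechanical_power(sigma_0_Pa: float, eps_dot0_per_s: float,
                     V_um3: float) -> float:
    """P = sigma_0 * eps_dot0 * V in watts (V in um^3)."""
    return float(sigma_0_Pa * eps_dot0_per_s * V_um3 * 1e-18)


# ---------------------------------------------------------------------------

_PRECEDENCE = {"barbed": 3, "force": 2, "blocked": 1, "none": 0}


def stall_census(state: NetworkState, p, stall_fraction: float = 0.01
                 ) -> StallCensus:
    """Why are the motors not walking?

    Every bound motor is classified by its most advanced arm with
    precedence barbed-end arrest > force stall > blocking; INACTIVE
    (one-armed) motors count as not stalled.  Fractions are over all bound
    motors and sum to one.
    """
    from .kinetics import _arm_tension
    occ = occupancy_map(state)
    k0 = float(walk_rate(0.0, p))
    counts = {"force": 0, "blocked": 0, "barbed": 0, "not_stalled": 0}
    n_motors = 0
    for lid, lk in state.linkers.items():
        if lk.kind != KIND_MOTOR:
            continue
        if lk.state == INACTIVE:
            n_motors += 1
            counts["not_stalled"] += 1
            continue
        if lk.state != ACTIVE:
            continue
        n_motors += 1
        best = "none"
        for ai, arm in enumerate(lk.arms):
            f = state.filaments[arm.filament]
            if arm.node == f.barbed_index:
                cls = "barbed"
            else:
                _, f_par = _arm_tension(state, p, lid, ai)
                if float(walk_rate(f_par, p)) < stall_fraction * k0:
                    cls = "force"
                elif (arm.filament, arm.node + f.toward_barbed) in occ:
                    cls = "blocked"
                else:
                    cls = "none"
            if _PRECEDENCE[cls] > _PRECEDENCE[best]:
                best = cls
        counts["barbed" if best == "barbed" else
               "force" if best == "force" else
               "blocked" if best == "blocked" else "not_stalled"] += 1
    if n_motors == 0:
        return StallCensus(0.0, 0.0, 0.0, 0.0, 0)
    return StallCensus(counts["force"] / n_motors,
                       counts["blocked"] / n_motors,
                       counts["barbed"] / n_motors,
                       counts["not_stalled"] / n_motors, n_motors)


def motor_force_distribution(state: NetworkState, p=None) -> dict:
    """Arm-tension magnitudes (pN) of ACTIVE motors: quartiles + histogram."""
    from .kinetics import _arm_tension
    from .params import reference_parameters
    p = p or reference_parameters()
    forces = []
    for lid, lk in state.linkers.items():
        if lk.kind != KIND_MOTOR or lk.state != ACTIVE:
            continue
        for ai in range(2):
            tension, _ = _arm_tension(state, p, lid, ai)
            forces.append(tension)
    forces = np.array(forces)
    if forces.size == 0:
        raise ValueError("no ACTIVE motors present")
    q1, med, q3 = np.percentile(forces, [25, 50, 75])
    hist, edges = np.histogram(forces, bins=20)
    return {"median_pN": float(med), "q1_pN": float(q1), "q3_pN": float(q3),
            "forces_pN": forces, "hist": hist, "bin_edges_pN": edges}


# ---------------------------------------------------------------------------

def hill_fit(points) -> HillFit:
    """Least-squares fit of (sigma_0 + a)(eps_dot0 + b) = c.

    ``points``: iterable of (sigma_0 Pa, eps_dot0 1/s), at least 4, from a
    substrate-stiffness sweep.  Initialization comes from the linearized
    form sigma*eps + b*sigma + a*eps + (ab - c) = 0, so the fit is
    deterministic.
    """
    pts = np.asarray(list(points), float)
    if pts.shape[0] < 4:
        raise ValueError("need at least 4 (sigma_0, eps_dot0) points")
    s, e = pts[:, 0], pts[:, 1]
    if np.ptp(s) == 0 or np.ptp(e) == 0 or np.any(pts < 0):
        raise ValueError("degenerate points: need positive, varying "
                         "sigma_0 and eps_dot0")
    # linearized initial estimate
    X = np.column_stack([e, s, np.ones_like(s)])
    coef, *_ = np.linalg.lstsq(X, -s * e, rcond=None)
    a0, b0, d0 = coef
    c0 = a0 * b0 - d0
    x0 = np.log(np.maximum([a0, b0, c0], 1e-12))

    def resid(x):
        a, b, c = np.exp(x)
        return (s + a) * (e + b) - c

    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise RuntimeError("Hill fit did not converge")
    a, b, c = np.exp(sol.x)
    sigma_max = c / b - a
    rms = float(np.sqrt(np.mean(sol.fun ** 2)))
    return HillFit(float(a), float(b), float(c),
                   float(a / sigma_max) if sigma_max > 0 else np.nan, rms)
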