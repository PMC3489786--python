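"""Contraction runs: the coupled mechanics / kinetics / substrate loop.

A run starts from a clamped network at zero wall stress and integrates for
the configured horizon.  Each kinetics window (n_kinetic Euler steps):

1. the Brownian-dynamics window advances all beads and accumulates the
   time-averaged inward normal force on each face's anchors;
2. the stochastic kinetics fire (unbinding, walking, binding);
3. filament ends within the sticky-capture distance of a face are clamped;
4. the six faces move toward their quasi-static substrate targets,
   displacement = (sigma/E) * (W0/2), where sigma is an exponentially
   smoothed wall stress (time constant ``tau_face_s``) to keep thermal
   anchor-force noise out of the face motion.

Records (stress per face and averaged, axis strains, energies, cumulative
event counts) are appended every ``record_every_s``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .boundary import (FaceCrossingError, apply_sticky_capture, face_targets,
                       sever_and_clamp, stress_from_forces, sticky_capture)
from .engine import Engine
from .kinetics import KineticsEngine
from .measure import MeasurementSeries
from .network import ACTIVE, KIND_MOTOR, NetworkState

__all__ = ["run_contraction", "run_sweep"]


def run_contraction(state: NetworkState, p, horizon_s: float, seed: int,
                    record_every_s: float = 0.1, tau_face_s: float = 0.2,
                    substrate: bool = True, kinetics: bool = True,
                    noise: bool = True) -> MeasurementSeries:
    """Run the active contraction protocol; mutates ``state`` in place.

    A periodic (freshly assembled) state is first severed, clamped and
    sticky-captured.  Returns the measurement series; the final network is
    left in ``state`` (or its clamped replacement, see metadata).
    """
    if state.domain.periodic.any():
        state = sticky_capture(sever_and_clamp(state, p), p)
    rng = np.random.default_rng(seed)
    en = Engine(state, p, noise=noise, det_limit_frac=2.0)
    kin = KineticsEngine(en, p) if kinetics else None

    dt_w = p.dt * p.n_kinetic
    n_windows = int(round(horizon_s / dt_w))
    rec_every = max(1, int(round(record_every_s / dt_w)))
    alpha = min(1.0, dt_w / tau_face_s)
    max_step = 0.01 * state.domain.W0

    sigma_ema = np.zeros(6)
    rows = []
    W0 = state.domain.W0

    def record(t, sigma_raw):
        w = state.domain.widths()
        eps_axes = (W0 - w) / W0
        rows.append({
            "t_s": t,
            "sigma_Pa": float(sigma_ema.mean()),
            "sigma_raw_Pa": float(sigma_raw.mean()),
            **{f"sigma_f{f}_Pa": float(sigma_ema[f]) for f in range(6)},
            "eps": float(eps_axes.mean()),
            **{f"eps_ax{a}": float(eps_axes[a]) for a in range(3)},
            "V_um3": state.domain.volume_nm3() * 1e-9,
            "E_ext_pNnm": float(energies[0]),
            "E_bend_pNnm": float(energies[1]),
            "E_rep_pNnm": float(energies[2]),
            "n_active_motors": sum(
                1 for lk in state.linkers.values()
                if lk.kind == KIND_MOTOR and lk.state == ACTIVE),
            **({f"n_{k}": v for k, v in kin.counts.items()} if kin else {}),
        })

    energies = np.zeros(3)
    record(0.0, np.zeros(6))
    bind_every = max(1, int(round(0.01 / dt_w)))   # slow chemistry stride
    sticky_every = max(1, int(round(0.005 / dt_w)))
    for w in range(n_windows):
        seed_w = int(rng.integers(2 ** 31))
        stress_force, energies = en.window(p.n_kinetic, seed_w)
        sigma_raw = stress_from_forces(en, stress_force)
        sigma_ema += alpha * (sigma_raw - sigma_ema)
        if kin is not None:
            kin.window(rng, do_bind=(w % bind_every == 0),
                       dt_bind=bind_every * dt_w)
        if w % sticky_every == 0:
            apply_sticky_capture(en, p)
        if substrate:
            tgt = face_targets(state.domain, sigma_ema)
            cur = state.domain.face_pos
            tgt = cur + np.clip(tgt - cur, -max_step, max_step)
            if np.any(tgt[1::2] - tgt[0::2] <= 0.05 * W0):
                raise FaceCrossingError(
                    f"opposing faces about to cross at t={state.time:.2f}s")
            for f in range(6):
                en.move_face(f, tgt[f])
        if (w + 1) % rec_every == 0:
            record((w + 1) * dt_w, sigma_raw)

    en.sync_to_state()
    meta = {"params": p.to_dict(), "seed": seed, "horizon_s": horizon_s,
            "record_every_s": record_every_s, "tau_face_s": tau_face_s}
    series = MeasurementSeries(pd.DataFrame(rows), meta)
    series.final_state = state
    series.events = kin.events if kin is not None else []
    return series


def run_sweep(base_state: NetworkState, p, grid: dict, horizon_s: float,
              seeds, progress=None) -> pd.DataFrame:
    """One contraction run per grid point x seed on copies of one network.

    ``grid`` maps ParameterSet field names to value lists (e.g.
    ``{"E": [100, 1000, 10000]}``).  Returns a tidy summary table; failed
    runs are isolated and reported in the ``error`` column.
    """
    import itertools

    from .measure import stall_census, summarize

    keys = list(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in keys)):
        for seed in seeds:
            pp = p.replace(**dict(zip(keys, values)))
            st = base_state.copy()
            st.domain.E = pp.E
            row = dict(zip(keys, values))
            row["seed"] = seed
            try:
                series = run_contraction(st, pp, horizon_s, seed)
                m = summarize(series, pp,
                              early_window_s=min(10.0, horizon_s / 2))
                row.update(m.to_dict())
                cen = stall_census(series.final_state, pp)
                row.update(census_force=cen.force,
                           census_blocked=cen.blocked,
                           census_barbed=cen.barbed,
                           census_not_stalled=cen.not_stalled)
            except Exception as exc:   # noqa: BLE001 - isolate per-run failures
                if progress:
                    progress(f"run {row} failed: {exc}")
                row["error"] = str(exc)
            rows.append(row)
            if progress:
                progress(f"done {row.get('seed')} {dict(zip(keys, values))}")
    return pd.DataFrame(rows)
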