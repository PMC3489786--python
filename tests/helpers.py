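"""Independent oracles shared by the unit and acceptance suites."""

import numpy as np

from actonet.engine import Engine


def numerical_gradient(energy_fn, pos, h=1e-4):
    """Central-difference gradient of a scalar energy over (N, 3) positions."""
    g = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for d in range(3):
            pp = pos.copy()
            pp[i, d] += h
            ep = energy_fn(pp)
            pp[i, d] -= 2 * h
            em = energy_fn(pp)
            g[i, d] = (ep - em) / (2 * h)
    return g


def check_force_is_gradient(state, p, term: str, rtol=1e-6):
    """Force of one conservative term == -numerical gradient of its energy."""
    en = Engine(state, p, noise=False, det_limit_frac=2.0)
    idx = {"extension": 0, "bending": 1, "repulsion": 2, "total": None}[term]

    def energy(pos):
        en.pos[:] = pos
        _, e = en.compute_forces()
        return e.sum() if idx is None else e[idx]

    pos0 = en.pos.copy()
    if term == "extension":
        from actonet import mechanics
        F = mechanics.extension_forces(state, p, engine=en).force
    elif term == "bending":
        from actonet import mechanics
        en.pos[:] = pos0
        F = mechanics.bending_forces(state, p, engine=en).force
    elif term == "repulsion":
        from actonet import mechanics
        en.pos[:] = pos0
        F = mechanics.repulsive_forces(state, p, engine=en).force
    else:
        en.pos[:] = pos0
        F, _ = en.compute_forces()
    en.pos[:] = pos0
    grad = numerical_gradient(energy, pos0)
    scale = max(np.abs(F).max(), 1e-9)
    return np.abs(F + grad).max() / scale


def brute_force_segment_distance(a1, b1, a2, b2, n=120):
    """Two-stage dense sampling of min distance between two segments."""
    s = np.linspace(0.0, 1.0, n)
    P = a1[None] + s[:, None] * (b1 - a1)[None]
    Q = a2[None] + s[:, None] * (b2 - a2)[None]
    d2 = ((P[:, None, :] - Q[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    lo_s, hi_s = max(0, i - 1) / (n - 1), min(n - 1, i + 1) / (n - 1)
    lo_t, hi_t = max(0, j - 1) / (n - 1), min(n - 1, j + 1) / (n - 1)
    s2 = np.linspace(lo_s, hi_s, n)
    t2 = np.linspace(lo_t, hi_t, n)
    P = a1[None] + s2[:, None] * (b1 - a1)[None]
    Q = a2[None] + t2[:, None] * (b2 - a2)[None]
    d2 = ((P[:, None, :] - Q[None, :, :]) ** 2).sum(-1)
    return np.sqrt(d2.min())


def brute_force_neighbor_pairs(state, cutoff):
    """All-pairs scan oracle for the contact search."""
    from actonet.mechanics import segment_distance
    segs = []
    for fid in sorted(state.filaments):
        f = state.filaments[fid]
        for i in range(f.n_segments):
            segs.append((fid, i, f.nodes[i], f.nodes[i + 1]))
    out = set()
    for a in range(len(segs)):
        for b in range(a + 1, len(segs)):
            fa, ia, p1, q1 = segs[a]
            fb, ib, p2, q2 = segs[b]
            if fa == fb and abs(ia - ib) < 2:
                continue
            d, _, _ = segment_distance(p1, q1, p2, q2)
            if d < cutoff:
                out.add(((fa, ia), (fb, ib)))
    return out


def measure_com_diffusion(p, n_windows=1500, steps_per_window=50, seed=7):
    """Diffusion coefficient (nm^2/s) of a free two-bead filament's centre
    of mass, from mean-squared window increments (Einstein relation)."""
    from actonet.fixtures import make_single_filament

    st = make_single_filament(2, p=p)
    en = Engine(st, p, noise=True, det_limit_frac=2.0)
    rng = np.random.default_rng(seed)
    dt_win = steps_per_window * p.dt
    com = np.empty((n_windows + 1, 3))
    com[0] = en.pos[:2].mean(axis=0)
    for k in range(n_windows):
        en.window(steps_per_window, int(rng.integers(2 ** 31)))
        com[k + 1] = en.pos[:2].mean(axis=0)
    inc = np.diff(com, axis=0)
    msd = (inc ** 2).sum(axis=1).mean()      # 6 D_com dt_win
    return msd / (6.0 * dt_win)


def sarcomere_plateau_tension(p_soft, duration_s=6.0, seed=7):
    """Run the motor 'sarcomere' with effectively rigid tethers at T = 0 and
    return the mean plateau arm tension (pN)."""
    from actonet.fixtures import make_motor_sarcomere
    from actonet.kinetics import KineticsEngine, _arm_tension

    st = make_motor_sarcomere(700.0, 1e-2, p=p_soft)
    en = Engine(st, p_soft, noise=False, det_limit_frac=2.0)
    kin = KineticsEngine(en, p_soft)
    rng = np.random.default_rng(seed)
    n_win = int(duration_s / (p_soft.dt * p_soft.n_kinetic))
    for _ in range(n_win):
        en.window(p_soft.n_kinetic, int(rng.integers(2 ** 31)))
        kin.window(rng, do_bind=False)
    en.sync_to_state()
    return float(np.mean([_arm_tension(st, p_soft, 0, ai)[0]
                          for ai in range(2)]))
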