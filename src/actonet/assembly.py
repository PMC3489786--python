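"""Generate an active actin network at dynamic steady state.

The constructor is a geometric/kinetic-Monte-Carlo scheme rather than a
full polymerization simulation: the measurement phase only needs a
geometrically representative network of stated composition, with actin
turnover already frozen.

1. The actin monomer pool implied by C_A and the domain volume is
   partitioned into filaments whose segment counts follow a geometric
   (nucleation/elongation steady-state) distribution with mean
   L_f_mean / r0_A, minimum 2 nodes.
2. Each filament grows as a discrete worm-like chain (angular step
   variance 2 kBT / kappa_b_A) from a uniform seed, unwrapped, with
   periodic boundaries in mind.
3. ACPs and motors start as implicit free monomers (counts R * N_monomer,
   uniformly distributed over the voxel pools) and bind/unbind by the same
   second-order and Bell (zero-force) rules used during measurement, on
   the frozen geometry, until their active fractions are at steady state
   (change < 2% between successive sliding windows).
4. Residual G-actin is deleted; assembly/disassembly stays deactivated.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .network import (ACTIVE, INACTIVE, KIND_ACP, KIND_MOTOR,
                      N_VOXELS_PER_AXIS, Arm, DomainBoundary, Filament,
                      Linker, NetworkState)

__all__ = ["assemble_network", "respawn_motors", "AssemblyError",
           "percolation_fraction", "spans_all_axes"]


class AssemblyError(RuntimeError):
    pass


def _sample_segment_counts(rng, mean_segments: float, n_filaments=None,
                           total_segments=None) -> np.ndarray:
    """Geometric segment counts, minimum 2 segments, mean ~ mean_segments."""
    m = max(mean_segments - 2.0, 1.0)
    if n_filaments is not None:
        return 2 + rng.geometric(1.0 / m, size=n_filaments)
    counts = []
    acc = 0
    while acc < total_segments:
        c = 2 + int(rng.geometric(1.0 / m))
        counts.append(c)
        acc += c
    return np.array(counts)


def _grow_filament(rng, start, n_segments, r0, sigma_theta):
    """Discrete WLC growth, unwrapped coordinates."""
    pts = np.empty((n_segments + 1, 3))
    pts[0] = start
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    for i in range(n_segments):
        pts[i + 1] = pts[i] + r0 * d
        # perturb direction by two transverse Gaussian angles
        e1 = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(e1) < 1e-6:
            e1 = np.cross(d, [1.0, 0.0, 0.0])
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        g1, g2 = rng.normal(0.0, sigma_theta, size=2)
        d = d + g1 * e1 + g2 * e2
        d /= np.linalg.norm(d)
    return pts


def assemble_network(p, seed: int, n_filaments: int | None = None,
                     kmc_dt: float = 0.05, kmc_min_s: float = 4.0,
                     kmc_max_s: float = 60.0,
                     require_percolation: bool = True) -> NetworkState:
    """Build a periodic network at linker-binding steady state.

    With ``n_filaments`` given, that many filaments are drawn (reduced-scale
    fixtures); otherwise the filament number follows from C_A and the
    domain volume.  Raises :class:`AssemblyError` when the resulting
    network does not percolate (too dilute).
    """
    ip = p.internal()
    rng = np.random.default_rng(seed)
    W = ip.W0
    lo = -W / 2.0
    mono_per_seg = ip.monomers_per_nm * ip.r0_A
    mean_seg = ip.Lf / ip.r0_A

    if n_filaments is None:
        n_mono = ip.C_A_per_nm3 * W ** 3
        counts = _sample_segment_counts(
            rng, mean_seg, total_segments=int(round(n_mono / mono_per_seg)))
    else:
        counts = _sample_segment_counts(rng, mean_seg,
                                        n_filaments=n_filaments)
        n_mono = counts.sum() * mono_per_seg

    sigma_theta = np.sqrt(ip.kBT / ip.kb_A)
    filaments: dict[int, Filament] = {}
    for fid, c in enumerate(counts):
        start = rng.uniform(lo, lo + W, size=3)
        pts = _grow_filament(rng, start, int(c), ip.r0_A, sigma_theta)
        filaments[fid] = Filament(pts, barbed_at_end=True)

    domain = DomainBoundary.cube(W, p.E, periodic=True)
    state = NetworkState(filaments, {}, domain)

    # free pools: uniform distribution of the implicit monomers
    n_ACP = int(round(p.R_ACP * n_mono))
    n_M = int(round(p.R_M * n_mono))
    nv = N_VOXELS_PER_AXIS ** 3
    state.free_ACP[:] = rng.multinomial(n_ACP, np.full(nv, 1.0 / nv))
    state.free_M[:] = rng.multinomial(n_M, np.full(nv, 1.0 / nv))

    _kmc_to_steady_state(state, p, rng, kmc_dt, kmc_min_s, kmc_max_s)

    if require_percolation:
        frac = percolation_fraction(state)
        if frac < 0.5:
            raise AssemblyError(
                f"network does not percolate: largest connected cluster "
                f"holds only {frac:.0%} of filaments "
                f"(C_A={p.C_A}, R_ACP={p.R_ACP}, R_M={p.R_M})")
    state.rng_state = rng.bit_generator.state
    return state


def _kmc_to_steady_state(state, p, rng, dt_a, min_s, max_s) -> None:
    """Bind/unbind kinetics on frozen geometry until steady state."""
    ip = p.internal()
    W = ip.W0
    lo = -W / 2.0

    fids, nidx, xyz = [], [], []
    offset: dict[int, int] = {}
    acc = 0
    for fid, f in state.filaments.items():
        offset[fid] = acc
        acc += f.n_nodes
        fids.extend([fid] * f.n_nodes)
        nidx.extend(range(f.n_nodes))
        xyz.append(f.nodes)
    fids = np.array(fids)
    nidx = np.array(nidx)
    xyz_w = np.mod(np.concatenate(xyz) - lo, W)          # wrapped into [0, W)
    tree = cKDTree(xyz_w, boxsize=W)
    n_nodes = len(fids)
    occ = np.full(n_nodes, -1, np.int64)                  # linker id or -1

    nvx = N_VOXELS_PER_AXIS
    nv = nvx ** 3
    ijk = np.clip((xyz_w / W * nvx).astype(int), 0, nvx - 1)
    voxel = (ijk[:, 0] * nvx + ijk[:, 1]) * nvx + ijk[:, 2]
    v_vox = W ** 3 / nv

    linkers = state.linkers
    next_id = 0
    history: list[tuple[float, float]] = []
    totals = {KIND_ACP: int(state.free_ACP.sum())
              + sum(1 for l in linkers.values() if l.kind == KIND_ACP),
              KIND_MOTOR: int(state.free_M.sum())
              + sum(1 for l in linkers.values() if l.kind == KIND_MOTOR)}

    t = 0.0
    while t < max_s:
        t += dt_a
        # ---- unbinding (zero force) -----------------------------------
        for lid in list(linkers):
            lk = linkers[lid]
            k0 = p.k0_u_M if lk.kind == KIND_MOTOR else p.k0_u_ACP
            for ai, arm in enumerate(lk.arms):
                if not arm.attached:
                    continue
                if rng.random() < 1.0 - np.exp(-k0 * dt_a):
                    g = offset[arm.filament] + arm.node
                    occ[g] = -1
                    arm.filament = None
                    arm.node = None
            attached = [a for a in lk.arms if a.attached]
            if len(attached) == 1 and lk.state == ACTIVE:
                lk.state = INACTIVE
            elif len(attached) == 0:
                pool = (state.free_M if lk.kind == KIND_MOTOR
                        else state.free_ACP)
                pool[rng.integers(nv)] += 1
                del linkers[lid]

        unocc = occ < 0
        sites_per_vox = np.bincount(voxel[unocc], minlength=nv)

        # ---- first-arm binding ----------------------------------------
        for kind, pool, k2, r0 in (
                (KIND_ACP, state.free_ACP, ip.kbind_ACP, ip.r0_ACP),
                (KIND_MOTOR, state.free_M, ip.kbind_M, ip.r0_M)):
            rates = k2 * (pool / v_vox) * sites_per_vox
            nev = rng.poisson(rates * dt_a)
            for vox in np.nonzero(nev)[0]:
                for _ in range(int(min(nev[vox], pool[vox]))):
                    cand = np.nonzero(unocc & (voxel == vox))[0]
                    if len(cand) == 0:
                        break
                    g = int(rng.choice(cand))
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    bp0 = xyz_w[g] + lo + r0 * u
                    linkers[next_id] = Linker(
                        kind, INACTIVE,
                        [Arm(int(fids[g]), int(nidx[g])), Arm()],
                        np.vstack([bp0, bp0.copy()]))
                    occ[g] = next_id
                    unocc[g] = False
                    pool[vox] -= 1
                    next_id += 1

        # ---- second-arm binding ---------------------------------------
        for lid in list(linkers):
            lk = linkers[lid]
            if lk.state != INACTIVE:
                continue
            bound_ai = 0 if lk.arms[0].attached else 1
            arm0 = lk.arms[bound_ai]
            g0 = offset[arm0.filament] + arm0.node
            k2 = ip.kbind_M if lk.kind == KIND_MOTOR else ip.kbind_ACP
            r0 = ip.r0_M if lk.kind == KIND_MOTOR else ip.r0_ACP
            reach = max(2 * r0 * (1 + p.bind_capture_tol), ip.r0_A)
            near = tree.query_ball_point(xyz_w[g0], reach)
            near = np.array([g for g in near
                             if unocc[g] and fids[g] != arm0.filament
                             and g != g0], int)
            if len(near) == 0:
                continue
            rate = k2 * len(near) / (4.0 / 3.0 * np.pi * reach ** 3)
            if rng.random() >= 1.0 - np.exp(-rate * dt_a):
                continue
            g = int(rng.choice(near))
            other = 1 - bound_ai
            lk.arms[other] = Arm(int(fids[g]), int(nidx[g]))
            lk.bp[other] = xyz_w[g] + lo  # normalized later by sever/clamp
            lk.state = ACTIVE
            occ[g] = lid
            unocc[g] = False

        # ---- steady-state detection -----------------------------------
        n_active = sum(1 for l in linkers.values() if l.state == ACTIVE)
        history.append((t, n_active / max(1, sum(totals.values()))))
        if t >= min_s and len(history) >= 40:
            w = max(10, len(history) // 10)
            recent = np.mean([h[1] for h in history[-w:]])
            before = np.mean([h[1] for h in history[-2 * w:-w]])
            if abs(recent - before) < 0.02 * max(recent, 1e-9):
                break


# ---------------------------------------------------------------------------

def percolation_fraction(state: NetworkState) -> float:
    """Fraction of filaments in the largest linker-connected cluster."""
    ids = sorted(state.filaments)
    index = {fid: i for i, fid in enumerate(ids)}
    rows, cols = [], []
    for lk in state.linkers.values():
        if lk.state != ACTIVE:
            continue
        a, b = lk.arms
        rows.append(index[a.filament])
        cols.append(index[b.filament])
    n = len(ids)
    if not rows:
        return 1.0 / max(n, 1)
    g = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    ncomp, labels = connected_components(g, directed=False)
    return np.bincount(labels).max() / n


def spans_all_axes(state: NetworkState) -> bool:
    """True if a clamped network transmits stress across every axis:
    some linker-connected cluster touches both faces of each axis."""
    ids = sorted(state.filaments)
    index = {fid: i for i, fid in enumerate(ids)}
    n = len(ids)
    rows, cols = [], []
    for lk in state.linkers.values():
        if lk.state != ACTIVE:
            continue
        a, b = lk.arms
        rows.append(index[a.filament])
        cols.append(index[b.filament])
    g = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)) \
        if rows else coo_matrix((n, n))
    _, labels = connected_components(g, directed=False)
    for axis in range(3):
        lo_ok = set()
        hi_ok = set()
        for (fid, end), face in state.domain.clamps.items():
            if face // 2 != axis:
                continue
            (lo_ok if face % 2 == 0 else hi_ok).add(labels[index[fid]])
        if not (lo_ok & hi_ok):
            return False
    return True


def respawn_motors(state: NetworkState, R_M_new: float, seed: int, p
                   ) -> NetworkState:
    """Replace the motor population at density ``R_M_new``, leaving the
    filament and ACP geometry untouched; new motors start as free monomers."""
    if R_M_new < 0:
        raise ValueError("R_M_new must be non-negative")
    st = state.copy()
    for lid in [l for l, lk in st.linkers.items() if lk.kind == KIND_MOTOR]:
        del st.linkers[lid]
    total_len_nm = sum(
        np.linalg.norm(np.diff(f.nodes, axis=0), axis=1).sum()
        for f in st.filaments.values())
    n_mono = total_len_nm * p.actin_monomers_per_nm
    n_M = int(round(R_M_new * n_mono))
    rng = np.random.default_rng(seed)
    nv = st.free_M.shape[0]
    st.free_M[:] = rng.multinomial(n_M, np.full(nv, 1.0 / nv))
    return st
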