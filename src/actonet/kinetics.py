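"""Stochastic kinetics: force-dependent motor walking, Bell unbinding,
and second-order (re)binding from implicit monomer pools.

Walking
-------
Active motor arms step one binding site (one filament node, spacing r0_A)
toward the barbed end at a load-dependent rate

    k_w(F_par) = 1 / (d_w1 exp(lambda_w1 F_par) + d_w2 exp(lambda_w2 F_par))

for resisting loads F_par > 0, and k_w(0) otherwise.  F_par is the arm
tension projected on the local filament tangent toward the pointed end;
only such resisting tension slows the motor.  The two-time-constant dwell
form mimics single-molecule myosin load dependence; with the reference
parameters the rate falls below 1% of its unloaded value at ~4 pN (the
stall force).  A step onto an occupied site is refused (blocking); an arm
that reaches the barbed-end node stays there until it unbinds.

Unbinding
---------
Bell's law k_u(F) = k0_u exp(lambda_u F / kBT) on the arm tension
magnitude, with (k0_u, lambda_u) per linker kind.

Binding
-------
Free linkers are implicit per-voxel monomer pools.  First-arm binding is a
second-order reaction k_bind [free][available sites] per voxel; a bound
(INACTIVE) linker may attach its second arm to an unoccupied node on a
different filament at span 2 r0 (+/- a tolerance), becoming ACTIVE.

Within one kinetics window (dt_kinetic = n_kinetic * dt) events are
evaluated unbinding first, then walking, then binding; firing events are
processed in a seeded random permutation to avoid site-contention bias.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .engine import Engine
from .network import (ACTIVE, FREE, INACTIVE, KIND_ACP, KIND_MOTOR, Arm,
                      Linker, NetworkState, occupancy_map)

__all__ = [
    "EventOutcome", "walk_rate", "stall_force", "unbind_rate",
    "attempt_walk", "attempt_unbind", "attempt_bind", "KineticsEngine",
]

WALK, BLOCK, UNBIND, BIND, BARBED_ARREST = (
    "walk", "block", "unbind", "bind", "barbed_arrest")


def events_to_csv(events, path) -> None:
    """Write an event log as comma-separated text
    (time, kind, linker, arm, filament, node)."""
    with open(path, "w") as fh:
        fh.write("time_s,kind,linker,arm,filament,node\n")
        for e in events:
            fh.write(f"{e.time:.6f},{e.kind},{e.linker},"
                     f"{'' if e.arm is None else e.arm},"
                     f"{'' if e.filament is None else e.filament},"
                     f"{'' if e.node is None else e.node}\n")


@dataclass
class EventOutcome:
    kind: str                 # walk | block | unbind | bind | barbed_arrest
    linker: int
    arm: int | None
    filament: int | None
    node: int | None
    time: float


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def walk_rate(F_parallel, p):
    """Load-dependent stepping rate, 1/s.  Vectorized over F_parallel (pN)."""
    F = np.maximum(np.asarray(F_parallel, float), 0.0)
    with np.errstate(over="ignore"):        # huge loads -> rate 0
        dwell = (p.d_w1 * np.exp(p.lambda_w1 * F)
                 + p.d_w2 * np.exp(p.lambda_w2 * F))
        return 1.0 / dwell


def stall_force(p, fraction: float = 0.01) -> float:
    """Load (pN) at which k_w falls to ``fraction`` of its unloaded value."""
    k0 = float(walk_rate(0.0, p))
    return float(brentq(lambda F: float(walk_rate(F, p)) - fraction * k0,
                        0.0, 1e3))


def unbind_rate(F, kind: str, p):
    """Bell unbinding rate, 1/s, for arm tension magnitude F (pN)."""
    F = np.maximum(np.asarray(F, float), 0.0)
    if kind == KIND_MOTOR:
        k0, lam = p.k0_u_M, p.lambda_u_M
    else:
        k0, lam = p.k0_u_ACP, p.lambda_u_ACP
    return k0 * np.exp(lam * F / p.kBT_pNnm)


# ---------------------------------------------------------------------------
# per-arm geometry helpers (NetworkState level, used by the spec operations)
# ---------------------------------------------------------------------------

def _arm_tension(state: NetworkState, p, lid: int, ai: int):
    """(tension magnitude pN, resisting component F_par pN along -barbed)."""
    ip = p.internal()
    lk = state.linkers[lid]
    arm = lk.arms[ai]
    f = state.filaments[arm.filament]
    node = f.nodes[arm.node]
    d = lk.bp[ai] - node
    r = np.linalg.norm(d)
    r0 = ip.r0_M if lk.kind == KIND_MOTOR else ip.r0_ACP
    ks = ip.ks_M if lk.kind == KIND_MOTOR else ip.ks_ACP
    ext = r - r0
    tension = ks * max(ext, 0.0)
    if tension == 0.0 or r == 0.0:
        return 0.0, 0.0
    # unit tangent toward the pointed end
    tb = f.toward_barbed
    if 0 <= arm.node - tb < f.n_nodes:
        tvec = f.nodes[arm.node - tb] - node
    else:
        tvec = node - f.nodes[arm.node + tb]
    tn = np.linalg.norm(tvec)
    if tn == 0.0:
        return tension, 0.0
    f_par = tension * float(np.dot(d / r, tvec / tn))
    return tension, max(f_par, 0.0)


def attempt_walk(state: NetworkState, motor_arm: tuple[int, int], p,
                 rng: np.random.Generator, dt_kinetic: float | None = None
                 ) -> EventOutcome | None:
    """One walking attempt of an attached motor arm; mutates the state.

    Returns the event outcome, or None if the stochastic clock did not fire.
    """
    lid, ai = motor_arm
    lk = state.linkers[lid]
    arm = lk.arms[ai]
    if not arm.attached or lk.state != ACTIVE:
        raise ValueError("walking requires an attached arm of an ACTIVE "
                         "motor")
    if dt_kinetic is None:
        dt_kinetic = p.dt * p.n_kinetic
    _, f_par = _arm_tension(state, p, lid, ai)
    k = float(walk_rate(f_par, p))
    if rng.random() >= 1.0 - np.exp(-k * dt_kinetic):
        return None
    f = state.filaments[arm.filament]
    if arm.node == f.barbed_index:
        return EventOutcome(BARBED_ARREST, lid, ai, arm.filament, arm.node,
                            state.time)
    target = arm.node + f.toward_barbed
    occ = occupancy_map(state)
    if (arm.filament, target) in occ:
        return EventOutcome(BLOCK, lid, ai, arm.filament, arm.node,
                            state.time)
    arm.node = target
    return EventOutcome(WALK, lid, ai, arm.filament, target, state.time)


def attempt_unbind(state: NetworkState, arm_ref: tuple[int, int], p,
                   rng: np.random.Generator, dt_kinetic: float | None = None
                   ) -> EventOutcome | None:
    """One unbinding attempt of an attached arm; mutates the state."""
    lid, ai = arm_ref
    lk = state.linkers[lid]
    arm = lk.arms[ai]
    if not arm.attached:
        raise ValueError("arm is not attached")
    if dt_kinetic is None:
        dt_kinetic = p.dt * p.n_kinetic
    tension, _ = _arm_tension(state, p, lid, ai)
    k = float(unbind_rate(tension, lk.kind, p))
    if rng.random() >= 1.0 - np.exp(-k * dt_kinetic):
        return None
    ev = EventOutcome(UNBIND, lid, ai, arm.filament, arm.node, state.time)
    arm.filament = None
    arm.node = None
    if lk.state == ACTIVE:
        lk.state = INACTIVE
    else:
        pool = state.free_M if lk.kind == KIND_MOTOR else state.free_ACP
        pool[state.voxel_of(lk.bp[ai])] += 1
        del state.linkers[lid]
    return ev


def _wrapped(state: NetworkState, x: np.ndarray) -> np.ndarray:
    """Positions wrapped into the periodic box (no-op for clamped domains)."""
    if not state.domain.periodic.any():
        return x
    lo = state.domain.face_pos[0::2]
    w = state.domain.widths()
    return lo + np.mod(x - lo, w)


def attempt_bind(state: NetworkState, p, rng: np.random.Generator,
                 dt_kinetic: float | None = None,
                 next_id: int | None = None) -> list[EventOutcome]:
    """Binding attempts for one kinetics window; mutates the state."""
    if dt_kinetic is None:
        dt_kinetic = p.dt * p.n_kinetic
    ip = p.internal()
    events: list[EventOutcome] = []
    if next_id is None:
        next_id = max(state.linkers, default=-1) + 1

    # gather node geometry and occupancy
    fids, nidx, xyz = [], [], []
    for fid, f in state.filaments.items():
        fids.extend([fid] * f.n_nodes)
        nidx.extend(range(f.n_nodes))
        xyz.append(f.nodes)
    if not fids:
        return events
    fids = np.array(fids)
    nidx = np.array(nidx)
    xyz = _wrapped(state, np.concatenate(xyz))
    occ = occupancy_map(state)
    occupied = np.array([(f, n) in occ for f, n in zip(fids, nidx)])
    voxel = np.array([state.voxel_of(x) for x in xyz])
    n_vox = state.free_ACP.shape[0]
    v_vox = state.domain.volume_nm3() / n_vox

    def free_site_candidates(vox):
        sel = (~occupied) & (voxel == vox)
        return np.nonzero(sel)[0]

    # ---- first-arm binding, per voxel ---------------------------------
    for kind, pool, k2 in ((KIND_ACP, state.free_ACP, ip.kbind_ACP),
                           (KIND_MOTOR, state.free_M, ip.kbind_M)):
        r0 = ip.r0_M if kind == KIND_MOTOR else ip.r0_ACP
        for vox in range(n_vox):
            nfree = int(pool[vox])
            if nfree == 0:
                continue
            cands = free_site_candidates(vox)
            if len(cands) == 0:
                continue
            rate = k2 * (nfree / v_vox) * len(cands)
            n_ev = min(rng.poisson(rate * dt_kinetic), nfree, len(cands))
            for _ in range(n_ev):
                cands = free_site_candidates(vox)
                if len(cands) == 0:
                    break
                i = int(rng.choice(cands))
                fid, node = int(fids[i]), int(nidx[i])
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                node_xyz = state.filaments[fid].nodes[node]
                bp0 = node_xyz + r0 * u          # arm born at rest
                lk = Linker(kind, INACTIVE,
                            [Arm(fid, node), Arm()],
                            np.vstack([bp0, bp0.copy()]))
                state.linkers[next_id] = lk
                occ[(fid, node)] = (next_id, 0)
                occupied[i] = True
                pool[vox] -= 1
                events.append(EventOutcome(BIND, next_id, 0, fid, node,
                                           state.time))
                next_id += 1

    # ---- second-arm binding (INACTIVE -> ACTIVE) ----------------------
    lo = state.domain.face_pos[0::2]
    w = state.domain.widths()
    for lid in list(state.linkers):
        lk = state.linkers[lid]
        if lk.state != INACTIVE:
            continue
        bound_ai = 0 if lk.arms[0].attached else 1
        other_ai = 1 - bound_ai
        arm0 = lk.arms[bound_ai]
        x0 = _wrapped(state, state.filaments[arm0.filament]
                      .nodes[arm0.node][None])[0]
        r0 = ip.r0_M if lk.kind == KIND_MOTOR else ip.r0_ACP
        k2 = ip.kbind_M if lk.kind == KIND_MOTOR else ip.kbind_ACP
        # capture reach: the linker span, but never below one binding-site
        # spacing (the nearest nodes straddle a filament crossing)
        reach = max(2 * r0 * (1 + p.bind_capture_tol), ip.r0_A)
        d = xyz - x0
        if state.domain.periodic.any():
            d -= np.round(d / w) * w
        dist = np.linalg.norm(d, axis=1)
        ok = ~occupied & (fids != arm0.filament) & (dist <= reach) & (dist > 0)
        idx = np.nonzero(ok)[0]
        if len(idx) == 0:
            continue
        # local second-order law: candidate sites at their in-shell density
        rate = k2 * len(idx) / (4.0 / 3.0 * np.pi * reach ** 3)
        if rng.random() >= 1.0 - np.exp(-rate * dt_kinetic):
            continue
        i = int(rng.choice(idx))
        fid, node = int(fids[i]), int(nidx[i])
        lk.arms[other_ai] = Arm(fid, node)
        node_xyz = state.filaments[fid].nodes[node]
        x0 = state.filaments[arm0.filament].nodes[arm0.node]
        span_now = np.linalg.norm(node_xyz - x0)
        dhat = ((node_xyz - x0) / span_now if span_now > 0
                else np.array([1.0, 0.0, 0.0]))
        lk.bp[bound_ai] = x0 + dhat * r0
        lk.bp[other_ai] = node_xyz - dhat * r0
        lk.backbone_r0 = float(np.linalg.norm(lk.bp[other_ai]
                                              - lk.bp[bound_ai]))
        lk.state = ACTIVE
        occ[(fid, node)] = (lid, other_ai)
        occupied[i] = True
        events.append(EventOutcome(BIND, lid, other_ai, fid, node,
                                   state.time))
    return events


# ---------------------------------------------------------------------------
# vectorized per-window kinetics for the production run loop
# ---------------------------------------------------------------------------

class KineticsEngine:
    """Vectorized kinetics working directly on an :class:`Engine`.

    Fast events (force-dependent unbinding and walking of ACTIVE linker
    arms) run every kinetics window on flat per-arm tables; slow chemistry
    (zero-force unbinding of INACTIVE linkers, first- and second-arm
    binding) runs on the coarser binding stride.  Only INACTIVE -> ACTIVE
    transitions change the mechanics topology and trigger array rebuilds;
    ACTIVE -> INACTIVE transitions are silenced in place.
    """

    def __init__(self, engine: Engine, p):
        self.en = engine
        self.p = p
        self.ip = p.internal()
        self.events: list[EventOutcome] = []
        self.counts = dict.fromkeys(
            (WALK, BLOCK, UNBIND, BIND, BARBED_ARREST), 0)
        self.rebuild()

    # ---------------------------------------------------------------- table
    def rebuild(self) -> None:
        en, st = self.en, self.en.state
        self.occ = np.full(en.n_fil_nodes, -1, np.int64)
        rows = []
        for lid, lk in st.linkers.items():
            for ai, arm in enumerate(lk.arms):
                if arm.attached:
                    self.occ[en.gidx(arm.filament, arm.node)] = lid
        for lid in en.lk_ids:                 # ACTIVE linkers only
            lk = st.linkers[lid]
            for ai, arm in enumerate(lk.arms):
                rows.append((lid, ai, 1 if lk.kind == KIND_MOTOR else 0,
                             arm.filament, arm.node))
        n = len(rows)
        self.lid = np.array([r[0] for r in rows], np.int64)
        self.ai = np.array([r[1] for r in rows], np.int64)
        self.is_motor = np.array([r[2] for r in rows], bool)
        self.fil = np.array([r[3] for r in rows], np.int64)
        self.node = np.array([r[4] for r in rows], np.int64)
        self.node_g = np.empty(n, np.int64)
        self.bp_g = np.empty(n, np.int64)
        self.pt_a = np.empty(n, np.int64)     # tangent toward pointed: a - b
        self.pt_b = np.empty(n, np.int64)
        self.barbed = np.empty(n, bool)
        self.tb = np.empty(n, np.int64)
        for r in range(n):
            fid, node = int(self.fil[r]), int(self.node[r])
            self.node_g[r] = en.gidx(fid, node)
            self.bp_g[r] = en.bp_gidx(int(self.lid[r]), int(self.ai[r]))
            self._set_geom(r, fid, node)
        self.alive = np.ones(n, bool)
        # global-node-index -> (filament id, local node) lookup
        gid_fil = np.empty(en.n_fil_nodes, np.int64)
        gid_node = np.empty(en.n_fil_nodes, np.int64)
        for fid in en.fil_ids:
            o = en.fil_offset[fid]
            nn = st.filaments[fid].n_nodes
            gid_fil[o:o + nn] = fid
            gid_node[o:o + nn] = np.arange(nn)
        self._gid_fil, self._gid_node = gid_fil, gid_node

    def _set_geom(self, r: int, fid: int, node: int) -> None:
        f = self.en.state.filaments[fid]
        tb = f.toward_barbed
        self.tb[r] = tb
        self.barbed[r] = (node == f.barbed_index)
        if 0 <= node - tb < f.n_nodes:
            self.pt_a[r] = self.en.gidx(fid, node - tb)
            self.pt_b[r] = self.en.gidx(fid, node)
        else:
            self.pt_a[r] = self.en.gidx(fid, node)
            self.pt_b[r] = self.en.gidx(fid, node + tb)

    # ------------------------------------------------------------- tensions
    def _tensions(self):
        en, ip = self.en, self.ip
        d = en.pos[self.bp_g] - en.pos[self.node_g]
        r = np.linalg.norm(d, axis=1)
        r0 = np.where(self.is_motor, ip.r0_M, ip.r0_ACP)
        ks = np.where(self.is_motor, ip.ks_M, ip.ks_ACP)
        tension = ks * np.maximum(r - r0, 0.0)
        tvec = en.pos[self.pt_a] - en.pos[self.pt_b]
        tn = np.linalg.norm(tvec, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ij->i", d, tvec) / (r * tn)
        cosang = np.nan_to_num(cosang)
        f_par = np.maximum(tension * cosang, 0.0)
        return tension, f_par

    # ---------------------------------------------------------------- window
    def window(self, rng: np.random.Generator, do_bind: bool = True,
               dt_bind: float | None = None) -> bool:
        """Run one kinetics window.

        Fast events run over dt_kinetic; slow chemistry only when
        ``do_bind``, over the accumulated ``dt_bind``.  Returns True if the
        mechanics arrays were rebuilt."""
        p, en = self.p, self.en
        st = en.state
        dtk = p.dt * p.n_kinetic
        t = st.time
        need_rebuild = False

        if len(self.lid):
            tension, f_par = self._tensions()

            # --- force-dependent unbinding of ACTIVE arms -----------------
            k0 = np.where(self.is_motor, p.k0_u_M, p.k0_u_ACP)
            lam = np.where(self.is_motor, p.lambda_u_M, p.lambda_u_ACP)
            ku = k0 * np.exp(lam * tension / p.kBT_pNnm)
            fire = (rng.random(len(ku)) < 1.0 - np.exp(-ku * dtk)) \
                & self.alive
            for r in rng.permutation(np.nonzero(fire)[0]):
                r = int(r)
                if not self.alive[r]:
                    continue
                lid, ai = int(self.lid[r]), int(self.ai[r])
                lk = st.linkers[lid]
                arm = lk.arms[ai]
                self.occ[self.node_g[r]] = -1
                self.events.append(EventOutcome(
                    UNBIND, lid, ai, arm.filament, arm.node, t))
                self.counts[UNBIND] += 1
                arm.filament = None
                arm.node = None
                lk.state = INACTIVE
                # demote: the remaining arm leaves the mechanics arrays and
                # re-joins through the slow-chemistry channel
                other = lk.arms[1 - ai]
                x = en.pos[en.gidx(other.filament, other.node)]
                u = en.pos[en.bp_gidx(lid, 1 - ai)] - x
                nu = np.linalg.norm(u)
                r0 = self.ip.r0_M if lk.kind == KIND_MOTOR else self.ip.r0_ACP
                dhat = (u / nu if nu > 0 else np.array([1.0, 0.0, 0.0]))
                lk.bp[1 - ai] = x + dhat * r0
                lk.bp[ai] = lk.bp[1 - ai].copy()
                lk.backbone_r0 = 0.0
                en.patch_deactivate(lid)
                self.alive[r] = False
                ro = np.nonzero((self.lid == lid) & (self.ai == 1 - ai))[0]
                if len(ro):
                    self.alive[int(ro[0])] = False

            # --- walking ---------------------------------------------------
            motor_rows = np.nonzero(self.is_motor & self.alive)[0]
            if len(motor_rows):
                kw = np.asarray(walk_rate(f_par[motor_rows], p))
                wfire = rng.random(len(motor_rows)) < 1.0 - np.exp(-kw * dtk)
                for r in rng.permutation(motor_rows[wfire]):
                    r = int(r)
                    if not self.alive[r]:
                        continue
                    lid, ai = int(self.lid[r]), int(self.ai[r])
                    fid, node = int(self.fil[r]), int(self.node[r])
                    if self.barbed[r]:
                        self.events.append(EventOutcome(
                            BARBED_ARREST, lid, ai, fid, node, t))
                        self.counts[BARBED_ARREST] += 1
                        continue
                    target = node + int(self.tb[r])
                    tg = en.gidx(fid, target)
                    if self.occ[tg] >= 0:
                        self.events.append(EventOutcome(
                            BLOCK, lid, ai, fid, node, t))
                        self.counts[BLOCK] += 1
                        continue
                    self.occ[self.node_g[r]] = -1
                    self.occ[tg] = lid
                    en.patch_walk(lid, ai, target)
                    self.node[r] = target
                    self.node_g[r] = tg
                    self._set_geom(r, fid, target)
                    self.events.append(EventOutcome(
                        WALK, lid, ai, fid, target, t))
                    self.counts[WALK] += 1

        # --- slow chemistry ------------------------------------------------
        if do_bind and self._chemistry(rng, dt_bind or dtk, t):
            need_rebuild = True
        if need_rebuild:
            en.sync_to_state()
            en.rebuild()
            self.rebuild()
        return need_rebuild

    # ------------------------------------------------------------ chemistry
    def _chemistry(self, rng, dtk: float, t: float) -> bool:
        """Zero-force INACTIVE unbinding, first- and second-arm binding.
        Returns True when an INACTIVE linker became ACTIVE."""
        p, ip, en = self.p, self.ip, self.en
        st = en.state
        n_vox = st.free_ACP.shape[0]
        v_vox = st.domain.volume_nm3() / n_vox
        pos_nodes = en.pos[:en.n_fil_nodes]
        lo = st.domain.face_pos[0::2]
        w = st.domain.widths()
        nvx = round(n_vox ** (1 / 3))
        ijk = np.clip(((pos_nodes - lo) / w * nvx).astype(int), 0, nvx - 1)
        voxel = (ijk[:, 0] * nvx + ijk[:, 1]) * nvx + ijk[:, 2]
        unocc = self.occ < 0
        activated = False
        next_id = max(st.linkers, default=-1) + 1

        # --- zero-force unbinding of INACTIVE linkers ----------------------
        inact = [(lid, lk) for lid, lk in st.linkers.items()
                 if lk.state == INACTIVE]
        for lid, lk in inact:
            k0 = p.k0_u_M if lk.kind == KIND_MOTOR else p.k0_u_ACP
            if rng.random() >= 1.0 - np.exp(-k0 * dtk):
                continue
            ai = 0 if lk.arms[0].attached else 1
            arm = lk.arms[ai]
            g = en.gidx(arm.filament, arm.node)
            self.occ[g] = -1
            unocc[g] = True
            self.events.append(EventOutcome(
                UNBIND, lid, ai, arm.filament, arm.node, t))
            self.counts[UNBIND] += 1
            pool = st.free_M if lk.kind == KIND_MOTOR else st.free_ACP
            pool[st.voxel_of(pos_nodes[g])] += 1
            del st.linkers[lid]

        # --- first-arm binding (implicit pool -> INACTIVE) -----------------
        for kind, pool, k2 in ((KIND_ACP, st.free_ACP, ip.kbind_ACP),
                               (KIND_MOTOR, st.free_M, ip.kbind_M)):
            r0 = ip.r0_M if kind == KIND_MOTOR else ip.r0_ACP
            sites_per_vox = np.bincount(voxel[unocc], minlength=n_vox)
            rates = k2 * (pool / v_vox) * sites_per_vox
            nev = rng.poisson(rates * dtk)
            for vox in np.nonzero(nev)[0]:
                for _ in range(int(min(nev[vox], pool[vox]))):
                    cand = np.nonzero(unocc & (voxel == vox))[0]
                    if len(cand) == 0:
                        break
                    g = int(rng.choice(cand))
                    fid, node = int(self._gid_fil[g]), int(self._gid_node[g])
                    u = rng.normal(size=3)
                    u /= np.linalg.norm(u)
                    bp0 = pos_nodes[g] + r0 * u
                    st.linkers[next_id] = Linker(
                        kind, INACTIVE, [Arm(fid, node), Arm()],
                        np.vstack([bp0, bp0.copy()]))
                    pool[vox] -= 1
                    unocc[g] = False
                    self.occ[g] = next_id
                    self.events.append(EventOutcome(BIND, next_id, 0,
                                                    fid, node, t))
                    self.counts[BIND] += 1
                    next_id += 1

        # --- second-arm binding (INACTIVE -> ACTIVE), local law ------------
        inact = [(lid, lk) for lid, lk in st.linkers.items()
                 if lk.state == INACTIVE]
        if inact:
            from scipy.spatial import cKDTree
            tree = cKDTree(pos_nodes)
            reach_M = max(2 * ip.r0_M * (1 + p.bind_capture_tol), ip.r0_A)
            reach_A = max(2 * ip.r0_ACP * (1 + p.bind_capture_tol), ip.r0_A)
            g0s = np.array([en.gidx(lk.arms[0 if lk.arms[0].attached else 1]
                                    .filament,
                                    lk.arms[0 if lk.arms[0].attached else 1]
                                    .node)
                            for _, lk in inact])
            balls = tree.query_ball_point(pos_nodes[g0s],
                                          max(reach_M, reach_A))
            order = rng.permutation(len(inact))
            for k in order:
                lid, lk = inact[int(k)]
                if lid not in st.linkers:
                    continue
                bound_ai = 0 if lk.arms[0].attached else 1
                arm0 = lk.arms[bound_ai]
                g0 = int(g0s[k])
                r0 = ip.r0_M if lk.kind == KIND_MOTOR else ip.r0_ACP
                reach = reach_M if lk.kind == KIND_MOTOR else reach_A
                cand = [g for g in balls[k]
                        if unocc[g] and self._gid_fil[g] != arm0.filament
                        and g != g0]
                if lk.kind != KIND_MOTOR:
                    cand = [g for g in cand
                            if np.linalg.norm(pos_nodes[g]
                                              - pos_nodes[g0]) <= reach]
                if not cand:
                    continue
                rate = (ip.kbind_M if lk.kind == KIND_MOTOR else ip.kbind_ACP)
                rate *= len(cand) / (4.0 / 3.0 * np.pi * reach ** 3)
                if rng.random() >= 1.0 - np.exp(-rate * dtk):
                    continue
                g = int(rng.choice(np.array(cand)))
                fid, node = int(self._gid_fil[g]), int(self._gid_node[g])
                other_ai = 1 - bound_ai
                lk.arms[other_ai] = Arm(fid, node)
                x0 = pos_nodes[g0]
                x1 = pos_nodes[g]
                span = np.linalg.norm(x1 - x0)
                dhat = ((x1 - x0) / span if span > 0
                        else np.array([1.0, 0.0, 0.0]))
                lk.bp[bound_ai] = x0 + dhat * r0
                lk.bp[other_ai] = x1 - dhat * r0
                lk.backbone_r0 = float(np.linalg.norm(lk.bp[other_ai]
                                                      - lk.bp[bound_ai]))
                lk.state = ACTIVE
                unocc[g] = False
                self.occ[g] = lid
                self.events.append(EventOutcome(BIND, lid, other_ai, fid,
                                                node, t))
                self.counts[BIND] += 1
                activated = True
        return activated
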