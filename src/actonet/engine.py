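"""Compiled simulation state: flat arrays + incremental topology updates.

The :class:`Engine` flattens a :class:`~actonet.network.NetworkState` into
the arrays consumed by :mod:`actonet._kernels` and keeps the two in sync:

* positions live in ``Engine.pos`` during a run (``sync_to_state`` writes
  them back into the network objects);
* motor walking patches spring/hinge indices in place;
* binding/unbinding events trigger a full topology rebuild (they are rare
  on the kinetics-window timescale);
* the excluded-volume candidate pair list is refreshed whenever any point
  has moved farther than half the Verlet skin since the last build.
"""

from __future__ import annotations

import numpy as np

from . import _kernels as K
from .network import ACTIVE, KIND_MOTOR, NetworkState

PAIR_SKIN = 3.0  # Verlet skin in units of r_c


class InstabilityError(RuntimeError):
    """Deterministic per-step displacement exceeded 0.1 r_c."""


class Engine:
    def __init__(self, state: NetworkState, p, noise: bool = True,
                 det_limit_frac: float = 0.1):
        """``det_limit_frac``: instability detector threshold, as a fraction
        of r_c, on the deterministic per-step displacement.  Production runs
        use a looser 0.5 (a steady multi-motor tension legitimately moves a
        bead more than 0.1 r_c per step at the production dt; that is
        overdamped drift, not instability)."""
        self.state = state
        self.p = p
        self.ip = p.internal()
        self.noise = noise
        self.det_limit_frac = det_limit_frac
        self.rebuild()

    # ------------------------------------------------------------------
    # topology compilation
    # ------------------------------------------------------------------
    def rebuild(self) -> None:
        st, ip = self.state, self.ip
        self.fil_ids = sorted(st.filaments)
        self.fil_offset: dict[int, int] = {}
        off = 0
        for fid in self.fil_ids:
            self.fil_offset[fid] = off
            off += st.filaments[fid].n_nodes
        self.n_fil_nodes = off
        # only ACTIVE linkers are materialized as beads: a singly-bound
        # linker transmits no force (its dangling arm merely diffuses), so
        # INACTIVE linkers live as occupancy bookkeeping + stored geometry
        self.lk_ids = sorted(lid for lid, lk in st.linkers.items()
                             if lk.state == ACTIVE)
        self.lk_offset = {lid: off + 2 * n
                          for n, lid in enumerate(self.lk_ids)}
        self.tether_offset = off + 2 * len(self.lk_ids)
        N = self.tether_offset + len(st.tethers)

        pos = np.empty((N, 3))
        for fid in self.fil_ids:
            o = self.fil_offset[fid]
            f = st.filaments[fid]
            pos[o:o + f.n_nodes] = f.nodes
        for lid in self.lk_ids:
            o = self.lk_offset[lid]
            pos[o:o + 2] = st.linkers[lid].bp
        for n, th in enumerate(st.tethers):
            pos[self.tether_offset + n] = th.anchor
        self.pos = pos
        self.F = np.zeros_like(pos)

        # ---- bonds ----------------------------------------------------
        b_i, b_j, b_k, b_r0 = [], [], [], []
        self.arm_bond_slot: dict[tuple[int, int], int] = {}
        self.arm_angle_slot: dict[tuple[int, int], int] = {}
        self.lk_backbone_slot: dict[int, int] = {}
        self._frozen: list[int] = []
        for fid in self.fil_ids:
            o = self.fil_offset[fid]
            f = st.filaments[fid]
            for i in range(f.n_nodes - 1):
                b_i.append(o + i)
                b_j.append(o + i + 1)
                b_k.append(ip.ks_A)
                b_r0.append(ip.r0_A if f.seg_r0 is None
                            else float(f.seg_r0[i]))
        for n, th in enumerate(st.tethers):
            b_i.append(self.gidx(th.filament, th.node))
            b_j.append(self.tether_offset + n)
            b_k.append(th.k_pN_per_nm)
            b_r0.append(th.r0)
        a_i, a_j, a_k, a_l, a_kap, a_t0 = [], [], [], [], [], []
        for fid in self.fil_ids:
            o = self.fil_offset[fid]
            n = st.filaments[fid].n_nodes
            for i in range(1, n - 1):
                a_i.append(o + i)       # u = prev - cur
                a_j.append(o + i - 1)
                a_k.append(o + i)       # v = next - cur
                a_l.append(o + i + 1)
                a_kap.append(ip.kb_A)
                a_t0.append(np.pi)

        for lid in self.lk_ids:
            lk = st.linkers[lid]
            o = self.lk_offset[lid]
            ks = ip.ks_ACP if lk.kind != KIND_MOTOR else ip.ks_M
            r0 = ip.r0_ACP if lk.kind != KIND_MOTOR else ip.r0_M
            kb1 = ip.kb_ACP1 if lk.kind != KIND_MOTOR else ip.kb_M1
            kb2 = ip.kb_ACP2 if lk.kind != KIND_MOTOR else ip.kb_M2
            # backbone bond joining the two arm roots; the linker body is
            # rigid relative to its arms (minifilament backbone)
            self.lk_backbone_slot[lid] = len(b_i)
            b_i.append(o)
            b_j.append(o + 1)
            b_k.append(ip.ks_ACP)
            b_r0.append(lk.backbone_r0)
            for ai, arm in enumerate(lk.arms):
                if not arm.attached:
                    continue
                ng = self.gidx(arm.filament, arm.node)
                self.arm_bond_slot[(lid, ai)] = len(b_i)
                b_i.append(ng)
                b_j.append(o + ai)
                b_k.append(ks)
                b_r0.append(r0)
                # right angle between the arm and the local filament axis
                nb = self._tangent_neighbor(arm.filament, arm.node)
                self.arm_angle_slot[(lid, ai)] = len(a_i)
                a_i.append(ng)
                a_j.append(o + ai)
                a_k.append(ng)
                a_l.append(nb)
                a_kap.append(kb2)
                a_t0.append(np.pi / 2.0)
            if lk.state == ACTIVE:
                g0 = self.gidx(lk.arms[0].filament, lk.arms[0].node)
                g1 = self.gidx(lk.arms[1].filament, lk.arms[1].node)
                self.arm_angle_slot[(lid, -1)] = len(a_i)
                a_i.append(g0)          # u = bp0 - node0
                a_j.append(o)
                a_k.append(o + 1)       # v = node1 - bp1
                a_l.append(g1)
                a_kap.append(kb1)
                a_t0.append(0.0)

        self.b_i = np.array(b_i, np.int64)
        self.b_j = np.array(b_j, np.int64)
        self.b_k = np.array(b_k, float)
        self.b_r0 = np.array(b_r0, float)
        self.a_i = np.array(a_i, np.int64)
        self.a_j = np.array(a_j, np.int64)
        self.a_k = np.array(a_k, np.int64)
        self.a_l = np.array(a_l, np.int64)
        self.a_kap = np.array(a_kap, float)
        self.a_t0 = np.array(a_t0, float)

        # ---- actin segments (for excluded volume) ---------------------
        seg_a, seg_b, seg_fil, seg_sid = [], [], [], []
        for fi, fid in enumerate(self.fil_ids):
            o = self.fil_offset[fid]
            n = st.filaments[fid].n_nodes
            for i in range(n - 1):
                seg_a.append(o + i)
                seg_b.append(o + i + 1)
                seg_fil.append(fi)
                seg_sid.append(i)
        self.seg_a = np.array(seg_a, np.int64)
        self.seg_b = np.array(seg_b, np.int64)
        self.seg_fil = np.array(seg_fil, np.int64)
        self.seg_sid = np.array(seg_sid, np.int64)

        # ---- clamps / anchors -----------------------------------------
        self.free_mask = np.ones(N)
        self._rebuild_anchors()
        self._pair_ref = None
        self._refresh_pairs()

    def _tangent_neighbor(self, fid: int, node: int) -> int:
        f = self.state.filaments[fid]
        nb = node + 1 if node + 1 < f.n_nodes else node - 1
        return self.fil_offset[fid] + nb

    def gidx(self, fid: int, node: int) -> int:
        return self.fil_offset[fid] + node

    def bp_gidx(self, lid: int, which: int) -> int:
        return self.lk_offset[lid] + which

    # ------------------------------------------------------------------
    def _rebuild_anchors(self) -> None:
        st = self.state
        idx, face, axis, sign = [], [], [], []
        self.free_mask[:] = 1.0
        self.free_mask[self.tether_offset:] = 0.0   # tether anchors are fixed
        if self._frozen:
            self.free_mask[self._frozen] = 0.0      # orphaned backbone points
        for (fid, end), fc in st.domain.clamps.items():
            f = st.filaments[fid]
            g = self.gidx(fid, 0 if end == 0 else f.n_nodes - 1)
            self.free_mask[g] = 0.0
            idx.append(g)
            face.append(fc)
            axis.append(fc // 2)
            sign.append(1.0 if fc % 2 == 0 else -1.0)  # inward normal
        self.anchor_idx = np.array(idx, np.int64)
        self.anchor_face = np.array(face, np.int64)
        self.anchor_axis = np.array(axis, np.int64)
        self.anchor_sign = np.array(sign, float)

    def clamp_node(self, fid: int, end: int, face: int) -> None:
        """Register a permanent clamp and project the node onto the face."""
        st = self.state
        f = st.filaments[fid]
        if (fid, end) in st.domain.clamps:
            return
        st.domain.clamps[(fid, end)] = face
        f.clamped[end] = True
        g = self.gidx(fid, 0 if end == 0 else f.n_nodes - 1)
        self.pos[g, face // 2] = st.domain.face_pos[face]
        self._rebuild_anchors()

    # ------------------------------------------------------------------
    # excluded-volume pair list
    # ------------------------------------------------------------------
    def _refresh_pairs(self) -> None:
        ip = self.ip
        cutoff = ip.rc * (1.0 + PAIR_SKIN)
        cap = max(64, 40 * len(self.seg_a))
        while True:
            p1, p2, cnt = K.build_pairs_celllist(
                self.pos, self.seg_a, self.seg_b, self.seg_fil,
                self.seg_sid, cutoff, cap)
            if cnt <= cap:
                break
            cap = 2 * cnt
        self.pair_s1 = p1[:cnt].copy()
        self.pair_s2 = p2[:cnt].copy()
        self._pair_ref = self.pos.copy()

    def _maybe_refresh_pairs(self) -> None:
        moved = K.max_displacement(self.pos, self._pair_ref, self.free_mask)
        if moved > 0.5 * PAIR_SKIN * self.ip.rc:
            self._refresh_pairs()

    # ------------------------------------------------------------------
    # event patches
    # ------------------------------------------------------------------
    def patch_walk(self, lid: int, ai: int, new_node: int) -> None:
        """Relocate an attached arm to ``new_node`` on the same filament."""
        lk = self.state.linkers[lid]
        arm = lk.arms[ai]
        fid = arm.filament
        arm.node = new_node
        ng = self.gidx(fid, new_node)
        s = self.arm_bond_slot[(lid, ai)]
        self.b_i[s] = ng
        a = self.arm_angle_slot[(lid, ai)]
        self.a_i[a] = ng
        self.a_k[a] = ng
        self.a_l[a] = self._tangent_neighbor(fid, new_node)
        pa = self.arm_angle_slot.get((lid, -1))
        if pa is not None:
            if ai == 0:
                self.a_i[pa] = ng
            else:
                self.a_l[pa] = ng

    def patch_deactivate(self, lid: int) -> None:
        """Silence all force terms of a linker in place (no array rebuild):
        used when an ACTIVE linker loses an arm.  Its backbone beads are
        frozen until the next topology rebuild reclaims the slots."""
        for key in ((lid, 0), (lid, 1), (lid, -1)):
            s = self.arm_bond_slot.pop(key, None)
            if s is not None:
                self.b_k[s] = 0.0
            a = self.arm_angle_slot.pop(key, None)
            if a is not None:
                self.a_kap[a] = 0.0
        bs = self.lk_backbone_slot.pop(lid, None)
        if bs is not None:
            self.b_k[bs] = 0.0
        o = self.lk_offset.get(lid)
        if o is not None:
            self.free_mask[o:o + 2] = 0.0
            self._frozen.extend([o, o + 1])

    # ------------------------------------------------------------------
    # stepping
    # ------------------------------------------------------------------
    def window(self, nsteps: int, seed: int):
        """Integrate ``nsteps`` steps; returns (stress_force pN (6,),
        energies pN*nm (3,)).  Raises :class:`InstabilityError`."""
        ip = self.ip
        stress_force = np.zeros(6)
        energies = np.zeros(3)
        status = K.run_window(
            self.pos, self.F,
            self.b_i, self.b_j, self.b_k, self.b_r0,
            self.a_i, self.a_j, self.a_k, self.a_l, self.a_kap, self.a_t0,
            self.pair_s1, self.pair_s2, self.seg_a, self.seg_b,
            ip.kr, ip.rc,
            self.free_mask, self.anchor_idx, self.anchor_sign,
            self.anchor_axis, self.anchor_face,
            ip.zeta, ip.kBT, ip.dt, nsteps,
            self.noise, seed & 0x7FFFFFFF, self.det_limit_frac * ip.rc,
            stress_force, energies)
        if status != K.STATUS_OK:
            raise InstabilityError(
                "deterministic displacement exceeded 0.1 r_c per step "
                f"at t={self.state.time:.4f} s")
        self.state.time += nsteps * ip.dt
        self._maybe_refresh_pairs()
        return stress_force, energies

    def compute_forces(self):
        """One force evaluation on the current positions (no motion).

        Returns (F (N,3) pN, energies (extension, bending, repulsion) pN*nm).
        """
        self.F[:] = 0.0
        e_ext = K.bond_forces(self.pos, self.b_i, self.b_j, self.b_k,
                              self.b_r0, self.F)
        if np.isnan(e_ext):
            raise ZeroDivisionError("zero-length bond with finite rest length")
        e_bend = K.angle_forces(self.pos, self.a_i, self.a_j, self.a_k,
                                self.a_l, self.a_kap, self.a_t0, self.F)
        e_rep = K.repulsion_forces(self.pos, self.pair_s1, self.pair_s2,
                                   self.seg_a, self.seg_b, self.ip.kr,
                                   self.ip.rc, self.F)
        return self.F.copy(), np.array([e_ext, e_bend, e_rep])

    # ------------------------------------------------------------------
    def move_face(self, face: int, new_pos: float) -> None:
        """Translate a face and its clamped anchors rigidly."""
        st = self.state
        delta = new_pos - st.domain.face_pos[face]
        if delta == 0.0:
            return
        st.domain.face_pos[face] = new_pos
        axis = face // 2
        sel = self.anchor_face == face
        self.pos[self.anchor_idx[sel], axis] += delta

    def sync_to_state(self) -> NetworkState:
        st = self.state
        for fid in self.fil_ids:
            o = self.fil_offset[fid]
            f = st.filaments[fid]
            f.nodes[:] = self.pos[o:o + f.n_nodes]
        for lid in self.lk_ids:
            lk = st.linkers.get(lid)
            if lk is None or lk.state != ACTIVE:
                continue  # demoted or unbound since the last build; the
                # stored resting geometry is authoritative for those
            o = self.lk_offset[lid]
            lk.bp[:] = self.pos[o:o + 2]
        return st
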