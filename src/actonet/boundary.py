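"""Elastic-boundary coupling: clamped domain construction, wall stress,
quasi-static substrate motion, and the oscillatory stiffness probe.

The periodic assembly box is converted into a clamped domain by severing
every filament at the face planes it crosses and permanently clamping the
cut ends there.  During a measurement run the six faces act as sticky
surfaces (any filament end within 30 nm is irreversibly clamped) and as an
elastic substrate: the normal stress sigma on a face (sum of the inward
normal forces on its anchors over the face area) displaces the face by a
distance corresponding to a strain sigma/E, referenced to the initial
width W0, with both faces of an axis moving symmetrically.
"""

from __future__ import annotations

import numpy as np

from .engine import Engine
from .network import Arm, DomainBoundary, Filament, NetworkState

_PA_PER_PN_NM2 = 1e6


class FaceCrossingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# periodic -> clamped conversion
# ---------------------------------------------------------------------------

def _wrap_count(x: np.ndarray, lo: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.floor((x - lo) / w).astype(np.int64)


def sever_and_clamp(state: NetworkState, p=None) -> NetworkState:
    """Cut filaments at the face planes, clamp the cut ends, deactivate
    periodicity.  Filament coordinates are expected unwrapped (continuous);
    each resulting piece is translated into the box by its image offset.

    Linker arms whose two attachments end up farther apart than a physical
    arm span (they bridged a periodic image) are detached.
    """
    st = state.copy()
    d = st.domain
    lo = d.face_pos[0::2].copy()
    w = d.widths().copy()

    new_fils: dict[int, Filament] = {}
    # (old fid, old node index) -> (new fid, new node index)
    remap: dict[tuple[int, int], tuple[int, int]] = {}
    clamps: dict[tuple[int, int], int] = {}
    nid = 0
    for fid in sorted(st.filaments):
        f = st.filaments[fid]
        nodes = f.nodes
        imgs = _wrap_count(nodes, lo, w)
        pieces: list[tuple[list[np.ndarray], list[int | None],
                           int | None, int | None]] = []
        cur_pts: list[np.ndarray] = [nodes[0]]
        cur_orig: list[int | None] = [0]
        start_face: int | None = None
        for i in range(1, len(nodes)):
            a, b = nodes[i - 1], nodes[i]
            # collect plane crossings of this segment, ordered along it
            crossings = []
            for ax in range(3):
                m0, m1 = imgs[i - 1, ax], imgs[i, ax]
                step = 1 if m1 > m0 else -1
                for m in range(m0, m1, step):
                    plane = lo[ax] + (m + (1 if step > 0 else 0)) * w[ax]
                    t = (plane - a[ax]) / (b[ax] - a[ax])
                    crossings.append((t, ax, step))
            for t, ax, step in sorted(crossings):
                cut = a + t * (b - a)
                cur_pts.append(cut)
                cur_orig.append(None)
                end_face = 2 * ax + (1 if step > 0 else 0)
                pieces.append((cur_pts, cur_orig, start_face, end_face))
                cur_pts = [cut.copy()]
                cur_orig = [None]
                start_face = 2 * ax + (0 if step > 0 else 1)
            cur_pts.append(b)
            cur_orig.append(i)
        pieces.append((cur_pts, cur_orig, start_face, None))

        for pts, orig, face0, face1 in pieces:
            if len(pts) < 2:
                continue
            arr = np.array(pts)
            # translate the piece into the box by its image offset; the
            # piece midpoint is strictly inside one image
            off = _wrap_count(arr.mean(axis=0)[None], lo, w)[0]
            arr = arr - off * w
            seg_r0 = np.full(len(arr) - 1, p.r0_A if p else 140.0)
            if orig[0] is None:
                seg_r0[0] = np.linalg.norm(arr[1] - arr[0])
            if orig[-1] is None:
                seg_r0[-1] = np.linalg.norm(arr[-1] - arr[-2])
            nf = Filament(arr, f.barbed_at_end, np.zeros(2, bool), seg_r0)
            new_fils[nid] = nf
            for k, oi in enumerate(orig):
                if oi is not None:
                    remap[(fid, oi)] = (nid, k)
            if face0 is not None:
                nf.clamped[0] = True
                nf.nodes[0, face0 // 2] = d.face_pos[face0]
                clamps[(nid, 0)] = face0
            if face1 is not None:
                nf.clamped[1] = True
                nf.nodes[-1, face1 // 2] = d.face_pos[face1]
                clamps[(nid, 1)] = face1
            nid += 1

    # remap linker attachments and rebuild backbone-point geometry in the
    # clamped coordinates; arms that bridged a periodic image (span much
    # larger than the physical linker span) are detached
    from .network import ACTIVE, INACTIVE, KIND_MOTOR
    for lid in list(st.linkers):
        lk = st.linkers[lid]
        r0 = (p.r0_M if p else 70.0) if lk.kind == KIND_MOTOR \
            else (p.r0_ACP if p else 35.0)
        for arm in lk.arms:
            if arm.attached:
                key = (arm.filament, arm.node)
                if key in remap:
                    arm.filament, arm.node = remap[key]
                else:            # node belonged to a dropped sliver piece
                    arm.filament = None
                    arm.node = None
        a0, a1 = lk.arms
        if a0.attached and a1.attached:
            x0 = new_fils[a0.filament].nodes[a0.node]
            x1 = new_fils[a1.filament].nodes[a1.node]
            span = np.linalg.norm(x1 - x0)
            if span > 6 * r0 or a0.filament == a1.filament:
                a1.filament = None
                a1.node = None
            else:
                dhat = ((x1 - x0) / span if span > 0
                        else np.array([1.0, 0.0, 0.0]))
                lk.bp[0] = x0 + dhat * r0
                lk.bp[1] = x1 - dhat * r0
                lk.backbone_r0 = float(np.linalg.norm(lk.bp[1] - lk.bp[0]))
        attached = [(ai, a) for ai, a in enumerate(lk.arms) if a.attached]
        if len(attached) == 2:
            lk.state = ACTIVE
        elif len(attached) == 1:
            ai, arm = attached[0]
            x = new_fils[arm.filament].nodes[arm.node]
            u = lk.bp[ai] - x
            nu = np.linalg.norm(u)
            dhat = u / nu if 0 < nu < 6 * r0 else np.array([1.0, 0.0, 0.0])
            lk.bp[ai] = x + dhat * r0
            lk.bp[1 - ai] = lk.bp[ai].copy()
            lk.backbone_r0 = 0.0
            lk.state = INACTIVE
        else:
            pool = st.free_M if lk.kind == KIND_MOTOR else st.free_ACP
            pool[st.voxel_of(np.clip(lk.bp[0], lo, lo + w - 1e-9))] += 1
            del st.linkers[lid]

    st.filaments = new_fils
    st.domain.clamps = clamps
    st.domain.periodic[:] = False
    return st


def sticky_capture(state: NetworkState, p) -> NetworkState:
    """Irreversibly clamp filament ends within the capture distance of a
    face; the anchor is the end's projection onto the face plane."""
    st = state
    d = st.domain
    for fid, f in st.filaments.items():
        for end, idx in ((0, 0), (1, f.n_nodes - 1)):
            if f.clamped[end]:
                continue
            x = f.nodes[idx]
            for face in range(6):
                axis = face // 2
                if abs(x[axis] - d.face_pos[face]) <= p.sticky_capture_nm:
                    # project onto the face; the end segment is re-rested at
                    # its new length so that capture injects no tension
                    x[axis] = d.face_pos[face]
                    if f.seg_r0 is None:
                        f.seg_r0 = np.full(f.n_segments, p.r0_A)
                    bond = 0 if end == 0 else f.n_segments - 1
                    nb = 1 if end == 0 else f.n_nodes - 2
                    f.seg_r0[bond] = np.linalg.norm(x - f.nodes[nb])
                    f.clamped[end] = True
                    d.clamps[(fid, end)] = face
                    break
    return st


def apply_sticky_capture(engine: Engine, p) -> int:
    """Engine-level sticky capture during a run; returns #new clamps."""
    st = engine.state
    d = st.domain
    n_new = 0
    for fid in engine.fil_ids:
        f = st.filaments[fid]
        for end, idx in ((0, 0), (1, f.n_nodes - 1)):
            if (fid, end) in d.clamps:
                continue
            g = engine.gidx(fid, idx)
            x = engine.pos[g]
            for face in range(6):
                axis = face // 2
                if abs(x[axis] - d.face_pos[face]) <= p.sticky_capture_nm:
                    engine.clamp_node(fid, end, face)
                    # re-rest the terminal bond at its post-projection length
                    nbg = engine.gidx(fid, 1 if end == 0 else f.n_nodes - 2)
                    bond_len = float(np.linalg.norm(engine.pos[g]
                                                    - engine.pos[nbg]))
                    slot = fid_bond_slot(engine, fid,
                                         0 if end == 0 else f.n_segments - 1)
                    engine.b_r0[slot] = bond_len
                    if f.seg_r0 is None:
                        f.seg_r0 = np.full(f.n_segments, p.r0_A)
                    f.seg_r0[0 if end == 0 else -1] = bond_len
                    n_new += 1
                    break
    return n_new


def fid_bond_slot(engine: Engine, fid: int, bond: int) -> int:
    """Index of a filament bond in the engine bond arrays (bonds are built
    filament-by-filament in id order, before linker/tether bonds)."""
    slot = 0
    for f in engine.fil_ids:
        if f == fid:
            return slot + bond
        slot += engine.state.filaments[f].n_segments
    raise KeyError(fid)


# ---------------------------------------------------------------------------
# wall stress and substrate motion
# ---------------------------------------------------------------------------

def face_stress(state: NetworkState, face: int, p,
                engine: Engine | None = None) -> float:
    """Instantaneous normal stress on a face, Pa (contractile positive)."""
    en = engine or Engine(state, p, noise=False)
    F, _ = en.compute_forces()
    sel = en.anchor_face == face
    total = float(np.sum(en.anchor_sign[sel]
                         * F[en.anchor_idx[sel], face // 2]))
    area = state.domain.face_area_nm2(face)
    return total / area * _PA_PER_PN_NM2


def stress_from_forces(engine: Engine, stress_force: np.ndarray) -> np.ndarray:
    """Convert per-face anchor force sums (pN) to stresses (Pa)."""
    d = engine.state.domain
    areas = np.array([d.face_area_nm2(f) for f in range(6)])
    return stress_force / areas * _PA_PER_PN_NM2


def face_targets(domain: DomainBoundary, sigma_Pa: np.ndarray) -> np.ndarray:
    """Quasi-static face positions for given per-face stresses.

    Each face's displacement from its reference position (+/- W0/2) equals
    (sigma/E) * (W0/2) along the inward normal; contractile (positive)
    stress moves the face inward.
    """
    half = domain.W0 / 2.0
    strain = sigma_Pa / domain.E
    tgt = np.empty(6)
    tgt[0::2] = -half + strain[0::2] * half
    tgt[1::2] = half - strain[1::2] * half
    return tgt


def update_faces(state: NetworkState, p, sigma_Pa: np.ndarray | None = None,
                 engine: Engine | None = None,
                 max_step_nm: float | None = None) -> NetworkState:
    """Move the six faces to their quasi-static sigma/E targets.

    ``sigma_Pa`` defaults to the instantaneous face stresses.  Anchors
    translate rigidly with their face.  Raises FaceCrossingError when
    opposing faces would meet.
    """
    en = engine or Engine(state, p, noise=False)
    if sigma_Pa is None:
        sigma_Pa = np.array([face_stress(state, f, p, en) for f in range(6)])
    tgt = face_targets(state.domain, sigma_Pa)
    cur = state.domain.face_pos
    if max_step_nm is not None:
        tgt = cur + np.clip(tgt - cur, -max_step_nm, max_step_nm)
    if np.any(tgt[1::2] - tgt[0::2] <= 0.05 * state.domain.W0):
        raise FaceCrossingError(
            f"opposing faces would cross: targets {tgt}")
    for face in range(6):
        en.move_face(face, tgt[face])
    en.sync_to_state()
    return state


# ---------------------------------------------------------------------------
# stiffness probe
# ---------------------------------------------------------------------------

def probe_stiffness(state: NetworkState, p, amplitude_nm: float = 280.0,
                    cycles: int = 3, freq_hz: float = 0.5,
                    axis: int = 0, fit_cycles: int = 2,
                    noise: bool = False) -> tuple[float, float]:
    """Oscillatory normal stiffness of the network, (E_n Pa, phase rad).

    With all motor and cross-linking kinetics frozen, the two faces of one
    axis are driven sinusoidally (differential displacement amplitude
    ``amplitude_nm``, i.e. each face moves by half) and the responding
    normal stress is recorded.  E_n is the ratio of the fitted stress and
    strain amplitudes over the last ``fit_cycles`` cycles; the phase delay
    of stress behind strain is also returned (small for a predominantly
    elastic network).
    """
    st = state.copy()
    en = Engine(st, p, noise=noise, det_limit_frac=2.0)
    ip = en.ip
    dt_w = ip.dt * p.n_kinetic
    n_win = int(round(cycles / freq_hz / dt_w))
    base = st.domain.face_pos.copy()
    omega = 2 * np.pi * freq_hz
    t_rec, s_rec, e_rec = [], [], []
    rng = np.random.default_rng(0)
    t = 0.0
    for k in range(n_win):
        t = (k + 1) * dt_w
        disp = 0.5 * amplitude_nm * np.sin(omega * t)
        en.move_face(2 * axis, base[2 * axis] - disp)
        en.move_face(2 * axis + 1, base[2 * axis + 1] + disp)
        sf, _ = en.window(p.n_kinetic, int(rng.integers(2 ** 31)))
        sig = stress_from_forces(en, sf)
        s_rec.append(0.5 * (sig[2 * axis] + sig[2 * axis + 1]))
        # applied strain, extension positive (the driven width change / W0);
        # contractile wall stress then responds in phase for an elastic net
        e_rec.append(2 * disp / st.domain.W0)
        t_rec.append(t)
    t_arr = np.array(t_rec)
    sel = t_arr >= (cycles - fit_cycles) / freq_hz
    if sel.sum() < 8:
        raise ValueError("probe too short for a sinusoid fit")

    def fit(y):
        X = np.column_stack([np.sin(omega * t_arr[sel]),
                             np.cos(omega * t_arr[sel]),
                             np.ones(sel.sum())])
        coef, *_ = np.linalg.lstsq(X, np.array(y)[sel], rcond=None)
        amp = float(np.hypot(coef[0], coef[1]))
        phase = float(np.arctan2(coef[1], coef[0]))
        return amp, phase

    s_amp, s_ph = fit(s_rec)
    e_amp, e_ph = fit(e_rec)
    if e_amp == 0:
        raise ValueError("zero strain amplitude")
    E_n = s_amp / e_amp
    phase = (s_ph - e_ph + np.pi) % (2 * np.pi) - np.pi
    return float(E_n), float(phase)
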