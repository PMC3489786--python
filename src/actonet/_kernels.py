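"""Numba kernels for the force field and the overdamped Euler integrator.

All kernels operate on flat arrays prepared by :mod:`actonet.engine`:

* ``pos``            -- (N, 3) positions, nm
* bonds              -- Hookean springs ``i, j, k (pN/nm), r0 (nm)``
* angles             -- hinge terms on the angle between u = p[j]-p[i] and
                        v = p[l]-p[k]: ``kappa (pN nm/rad^2), theta0``
* repulsion          -- candidate segment pairs, harmonic overlap below r_c

Forces are exact analytic gradients of the quadratic potentials; the
integrator adds a thermal kick with per-component variance 2 kBT zeta / dt
(uniform variates, variance-matched) and moves free nodes by F/zeta * dt.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_UNSTABLE = 1

_EPS = 1e-12
# hinges on near-degenerate bonds (severing slivers) carry no torque:
# a quadratic angle term over a ~nm lever arm produces unphysical forces
MIN_HINGE_NM = 30.0


@njit(cache=True, fastmath=True)
def bond_forces(pos, b_i, b_j, b_k, b_r0, F):
    """Accumulate spring forces; returns extension energy (pN nm)."""
    E = 0.0
    for n in range(b_i.shape[0]):
        i = b_i[n]
        j = b_j[n]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < _EPS:
            if b_r0[n] > 0.0:
                # zero-length bond with finite rest length: direction undefined
                return np.nan
            continue
        f = -b_k[n] * (r - b_r0[n]) / r     # force on j along +d when compressed
        F[j, 0] += f * dx
        F[j, 1] += f * dy
        F[j, 2] += f * dz
        F[i, 0] -= f * dx
        F[i, 1] -= f * dy
        F[i, 2] -= f * dz
        E += 0.5 * b_k[n] * (r - b_r0[n]) ** 2
    return E


@njit(cache=True, fastmath=True)
def angle_forces(pos, a_i, a_j, a_k, a_l, a_kap, a_t0, F):
    """Accumulate hinge forces; returns bending energy (pN nm)."""
    E = 0.0
    for n in range(a_i.shape[0]):
        i = a_i[n]
        j = a_j[n]
        k = a_k[n]
        l = a_l[n]
        ux = pos[j, 0] - pos[i, 0]
        uy = pos[j, 1] - pos[i, 1]
        uz = pos[j, 2] - pos[i, 2]
        vx = pos[l, 0] - pos[k, 0]
        vy = pos[l, 1] - pos[k, 1]
        vz = pos[l, 2] - pos[k, 2]
        lu = np.sqrt(ux * ux + uy * uy + uz * uz)
        lv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if lu < MIN_HINGE_NM or lv < MIN_HINGE_NM:
            continue  # degenerate/sliver hinge carries no defined torque
        ux /= lu
        uy /= lu
        uz /= lu
        vx /= lv
        vy /= lv
        vz /= lv
        c = ux * vx + uy * vy + uz * vz
        if c > 1.0:
            c = 1.0
        elif c < -1.0:
            c = -1.0
        th = np.arccos(c)
        dth = th - a_t0[n]
        E += 0.5 * a_kap[n] * dth * dth
        s = np.sqrt(1.0 - c * c)
        if s < 1e-8:
            if abs(dth) < 1e-6:
                continue        # at a smooth extremum, zero torque
            s = 1e-8            # documented tie-break near theta = 0 or pi
        g = a_kap[n] * dth / s
        # F_j = g*(v_hat - c*u_hat)/|u| ; F_l = g*(u_hat - c*v_hat)/|v|
        gu = g / lu
        gv = g / lv
        fjx = gu * (vx - c * ux)
        fjy = gu * (vy - c * uy)
        fjz = gu * (vz - c * uz)
        flx = gv * (ux - c * vx)
        fly = gv * (uy - c * vy)
        flz = gv * (uz - c * vz)
        F[j, 0] += fjx
        F[j, 1] += fjy
        F[j, 2] += fjz
        F[i, 0] -= fjx
        F[i, 1] -= fjy
        F[i, 2] -= fjz
        F[l, 0] += flx
        F[l, 1] += fly
        F[l, 2] += flz
        F[k, 0] -= flx
        F[k, 1] -= fly
        F[k, 2] -= flz
    return E


@njit(cache=True, fastmath=True)
def _seg_dist_core(p1x, p1y, p1z, q1x, q1y, q1z,
                   p2x, p2y, p2z, q2x, q2y, q2z):
    """Closest points of two segments (Ericson); returns (dist, s, t)."""
    d1x = q1x - p1x
    d1y = q1y - p1y
    d1z = q1z - p1z
    d2x = q2x - p2x
    d2y = q2y - p2y
    d2z = q2z - p2z
    rx = p1x - p2x
    ry = p1y - p2y
    rz = p1z - p2z
    a = d1x * d1x + d1y * d1y + d1z * d1z
    e = d2x * d2x + d2y * d2y + d2z * d2z
    f = d2x * rx + d2y * ry + d2z * rz
    if a <= _EPS and e <= _EPS:
        s = 0.0
        t = 0.0
    elif a <= _EPS:
        s = 0.0
        t = min(max(f / e, 0.0), 1.0)
    else:
        c = d1x * rx + d1y * ry + d1z * rz
        if e <= _EPS:
            t = 0.0
            s = min(max(-c / a, 0.0), 1.0)
        else:
            b = d1x * d2x + d1y * d2y + d1z * d2z
            denom = a * e - b * b
            if denom > _EPS:
                s = min(max((b * f - c * e) / denom, 0.0), 1.0)
            else:
                s = 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(max(-c / a, 0.0), 1.0)
            elif t > 1.0:
                t = 1.0
                s = min(max((b - c) / a, 0.0), 1.0)
    cx = p1x + s * d1x - p2x - t * d2x
    cy = p1y + s * d1y - p2y - t * d2y
    cz = p1z + s * d1z - p2z - t * d2z
    return np.sqrt(cx * cx + cy * cy + cz * cz), s, t


@njit(cache=True, fastmath=True)
def segment_distance_jit(a1, b1, a2, b2):
    return _seg_dist_core(a1[0], a1[1], a1[2], b1[0], b1[1], b1[2],
                          a2[0], a2[1], a2[2], b2[0], b2[1], b2[2])


@njit(cache=True, fastmath=True)
def repulsion_forces(pos, pair_s1, pair_s2, seg_a, seg_b, kr, rc, F):
    """Accumulate excluded-volume forces; returns repulsion energy."""
    E = 0.0
    for n in range(pair_s1.shape[0]):
        s1 = pair_s1[n]
        s2 = pair_s2[n]
        ia = seg_a[s1]
        ib = seg_b[s1]
        ja = seg_a[s2]
        jb = seg_b[s2]
        d, s, t = _seg_dist_core(
            pos[ia, 0], pos[ia, 1], pos[ia, 2],
            pos[ib, 0], pos[ib, 1], pos[ib, 2],
            pos[ja, 0], pos[ja, 1], pos[ja, 2],
            pos[jb, 0], pos[jb, 1], pos[jb, 2])
        if d >= rc:
            continue
        E += 0.5 * kr * (d - rc) ** 2
        c1x = pos[ia, 0] + s * (pos[ib, 0] - pos[ia, 0])
        c1y = pos[ia, 1] + s * (pos[ib, 1] - pos[ia, 1])
        c1z = pos[ia, 2] + s * (pos[ib, 2] - pos[ia, 2])
        c2x = pos[ja, 0] + t * (pos[jb, 0] - pos[ja, 0])
        c2y = pos[ja, 1] + t * (pos[jb, 1] - pos[ja, 1])
        c2z = pos[ja, 2] + t * (pos[jb, 2] - pos[ja, 2])
        nx = c1x - c2x
        ny = c1y - c2y
        nz = c1z - c2z
        if d > _EPS:
            nx /= d
            ny /= d
            nz /= d
        else:
            # coincident closest points: deterministic tie-break direction
            nx, ny, nz = 1.0, 0.0, 0.0
        fmag = -kr * (d - rc)          # > 0, pushes segment 1 away from 2
        fx = fmag * nx
        fy = fmag * ny
        fz = fmag * nz
        F[ia, 0] += (1.0 - s) * fx
        F[ia, 1] += (1.0 - s) * fy
        F[ia, 2] += (1.0 - s) * fz
        F[ib, 0] += s * fx
        F[ib, 1] += s * fy
        F[ib, 2] += s * fz
        F[ja, 0] -= (1.0 - t) * fx
        F[ja, 1] -= (1.0 - t) * fy
        F[ja, 2] -= (1.0 - t) * fz
        F[jb, 0] -= t * fx
        F[jb, 1] -= t * fy
        F[jb, 2] -= t * fz
    return E


@njit(cache=True, fastmath=True)
def build_pairs_celllist(pos, seg_a, seg_b, seg_fil, seg_sid, cutoff,
                         max_pairs):
    """Candidate segment pairs with midpoint cell-list search.

    Returns (pair_s1, pair_s2, count).  Pairs on the same filament fewer
    than 2 bonds apart are excluded.  The cell edge exceeds cutoff plus the
    longest segment, so every pair with true minimum distance < cutoff is
    found (superset; exact distances are evaluated by the force kernel).
    """
    S = seg_a.shape[0]
    out1 = np.empty(max_pairs, np.int64)
    out2 = np.empty(max_pairs, np.int64)
    if S == 0:
        return out1, out2, 0
    mid = np.empty((S, 3))
    maxlen = 1.0
    for s in range(S):
        dx = pos[seg_b[s], 0] - pos[seg_a[s], 0]
        dy = pos[seg_b[s], 1] - pos[seg_a[s], 1]
        dz = pos[seg_b[s], 2] - pos[seg_a[s], 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        if L > maxlen:
            maxlen = L
        mid[s, 0] = 0.5 * (pos[seg_a[s], 0] + pos[seg_b[s], 0])
        mid[s, 1] = 0.5 * (pos[seg_a[s], 1] + pos[seg_b[s], 1])
        mid[s, 2] = 0.5 * (pos[seg_a[s], 2] + pos[seg_b[s], 2])
    edge = cutoff + maxlen + 1e-9
    lo = np.empty(3)
    hi = np.empty(3)
    for d in range(3):
        lo[d] = mid[:, d].min()
        hi[d] = mid[:, d].max()
    nc = np.empty(3, np.int64)
    for d in range(3):
        nc[d] = max(1, int((hi[d] - lo[d]) / edge) + 1)
    key = np.empty(S, np.int64)
    for s in range(S):
        cx = int((mid[s, 0] - lo[0]) / edge)
        cy = int((mid[s, 1] - lo[1]) / edge)
        cz = int((mid[s, 2] - lo[2]) / edge)
        key[s] = (cx * nc[1] + cy) * nc[2] + cz
    order = np.argsort(key)
    skey = key[order]
    count = 0
    for a in range(S):
        s1 = order[a]
        cx = int((mid[s1, 0] - lo[0]) / edge)
        cy = int((mid[s1, 1] - lo[1]) / edge)
        cz = int((mid[s1, 2] - lo[2]) / edge)
        for ox in range(-1, 2):
            x = cx + ox
            if x < 0 or x >= nc[0]:
                continue
            for oy in range(-1, 2):
                y = cy + oy
                if y < 0 or y >= nc[1]:
                    continue
                for oz in range(-1, 2):
                    z = cz + oz
                    if z < 0 or z >= nc[2]:
                        continue
                    k = (x * nc[1] + y) * nc[2] + z
                    b = np.searchsorted(skey, k)
                    while b < S and skey[b] == k:
                        s2 = order[b]
                        b += 1
                        if s2 <= s1:
                            continue
                        if (seg_fil[s1] == seg_fil[s2]
                                and abs(seg_sid[s1] - seg_sid[s2]) < 2):
                            continue
                        dd = 0.0
                        for d in range(3):
                            dd += (mid[s1, d] - mid[s2, d]) ** 2
                        if dd > (cutoff + maxlen) ** 2:
                            continue
                        if count < max_pairs:
                            out1[count] = s1
                            out2[count] = s2
                        count += 1
    return out1, out2, count


@njit(cache=True, fastmath=True)
def run_window(pos, F,
               b_i, b_j, b_k, b_r0,
               a_i, a_j, a_k, a_l, a_kap, a_t0,
               pair_s1, pair_s2, seg_a, seg_b, kr, rc,
               free_mask, anchor_idx, anchor_sign, anchor_axis, anchor_face,
               zeta, kBT, dt, nsteps, noise_on, seed, det_disp_limit,
               stress_force, energies):
    """Integrate ``nsteps`` Euler steps.

    * thermal kick: uniform variates, per-component variance 2 kBT zeta/dt
    * clamped nodes (free_mask == 0) never move
    * ``stress_force`` (6,) receives the time-averaged inward normal force
      summed over each face's anchors
    * returns STATUS_UNSTABLE if any deterministic per-step displacement
      exceeds ``det_disp_limit``
    """
    np.random.seed(seed)
    N = pos.shape[0]
    amp = 0.0
    if noise_on and kBT > 0.0:
        amp = np.sqrt(6.0 * kBT * zeta / dt)
    inv_zeta_dt = dt / zeta
    for f in range(6):
        stress_force[f] = 0.0
    status = STATUS_OK
    for step in range(nsteps):
        for i in range(N):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            F[i, 2] = 0.0
        e_ext = bond_forces(pos, b_i, b_j, b_k, b_r0, F)
        if np.isnan(e_ext):
            status = STATUS_UNSTABLE
            break
        e_bend = angle_forces(pos, a_i, a_j, a_k, a_l, a_kap, a_t0, F)
        e_rep = repulsion_forces(pos, pair_s1, pair_s2, seg_a, seg_b,
                                 kr, rc, F)
        energies[0] = e_ext
        energies[1] = e_bend
        energies[2] = e_rep
        # wall stress bookkeeping from the deterministic force field
        for n in range(anchor_idx.shape[0]):
            i = anchor_idx[n]
            stress_force[anchor_face[n]] += (anchor_sign[n]
                                             * F[i, anchor_axis[n]])
        # integrate
        for i in range(N):
            if free_mask[i] == 0.0:
                continue
            ddx = F[i, 0] * inv_zeta_dt
            ddy = F[i, 1] * inv_zeta_dt
            ddz = F[i, 2] * inv_zeta_dt
            if (abs(ddx) > det_disp_limit or abs(ddy) > det_disp_limit
                    or abs(ddz) > det_disp_limit):
                status = STATUS_UNSTABLE
            if amp > 0.0:
                ddx += amp * (2.0 * np.random.random() - 1.0) * inv_zeta_dt
                ddy += amp * (2.0 * np.random.random() - 1.0) * inv_zeta_dt
                ddz += amp * (2.0 * np.random.random() - 1.0) * inv_zeta_dt
            pos[i, 0] += ddx
            pos[i, 1] += ddy
            pos[i, 2] += ddz
        if status != STATUS_OK:
            break
    for f in range(6):
        stress_force[f] /= max(1, nsteps)
    return status


@njit(cache=True, fastmath=True)
def max_displacement(pos, ref, active_mask):
    m = 0.0
    for i in range(pos.shape[0]):
        if active_mask[i] == 0.0:
            continue
        for d in range(3):
            v = abs(pos[i, d] - ref[i, d])
            if v > m:
                m = v
    return m
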