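"""Snapshot serialization (documented columnar text format, bit-exact
round trip) and legacy-ASCII VTK polydata export for visualization.

Snapshot format (plain text, ``%.17g`` floats so values round-trip
exactly)::

    #actonet-snapshot v1
    @meta        time
    @domain      W0 E face_pos(6) periodic(3)
    @clamps      fid end face
    @filaments   fid n_nodes barbed_at_end
    @nodes       fid idx x y z
    @seg_r0      fid idx r0          (only filaments with custom rests)
    @linkers     lid kind state a0_fil a0_node a1_fil a1_node bp(6) bb_r0
    @pools       free_ACP(n) / free_M(n)
    @tethers     fil node anchor(3) k r0
"""

from __future__ import annotations

import numpy as np

from .network import (Arm, DomainBoundary, Filament, Linker, NetworkState,
                      Tether)

_F = "%.17g"


def _fmt(*vals) -> str:
    out = []
    for v in vals:
        if isinstance(v, (float, np.floating)):
            out.append(_F % v)
        else:
            out.append(str(v))
    return " ".join(out)


def save_snapshot(state: NetworkState, path) -> None:
    d = state.domain
    lines = ["#actonet-snapshot v1", "@meta", _fmt(state.time), "@domain",
             _fmt(d.W0, d.E),
             _fmt(*d.face_pos),
             " ".join(str(int(b)) for b in d.periodic),
             "@clamps"]
    for (fid, end), face in sorted(d.clamps.items()):
        lines.append(_fmt(fid, end, face))
    lines.append("@filaments")
    for fid in sorted(state.filaments):
        f = state.filaments[fid]
        lines.append(_fmt(fid, f.n_nodes, int(f.barbed_at_end)))
    lines.append("@nodes")
    for fid in sorted(state.filaments):
        f = state.filaments[fid]
        for i, x in enumerate(f.nodes):
            lines.append(_fmt(fid, i, *x))
    lines.append("@seg_r0")
    for fid in sorted(state.filaments):
        f = state.filaments[fid]
        if f.seg_r0 is not None:
            for i, r in enumerate(f.seg_r0):
                lines.append(_fmt(fid, i, r))
    lines.append("@linkers")
    for lid in sorted(state.linkers):
        lk = state.linkers[lid]
        a0, a1 = lk.arms
        lines.append(_fmt(
            lid, lk.kind, lk.state,
            -1 if a0.filament is None else a0.filament,
            -1 if a0.node is None else a0.node,
            -1 if a1.filament is None else a1.filament,
            -1 if a1.node is None else a1.node,
            *lk.bp[0], *lk.bp[1], lk.backbone_r0))
    lines.append("@pools")
    lines.append(" ".join(str(int(v)) for v in state.free_ACP))
    lines.append(" ".join(str(int(v)) for v in state.free_M))
    lines.append("@tethers")
    for th in state.tethers:
        lines.append(_fmt(th.filament, th.node, *th.anchor,
                          th.k_pN_per_nm, th.r0))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_snapshot(path) -> NetworkState:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or not lines[0].startswith("#actonet-snapshot"):
        raise ValueError(f"{path}: not an actonet snapshot")
    sections: dict[str, list[str]] = {}
    cur = None
    for ln in lines[1:]:
        if ln.startswith("@"):
            cur = ln[1:]
            sections[cur] = []
        elif cur is not None and ln:
            sections[cur].append(ln)

    time = float(sections["meta"][0])
    dom = sections["domain"]
    W0, E = (float(v) for v in dom[0].split())
    face_pos = np.array([float(v) for v in dom[1].split()])
    periodic = np.array([bool(int(v)) for v in dom[2].split()])
    clamps = {}
    for ln in sections.get("clamps", []):
        fid, end, face = (int(v) for v in ln.split())
        clamps[(fid, end)] = face
    domain = DomainBoundary(W0, face_pos, E, periodic, clamps)

    fil_hdr = {}
    for ln in sections["filaments"]:
        fid, n, barbed = (int(v) for v in ln.split())
        fil_hdr[fid] = (n, bool(barbed))
    nodes = {fid: np.empty((n, 3)) for fid, (n, _) in fil_hdr.items()}
    for ln in sections["nodes"]:
        parts = ln.split()
        fid, i = int(parts[0]), int(parts[1])
        nodes[fid][i] = [float(v) for v in parts[2:5]]
    seg_r0: dict[int, np.ndarray] = {}
    for ln in sections.get("seg_r0", []):
        parts = ln.split()
        fid, i = int(parts[0]), int(parts[1])
        seg_r0.setdefault(fid, np.full(fil_hdr[fid][0] - 1, np.nan))[i] = \
            float(parts[2])
    filaments = {}
    for fid, (n, barbed) in fil_hdr.items():
        f = Filament(nodes[fid], barbed, seg_r0=seg_r0.get(fid))
        for end in (0, 1):
            f.clamped[end] = (fid, end) in clamps
        filaments[fid] = f

    linkers = {}
    for ln in sections.get("linkers", []):
        parts = ln.split()
        lid = int(parts[0])
        kind, st_ = parts[1], parts[2]
        ints = [int(v) for v in parts[3:7]]
        bp = np.array([float(v) for v in parts[7:13]]).reshape(2, 3)
        arms = [Arm(None if ints[0] < 0 else ints[0],
                    None if ints[1] < 0 else ints[1]),
                Arm(None if ints[2] < 0 else ints[2],
                    None if ints[3] < 0 else ints[3])]
        backbone_r0 = float(parts[13]) if len(parts) > 13 else 0.0
        linkers[lid] = Linker(kind, st_, arms, bp, backbone_r0)

    state = NetworkState(filaments, linkers, domain, time)
    pools = sections.get("pools", [])
    if len(pools) >= 2:
        state.free_ACP = np.array([int(v) for v in pools[0].split()])
        state.free_M = np.array([int(v) for v in pools[1].split()])
    for ln in sections.get("tethers", []):
        parts = ln.split()
        state.tethers.append(Tether(
            int(parts[0]), int(parts[1]),
            np.array([float(v) for v in parts[2:5]]),
            float(parts[5]), float(parts[6])))
    return state


# ---------------------------------------------------------------------------

def export_vtk(state: NetworkState, path) -> None:
    """Legacy-ASCII VTK polydata: filament polylines + linker segments,
    with an entity-type point scalar (0 actin, 1 ACP, 2 motor)."""
    pts: list[np.ndarray] = []
    kinds: list[int] = []
    lines: list[list[int]] = []
    for fid in sorted(state.filaments):
        f = state.filaments[fid]
        start = len(pts)
        pts.extend(f.nodes)
        kinds.extend([0] * f.n_nodes)
        lines.append(list(range(start, start + f.n_nodes)))
    for lid in sorted(state.linkers):
        lk = state.linkers[lid]
        code = 2 if lk.kind == "motor" else 1
        start = len(pts)
        pts.extend([lk.bp[0], lk.bp[1]])
        kinds.extend([code, code])
        lines.append([start, start + 1])
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nactonet network\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for x in pts:
            fh.write(f"{x[0]:.4f} {x[1]:.4f} {x[2]:.4f}\n")
        total = sum(len(l) + 1 for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join([str(len(l))] + [str(i) for i in l]) + "\n")
        fh.write(f"POINT_DATA {len(pts)}\nSCALARS entity int 1\n"
                 "LOOKUP_TABLE default\n")
        fh.write("\n".join(str(k) for k in kinds) + "\n")
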