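"""Network data model: filaments, cross-linkers, motors, occupancy, domain.

Conventions
-----------
* Coordinates are continuous 3-D positions in nm with the origin at the
  domain centre; face ``2*axis + side`` (side 0 = negative, 1 = positive)
  sits at ``domain.face_pos[...]``.
* A filament is an ordered bead chain; ``barbed_at_end`` selects which end
  index is the barbed end.  Binding sites are the nodes (spacing r0_A), at
  most one linker arm per node.
* ACPs and motors share one shape (:class:`Linker`): two arms, each arm a
  spring from a backbone point to its attached filament node.  FREE linkers
  are implicit - they live only in per-voxel monomer pools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

KIND_ACP = "ACP"
KIND_MOTOR = "motor"
FREE, INACTIVE, ACTIVE = "FREE", "INACTIVE", "ACTIVE"

N_VOXELS_PER_AXIS = 3  # free-monomer pool resolution


@dataclass
class Filament:
    nodes: np.ndarray                 # (n, 3) float64, nm
    barbed_at_end: bool = True        # True: barbed end is index n-1
    clamped: np.ndarray = field(default_factory=lambda: np.zeros(2, bool))
    # clamped[0] refers to node 0, clamped[1] to node n-1
    seg_r0: np.ndarray | None = None  # per-bond rest lengths (severed ends
                                      # are born unstressed); None -> r0_A

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.nodes) - 1

    @property
    def barbed_index(self) -> int:
        return self.n_nodes - 1 if self.barbed_at_end else 0

    @property
    def pointed_index(self) -> int:
        return 0 if self.barbed_at_end else self.n_nodes - 1

    @property
    def toward_barbed(self) -> int:
        """Node-index increment that moves toward the barbed end."""
        return 1 if self.barbed_at_end else -1

    def copy(self) -> "Filament":
        return Filament(self.nodes.copy(), self.barbed_at_end,
                        self.clamped.copy(),
                        None if self.seg_r0 is None else self.seg_r0.copy())


@dataclass
class Arm:
    filament: int | None = None       # filament id, None when detached
    node: int | None = None

    @property
    def attached(self) -> bool:
        return self.filament is not None


@dataclass
class Linker:
    kind: str                         # KIND_ACP | KIND_MOTOR
    state: str                        # INACTIVE | ACTIVE (FREE is implicit)
    arms: list[Arm]
    bp: np.ndarray                    # (2, 3) backbone points, nm
    backbone_r0: float = 0.0          # rest length of the bp0-bp1 bond;
                                      # set at binding so no force is injected

    def copy(self) -> "Linker":
        return Linker(self.kind, self.state,
                      [Arm(a.filament, a.node) for a in self.arms],
                      self.bp.copy(), self.backbone_r0)


@dataclass
class Tether:
    """External spring from a filament node to a fixed anchor point.

    Used by test fixtures (e.g. the motor 'sarcomere') to hold filaments
    against motor-generated tension without clamping them to a face.
    """
    filament: int
    node: int
    anchor: np.ndarray        # (3,) nm, immobile
    k_pN_per_nm: float
    r0: float = 0.0           # rest length, nm

    def copy(self) -> "Tether":
        return Tether(self.filament, self.node, self.anchor.copy(),
                      self.k_pN_per_nm, self.r0)


@dataclass
class DomainBoundary:
    W0: float                                     # reference width, nm
    face_pos: np.ndarray                          # (6,) signed positions, nm
    E: float                                      # substrate modulus, Pa
    periodic: np.ndarray = field(default_factory=lambda: np.ones(3, bool))
    clamps: dict = field(default_factory=dict)    # (fil_id, end 0|1) -> face

    @classmethod
    def cube(cls, W0_nm: float, E_Pa: float, periodic: bool = True
             ) -> "DomainBoundary":
        h = W0_nm / 2.0
        return cls(W0=W0_nm, face_pos=np.array([-h, h, -h, h, -h, h]),
                   E=E_Pa, periodic=np.full(3, periodic))

    def widths(self) -> np.ndarray:
        return self.face_pos[1::2] - self.face_pos[0::2]

    def volume_nm3(self) -> float:
        return float(np.prod(self.widths()))

    def face_area_nm2(self, face: int) -> float:
        w = self.widths()
        axis = face // 2
        others = [a for a in range(3) if a != axis]
        return float(w[others[0]] * w[others[1]])

    def copy(self) -> "DomainBoundary":
        return DomainBoundary(self.W0, self.face_pos.copy(), self.E,
                              self.periodic.copy(), dict(self.clamps))


@dataclass
class NetworkState:
    filaments: dict[int, Filament]
    linkers: dict[int, Linker]
    domain: DomainBoundary
    time: float = 0.0
    # implicit free-monomer pools, one count per voxel (flattened 3x3x3 grid)
    free_ACP: np.ndarray = field(
        default_factory=lambda: np.zeros(N_VOXELS_PER_AXIS ** 3, np.int64))
    free_M: np.ndarray = field(
        default_factory=lambda: np.zeros(N_VOXELS_PER_AXIS ** 3, np.int64))
    tethers: list = field(default_factory=list)
    rng_state: dict | None = None

    def copy(self) -> "NetworkState":
        return NetworkState(
            {i: f.copy() for i, f in self.filaments.items()},
            {i: l.copy() for i, l in self.linkers.items()},
            self.domain.copy(), self.time,
            self.free_ACP.copy(), self.free_M.copy(),
            [t.copy() for t in self.tethers],
            dict(self.rng_state) if self.rng_state else None)

    # ------------------------------------------------------------- census
    def linker_counts(self, kind: str) -> dict[str, int]:
        free = int((self.free_ACP if kind == KIND_ACP else self.free_M).sum())
        inactive = sum(1 for l in self.linkers.values()
                       if l.kind == kind and l.state == INACTIVE)
        active = sum(1 for l in self.linkers.values()
                     if l.kind == kind and l.state == ACTIVE)
        return {FREE: free, INACTIVE: inactive, ACTIVE: active}

    def voxel_of(self, point: np.ndarray) -> int:
        """Flat voxel index of a point under the current face positions."""
        n = N_VOXELS_PER_AXIS
        lo = self.domain.face_pos[0::2]
        w = self.domain.widths()
        ijk = np.clip(((point - lo) / w * n).astype(int), 0, n - 1)
        return int(ijk[0] * n * n + ijk[1] * n + ijk[2])


# ---------------------------------------------------------------------------
# occupancy and validation
# ---------------------------------------------------------------------------

def occupancy_map(state: NetworkState) -> dict[tuple[int, int], tuple[int, int]]:
    """(filament id, node) -> (linker id, arm index) for every attached arm."""
    occ: dict[tuple[int, int], tuple[int, int]] = {}
    for lid, lk in state.linkers.items():
        for ai, arm in enumerate(lk.arms):
            if arm.attached:
                key = (arm.filament, arm.node)
                if key in occ:  # collision reported by validate()
                    continue
                occ[key] = (lid, ai)
    return occ


def validate(state: NetworkState, p=None) -> list[str]:
    """Return a list of invariant violations (empty iff the state is valid)."""
    from .params import reference_parameters
    p = p or reference_parameters()
    bad: list[str] = []

    for fid, f in state.filaments.items():
        if f.n_nodes < 2:
            bad.append(f"filament {fid}: fewer than 2 nodes")
            continue
        seg = np.linalg.norm(np.diff(f.nodes, axis=0), axis=1)
        rest = (np.full(f.n_segments, p.r0_A) if f.seg_r0 is None
                else f.seg_r0)
        dev = np.abs(seg - rest)
        # periodic assembly states wrap across faces; skip wrapped bonds
        if state.domain.periodic.any():
            dev = dev[seg < state.domain.W0 / 2]
        if dev.size and np.any(dev > 0.3 * p.r0_A):
            bad.append(f"filament {fid}: segment length deviates more than "
                       "30% of r0_A from its rest length")

    seen: dict[tuple[int, int], int] = {}
    for lid, lk in state.linkers.items():
        attached = [a for a in lk.arms if a.attached]
        if lk.state == ACTIVE:
            if len(attached) != 2:
                bad.append(f"linker {lid}: ACTIVE with {len(attached)} arms")
            elif attached[0].filament == attached[1].filament:
                bad.append(f"linker {lid}: ACTIVE arms share one filament")
        elif lk.state == INACTIVE:
            if len(attached) != 1:
                bad.append(f"linker {lid}: INACTIVE with {len(attached)} arms")
        else:
            bad.append(f"linker {lid}: unexpected state {lk.state}")
        for arm in attached:
            if arm.filament not in state.filaments:
                bad.append(f"linker {lid}: dangling filament id {arm.filament}")
                continue
            fil = state.filaments[arm.filament]
            if not (0 <= arm.node < fil.n_nodes):
                bad.append(f"linker {lid}: node index {arm.node} out of range")
                continue
            key = (arm.filament, arm.node)
            if key in seen and seen[key] != lid:
                bad.append(f"node {key}: hosts arms of linkers "
                           f"{seen[key]} and {lid}")
            seen[key] = lid

    d = state.domain
    if np.any(d.face_pos[1::2] <= d.face_pos[0::2]):
        bad.append("domain: opposing faces cross")
    for (fid, end), face in d.clamps.items():
        if fid not in state.filaments:
            bad.append(f"clamp registry: dangling filament id {fid}")
            continue
        f = state.filaments[fid]
        node = f.nodes[0 if end == 0 else -1]
        axis = face // 2
        if abs(node[axis] - d.face_pos[face]) > 1e-6:
            bad.append(f"clamp ({fid},{end}): anchor off its face plane")
        if not f.clamped[end]:
            bad.append(f"clamp ({fid},{end}): clamped flag not set")
    for fid, f in state.filaments.items():
        for end in (0, 1):
            if f.clamped[end] and (fid, end) not in d.clamps:
                bad.append(f"filament {fid} end {end}: flagged clamped "
                           "but absent from registry")
    return bad


# ---------------------------------------------------------------------------
# segment contact search
# ---------------------------------------------------------------------------

def _all_segments(state: NetworkState) -> tuple[np.ndarray, np.ndarray,
                                                np.ndarray, np.ndarray]:
    """Segment endpoints (S,3),(S,3) plus (fil id, seg index) per segment."""
    a, b, fid, sid = [], [], [], []
    for i, f in state.filaments.items():
        a.append(f.nodes[:-1])
        b.append(f.nodes[1:])
        fid.append(np.full(f.n_segments, i))
        sid.append(np.arange(f.n_segments))
    if not a:
        z = np.zeros((0, 3))
        return z, z, np.zeros(0, int), np.zeros(0, int)
    return (np.concatenate(a), np.concatenate(b),
            np.concatenate(fid), np.concatenate(sid))


def neighbor_segments(state: NetworkState, cutoff: float
                      ) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All pairs of actin segments with minimum distance below ``cutoff``.

    Cell-list search (cell edge >= cutoff + the longest admissible segment)
    followed by an exact segment-segment distance filter.  Segments of the
    same filament fewer than 2 bonds apart are excluded.
    """
    from .mechanics import segment_distance
    a, b, fid, sid = _all_segments(state)
    if len(a) == 0:
        return []
    mid = 0.5 * (a + b)
    seg_len = np.linalg.norm(b - a, axis=1)
    edge = cutoff + max(seg_len.max(), 1.0)
    lo = mid.min(axis=0) - 1e-9
    cells = np.floor((mid - lo) / edge).astype(np.int64)
    ncell = cells.max(axis=0) + 1
    key = (cells[:, 0] * ncell[1] + cells[:, 1]) * ncell[2] + cells[:, 2]
    buckets: dict[int, list[int]] = {}
    for i, k in enumerate(key):
        buckets.setdefault(int(k), []).append(i)

    out = []
    offs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)]
    for i in range(len(a)):
        cx, cy, cz = cells[i]
        for dx, dy, dz in offs:
            k = ((cx + dx) * ncell[1] + (cy + dy)) * ncell[2] + (cz + dz)
            for j in buckets.get(int(k), ()):
                if j <= i:
                    continue
                if fid[i] == fid[j] and abs(sid[i] - sid[j]) < 2:
                    continue
                dist, _, _ = segment_distance(a[i], b[i], a[j], b[j])
                if dist < cutoff:
                    out.append(((int(fid[i]), int(sid[i])),
                                (int(fid[j]), int(sid[j]))))
    return out
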