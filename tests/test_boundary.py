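import numpy as np
import pytest

from actonet import face_stress, sever_and_clamp, sticky_capture, update_faces
from actonet.boundary import FaceCrossingError, face_targets, probe_stiffness
from actonet.network import DomainBoundary, Filament, NetworkState


def _state_with(filaments, p, W_nm=2000.0, E=None, periodic=False):
    dom = DomainBoundary.cube(W_nm, E or p.E, periodic)
    return NetworkState(dict(enumerate(filaments)), {}, dom)


class TestSeverAndClamp:
    def test_interior_filament_untouched(self, p):
        x = np.arange(5) * p.r0_A - 280.0
        f = Filament(np.column_stack([x, np.zeros(5), np.zeros(5)]))
        st = _state_with([f], p, periodic=True)
        out = sever_and_clamp(st, p)
        assert len(out.filaments) == 1
        assert np.allclose(out.filaments[0].nodes, f.nodes)
        assert out.domain.clamps == {}
        assert not out.domain.periodic.any()

    def test_single_crossing_splits_and_clamps(self, p):
        # crosses the +x face (at 1000) once
        x = 600.0 + np.arange(5) * p.r0_A
        f = Filament(np.column_stack([x, np.zeros(5), np.zeros(5)]))
        st = _state_with([f], p, periodic=True)
        out = sever_and_clamp(st, p)
        assert len(out.filaments) == 2
        faces = sorted(out.domain.clamps.values())
        assert faces == [0, 1]     # one end on +x, the wrapped end on -x
        for (fid, end), face in out.domain.clamps.items():
            node = out.filaments[fid].nodes[0 if end == 0 else -1]
            assert node[face // 2] == pytest.approx(
                out.domain.face_pos[face])

    def test_no_boundary_crossings_remain(self, p):
        rng = np.random.default_rng(8)
        fils = []
        for _ in range(15):
            start = rng.uniform(-1000, 1000, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            fils.append(Filament(start + np.arange(12)[:, None]
                                 * p.r0_A * d))
        st = _state_with(fils, p, periodic=True)
        out = sever_and_clamp(st, p)
        lo = out.domain.face_pos[0::2]
        hi = out.domain.face_pos[1::2]
        for f in out.filaments.values():
            assert np.all(f.nodes >= lo - 1e-6)
            assert np.all(f.nodes <= hi + 1e-6)

    def test_polarity_direction_preserved(self, p):
        x = 600.0 + np.arange(5) * p.r0_A
        f = Filament(np.column_stack([x, np.zeros(5), np.zeros(5)]),
                     barbed_at_end=True)
        out = sever_and_clamp(_state_with([f], p, periodic=True), p)
        assert all(nf.barbed_at_end for nf in out.filaments.values())


class TestStickyCapture:
    def _end_state(self, p, gap):
        W = 2000.0
        x0 = -W / 2 + gap
        x = x0 + np.arange(4) * p.r0_A
        f = Filament(np.column_stack([x, np.zeros(4), np.zeros(4)]))
        return _state_with([f], p, W_nm=W)

    def test_end_within_30nm_is_clamped(self, p):
        st = sticky_capture(self._end_state(p, 29.0), p)
        assert (0, 0) in st.domain.clamps
        assert st.filaments[0].nodes[0, 0] == st.domain.face_pos[0]

    def test_end_beyond_30nm_is_not(self, p):
        st = sticky_capture(self._end_state(p, 31.0), p)
        assert st.domain.clamps == {}

    def test_idempotent(self, p):
        st = sticky_capture(self._end_state(p, 10.0), p)
        snapshot = dict(st.domain.clamps)
        rest = st.filaments[0].seg_r0.copy()
        st = sticky_capture(st, p)
        assert st.domain.clamps == snapshot
        assert np.array_equal(st.filaments[0].seg_r0, rest)

    def test_capture_injects_no_tension(self, p):
        from actonet.mechanics import extension_forces
        st = sticky_capture(self._end_state(p, 20.0), p)
        acc = extension_forces(st, p)
        assert np.abs(acc.force).max() < 1e-9


class TestFaceStress:
    def test_no_clamps_zero_stress(self, p):
        st = self_contained = _state_with(
            [Filament(np.array([[0.0, 0, 0], [140.0, 0, 0]]))], p)
        assert face_stress(self_contained, 0, p) == 0.0

    def test_single_clamped_spring(self, p):
        W = 2000.0
        delta = 15.0
        nodes = np.array([[-W / 2, 0, 0], [-W / 2 + p.r0_A + delta, 0, 0]])
        f = Filament(nodes)
        f.clamped[0] = True
        st = _state_with([f], p, W_nm=W)
        st.domain.clamps[(0, 0)] = 0
        ks = p.kappa_s_A * 1e3
        area = W * W
        expected = ks * delta / area * 1e6      # Pa, contractile positive
        assert face_stress(st, 0, p) == pytest.approx(expected, rel=1e-9)
        assert face_stress(st, 1, p) == 0.0

    def test_opposing_faces_balance(self, p):
        # one filament clamped on both x faces, uniformly pre-stretched
        W = 6.5 * p.r0_A          # 6 bonds stretched to ~151 nm each
        x = np.linspace(-W / 2, W / 2, 7)
        f = Filament(np.column_stack([x, np.zeros(7), np.zeros(7)]))
        f.clamped[:] = True
        st = _state_with([f], p, W_nm=W)
        st.domain.clamps = {(0, 0): 0, (0, 1): 1}
        s_lo = face_stress(st, 0, p)
        s_hi = face_stress(st, 1, p)
        assert s_lo == pytest.approx(s_hi, rel=1e-9)
        assert s_lo > 0      # stretched -> contractile


class TestUpdateFaces:
    def test_zero_stress_no_motion(self, p):
        st = _state_with([Filament(np.array([[0.0, 0, 0], [140.0, 0, 0]]))],
                         p)
        before = st.domain.face_pos.copy()
        update_faces(st, p, sigma_Pa=np.zeros(6))
        assert np.array_equal(st.domain.face_pos, before)

    def test_steady_strain_equals_sigma_over_E(self, p):
        st = _state_with([Filament(np.array([[0.0, 0, 0], [140.0, 0, 0]]))],
                         p, E=2000.0)
        sigma = np.array([40.0, 40.0, 0, 0, 0, 0])
        update_faces(st, p, sigma_Pa=sigma)
        W0 = st.domain.W0
        widths = st.domain.widths()
        strain = (W0 - widths[0]) / W0
        assert strain == pytest.approx(40.0 / 2000.0, rel=1e-6)

    def test_rigid_substrate_limit(self, p):
        st = _state_with([Filament(np.array([[0.0, 0, 0], [140.0, 0, 0]]))],
                         p, E=1e12)
        update_faces(st, p, sigma_Pa=np.full(6, 100.0))
        assert np.allclose(st.domain.widths(), st.domain.W0)

    def test_face_crossing_detected(self, p):
        st = _state_with([Filament(np.array([[0.0, 0, 0], [140.0, 0, 0]]))],
                         p, E=10.0)
        with pytest.raises(FaceCrossingError):
            update_faces(st, p, sigma_Pa=np.full(6, 100.0))

    def test_anchors_translate_with_their_face(self, p):
        W = 2000.0
        nodes = np.array([[-W / 2, 0, 0], [-W / 2 + p.r0_A, 0, 0]])
        f = Filament(nodes)
        f.clamped[0] = True
        st = _state_with([f], p, W_nm=W, E=1000.0)
        st.domain.clamps[(0, 0)] = 0
        update_faces(st, p, sigma_Pa=np.array([50.0, 0, 0, 0, 0, 0]))
        assert st.filaments[0].nodes[0, 0] == pytest.approx(
            st.domain.face_pos[0])


class TestProbeStiffness:
    def test_spanning_spring_matches_composite_modulus(self, p):
        """A filament clamped across one axis is a chain of n springs; the
        probe must recover E_n = (kappa_s/n) * W0 / A within 2%."""
        n_seg = 6
        W = n_seg * p.r0_A
        x = np.linspace(-W / 2, W / 2, n_seg + 1)
        f = Filament(np.column_stack([x, np.zeros(n_seg + 1),
                                      np.zeros(n_seg + 1)]))
        f.clamped[:] = True
        st = _state_with([f], p, W_nm=W)
        st.domain.clamps = {(0, 0): 0, (0, 1): 1}
        E_n, phase = probe_stiffness(st, p, amplitude_nm=20.0, cycles=3,
                                     freq_hz=0.5, axis=0)
        ks = p.kappa_s_A * 1e3
        expected = (ks / n_seg) * W / (W * W) * 1e6
        assert E_n == pytest.approx(expected, rel=0.02)
        assert abs(phase) < 0.1          # purely elastic response

    def test_targets_are_symmetric(self, p):
        dom = DomainBoundary.cube(1000.0, 100.0, False)
        tgt = face_targets(dom, np.full(6, 10.0))
        assert np.allclose(tgt[1::2], -tgt[0::2])
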