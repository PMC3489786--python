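import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from actonet import mechanics
from actonet.engine import Engine, InstabilityError
from actonet.fixtures import make_single_filament
from actonet.mechanics import min_distance, segment_distance
from conftest import crooked_state
from helpers import (brute_force_segment_distance, check_force_is_gradient,
                     measure_com_diffusion)


# ---------------------------------------------------------------------------
# conservative terms are exact gradients (the master oracle)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("term", ["extension", "bending", "repulsion",
                                  "total"])
def test_force_equals_minus_numerical_gradient(p, term):
    st = crooked_state(p, seed=3)
    # push two filaments into contact so repulsion is non-trivial
    st.filaments[1].nodes[:, 1] -= 157.0
    rel = check_force_is_gradient(st, p, term)
    assert rel < 1e-6


def test_rest_state_has_zero_force_and_energy(p):
    st = make_single_filament(8, p=p)
    acc = mechanics.total_forces(st, p)
    assert np.abs(acc.force).max() == pytest.approx(0.0, abs=1e-9)
    assert acc.energy_extension == 0.0
    assert acc.energy_bending == 0.0


def test_stretched_segment_hooke_forces(p):
    st = make_single_filament(2, p=p)
    delta = 12.0
    st.filaments[0].nodes[1, 0] += delta
    acc = mechanics.extension_forces(st, p)
    ks = p.kappa_s_A * 1e3            # pN/nm
    assert acc.force[1, 0] == pytest.approx(-ks * delta, rel=1e-12)
    assert acc.force[0, 0] == pytest.approx(ks * delta, rel=1e-12)
    assert acc.energy_extension == pytest.approx(0.5 * ks * delta ** 2)


def test_straight_filament_has_zero_bending_force(p):
    st = make_single_filament(10, p=p)
    acc = mechanics.bending_forces(st, p)
    assert np.abs(acc.force).max() < 1e-9


def test_net_force_is_zero_without_clamps(p):
    st = crooked_state(p, seed=9)
    st.filaments[1].nodes[:, 1] -= 157.0
    F, _ = Engine(st, p, noise=False, det_limit_frac=2.0).compute_forces()
    assert np.abs(F.sum(axis=0)).max() < 1e-9


# ---------------------------------------------------------------------------
# segment-segment minimum distance
# ---------------------------------------------------------------------------

class TestMinDistance:
    def test_parallel_offset(self):
        d, (s, t) = min_distance((np.zeros(3), np.array([1.0, 0, 0])),
                                 (np.array([0.0, 2, 0]),
                                  np.array([1.0, 2, 0])))
        assert d == pytest.approx(2.0)

    def test_perpendicular_crossing(self):
        d, _ = min_distance((np.array([-1.0, 0, 0]), np.array([1.0, 0, 0])),
                            (np.array([0.0, -1, 0]), np.array([0.0, 1, 0])))
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_endpoint_case(self):
        d, (s, t) = min_distance((np.zeros(3), np.array([1.0, 0, 0])),
                                 (np.array([3.0, 4, 0]),
                                  np.array([5.0, 4, 0])))
        assert d == pytest.approx(np.hypot(2, 4))
        assert (s, t) == (1.0, 0.0)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(hst.integers(0, 10 ** 6))
    def test_matches_dense_sampling(self, seed):
        rng = np.random.default_rng(seed)
        a1, b1, a2, b2 = rng.uniform(-100, 100, (4, 3))
        d, _, _ = segment_distance(a1, b1, a2, b2)
        ref = brute_force_segment_distance(a1, b1, a2, b2)
        assert d == pytest.approx(ref, abs=1e-3 * max(ref, 1.0))
        assert d <= ref + 1e-9   # exact solution can only be smaller


def test_repulsion_vanishes_at_contact_threshold(p):
    from actonet.network import DomainBoundary, Filament, NetworkState
    n = 5
    x = np.arange(n) * p.r0_A
    f0 = Filament(np.column_stack([x, np.zeros(n), np.zeros(n)]))
    f1 = Filament(np.column_stack([x, np.full(n, p.r_c), np.zeros(n)]))
    st = NetworkState({0: f0, 1: f1}, {},
                      DomainBoundary.cube(8000.0, p.E, False))
    acc = mechanics.repulsive_forces(st, p)
    assert np.abs(acc.force).max() == pytest.approx(0.0, abs=1e-9)
    st.filaments[1].nodes[:, 1] = 0.5 * p.r_c    # overlapping
    acc = mechanics.repulsive_forces(st, p)
    assert acc.energy_repulsion > 0
    assert np.abs(acc.force.sum(axis=0)).max() < 1e-9   # Newton's third law


def test_repulsion_lever_rule_at_midpoint(p):
    from actonet.network import DomainBoundary, Filament, NetworkState
    L = p.r0_A
    f0 = Filament(np.array([[-L / 2, 0, 0], [L / 2, 0, 0]]))
    # crossing at f0's midpoint, 0.5 r_c below
    f1 = Filament(np.array([[0, -L / 2, 0.5 * p.r_c],
                            [0, L / 2, 0.5 * p.r_c]]))
    st = NetworkState({0: f0, 1: f1}, {},
                      DomainBoundary.cube(10 * L, p.E, False))
    F = mechanics.repulsive_forces(st, p).force
    assert F[0, 2] == pytest.approx(F[1, 2], rel=1e-9)   # equal half-forces
    assert F[0, 2] < 0 < F[2, 2]


# ---------------------------------------------------------------------------
# thermal forces and integration
# ---------------------------------------------------------------------------

def test_thermal_force_zero_at_zero_temperature(p, rng):
    st = make_single_filament(4, p=p)
    acc = mechanics.thermal_forces(st, p.replace(T=1e-300), rng)
    assert np.abs(acc.force).max() < 1e-100


def test_thermal_force_statistics(p, rng):
    st = make_single_filament(2, p=p)
    draws = np.array([mechanics.thermal_forces(st, p, rng).force
                      for _ in range(4000)])
    var_target = 2 * p.kBT_pNnm * (p.zeta_per_segment * 1e3) / p.dt
    se = np.sqrt(var_target / draws.size)
    assert abs(draws.mean()) < 4 * se
    assert draws.var() == pytest.approx(var_target, rel=0.1)


def test_free_bead_diffusion_obeys_einstein_relation(p):
    # centre of mass of a free two-bead filament: D = kBT / (2 zeta)
    D = measure_com_diffusion(p, n_windows=1500, steps_per_window=50)
    zeta = p.zeta_per_segment * 1e3
    assert D == pytest.approx(p.kBT_pNnm / (2 * zeta), rel=0.05)


def test_overdamped_spring_relaxation_matches_closed_form(p):
    # two free beads joined by one spring relax with rate 2 kappa / zeta
    pf = p.replace(dt=1e-5)
    st = make_single_filament(2, p=pf)
    delta0 = 10.0
    st.filaments[0].nodes[1, 0] += delta0
    ks = pf.kappa_s_A * 1e3
    zeta = pf.zeta_per_segment * 1e3
    tau = zeta / (2 * ks)
    n = int(round(tau / pf.dt))
    st = mechanics.euler_step(st, pf, n_steps=n)
    delta = (st.filaments[0].nodes[1, 0] - st.filaments[0].nodes[0, 0]
             - pf.r0_A)
    assert delta == pytest.approx(delta0 * np.exp(-n * pf.dt / tau),
                                  rel=0.01)


def test_euler_step_zero_force_leaves_positions(p):
    st = make_single_filament(5, p=p)
    before = st.filaments[0].nodes.copy()
    mechanics.euler_step(st, p, n_steps=10)
    assert np.array_equal(st.filaments[0].nodes, before)


def test_clamped_node_does_not_move(p):
    st = make_single_filament(3, p=p)
    # translate the filament so its first node sits on the -x face
    st.filaments[0].nodes[:, 0] += (st.domain.face_pos[0]
                                    - st.filaments[0].nodes[0, 0])
    st.filaments[0].clamped[0] = True
    st.domain.clamps[(0, 0)] = 0
    st.filaments[0].nodes[1, 0] += 3.0           # load the clamped bond
    anchor = st.filaments[0].nodes[0].copy()
    mechanics.euler_step(st, p, n_steps=50)
    assert np.array_equal(st.filaments[0].nodes[0], anchor)


def test_instability_detected_on_violent_stretch(p):
    st = make_single_filament(2, p=p)
    st.filaments[0].nodes[1, 0] += 30 * p.r0_A
    with pytest.raises(InstabilityError):
        mechanics.euler_step(st, p, n_steps=1)


def test_hinge_angle_equipartition(p):
    """Thermal variance of a filament hinge angle matches 2 kBT / kappa_b
    (two transverse modes)."""
    from actonet.params import drag_coefficient
    mu = 8.6e-4
    pf = p.replace(mu=mu, zeta_per_segment=drag_coefficient(mu, p.r0_A),
                   dt=2e-6, kappa_s_A=1e-5, kappa_r=1e-6)
    st = make_single_filament(3, p=pf)
    en = Engine(st, pf, noise=True, det_limit_frac=2.0)
    rng = np.random.default_rng(11)
    samples = []
    for k in range(2000):
        en.window(100, int(rng.integers(2 ** 31)))
        u = en.pos[0] - en.pos[1]
        v = en.pos[2] - en.pos[1]
        c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        samples.append(np.arccos(np.clip(c, -1, 1)))
    dev2 = ((np.pi - np.array(samples[200:])) ** 2).mean()
    kb = pf.kappa_b_A * 1e21
    assert dev2 == pytest.approx(2 * pf.kBT_pNnm / kb, rel=0.10)
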