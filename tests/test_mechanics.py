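"""Force fields: potential-gradient consistency, trivial values, balance,
integration, and the compiled-kernel equivalence."""

import numpy as np
import pytest

from ecmdyn import mechanics as M
from ecmdyn.config import SimConfig, desk_config
from ecmdyn.integrate import Stepper
from ecmdyn.network import generate_network

from conftest import add_crosslink, make_chain


def small_config(**kw):
    params = dict(l_xy=20.0, l_z=20.0, fiber_count=0, kappa_e=10.0, kappa_b=1.0,
                  crosslink_stiffness=5.0, repulsion_stiffness=50.0, dt=1e-4)
    params.update(kw)
    return SimConfig(**params)


# ---------------------------------------------------------------- stretch
def test_stretch_zero_extension_zero_force():
    net = make_chain([[0, 0, 0], [1, 0, 0]])
    f, e = M.stretch_forces(net, small_config())
    assert np.allclose(f, 0.0)
    assert e == 0.0


def test_stretch_direct_substitution():
    """kappa_e = 10 pN/um at 0.2 um extension: |F| = 2 pN, U = 0.2 pN·um."""
    net = make_chain([[0, 0, 0], [1.2, 0, 0]])
    net.rest_length[:] = 1.0
    f, e = M.stretch_forces(net, small_config())
    assert np.linalg.norm(f[0]) == pytest.approx(2.0)
    assert f[0, 0] == pytest.approx(2.0)   # tensile: node pulled toward partner
    assert e == pytest.approx(0.2)


def test_stretch_degenerate_segment_raises():
    net = make_chain([[0, 0, 0], [1, 0, 0]])
    net.positions[1] = net.positions[0]
    with pytest.raises(M.DegenerateGeometryError):
        M.stretch_forces(net, small_config())


# ------------------------------------------------------------------ bend
def test_bend_collinear_zero():
    net = make_chain([[0, 0, 0], [1, 0, 0], [2, 0, 0]])
    f, e = M.bend_forces(net, small_config())
    assert np.allclose(f, 0.0)
    assert e == 0.0


def test_bend_right_angle_energy():
    net = make_chain([[0, 0, 0], [1, 0, 0], [1, 1, 0]])
    _, e = M.bend_forces(net, small_config(kappa_b=1.0))
    assert e == pytest.approx(0.5 * (np.pi / 2) ** 2)


def test_bend_triplet_zero_net_force_and_torque():
    rng = np.random.default_rng(3)
    pts = rng.uniform(2, 8, (3, 3))
    net = make_chain(pts)
    f, _ = M.bend_forces(net, small_config())
    assert np.allclose(f.sum(axis=0), 0.0, atol=1e-12)
    torque = np.cross(net.positions, f).sum(axis=0)
    assert np.allclose(torque, 0.0, atol=1e-10)


def test_bend_folded_raises():
    net = make_chain([[0, 0, 0], [1, 0, 0], [0, 1e-9, 0]])
    with pytest.raises(M.DegenerateGeometryError):
        M.bend_forces(net, small_config())


# ------------------------------------------------------------- crosslink
def test_crosslink_rest_separation_no_force():
    net = make_two_parallel(gap=0.04)  # separation exactly 2*arm_length
    f, e = M.crosslink_forces(net, small_config())
    assert np.allclose(f, 0.0, atol=1e-12)
    assert net.cl_tension[0] == pytest.approx(0.0, abs=1e-9)
    assert e == pytest.approx(0.0, abs=1e-12)


def make_two_parallel(gap, crosslinked=True):
    """Two parallel unit segments offset by ``gap``, optionally joined by a
    midpoint crosslink (crosslinked pairs carry no volume exclusion)."""
    pos = np.array([[5, 5, 5], [6, 5, 5], [5, 5 + gap, 5], [6, 5 + gap, 5]], float)
    net = make_chain(pos[:2])
    net.positions = pos
    net.fixed = np.zeros(4, bool)
    net.seg_nodes = np.array([[0, 1], [2, 3]], dtype=np.intp)
    net.seg_fiber = np.array([0, 1], dtype=np.intp)
    net.rest_length = np.ones(2)
    net.fiber_nodes = [np.array([0, 1]), np.array([2, 3])]
    net._triplets = None
    if crosslinked:
        add_crosslink(net, 0, 1, 0.5, 0.5)
    return net


def test_crosslink_compressed_tension_clamped_to_zero():
    """Only positive stretching forces feed the kinetics."""
    net = make_two_parallel(gap=0.01)  # closer than the 0.04 rest length
    f, _ = M.crosslink_forces(net, small_config())
    assert net.cl_tension[0] == 0.0
    assert not np.allclose(f, 0.0)  # compression still pushes them apart


def test_crosslink_lever_distribution_reproduces_point_force_and_torque():
    rng = np.random.default_rng(7)
    net = make_two_parallel(gap=0.3)
    net.cl_t[0] = [0.3, 0.8]
    cfg = small_config()
    f, _ = M.crosslink_forces(net, cfg)
    xa, xb = net.crosslink_points()
    d = (xb - xa)[0]
    ext = np.linalg.norm(d) - net.cl_rest[0]
    fvec = cfg.crosslink_stiffness * ext * d / np.linalg.norm(d)
    # resultant on fiber 1 equals the point force at the attachment
    res = f[0] + f[1]
    assert np.allclose(res, fvec, rtol=1e-12)
    # torque about origin equals x_a × F
    torque = np.cross(net.positions[0], f[0]) + np.cross(net.positions[1], f[1])
    assert np.allclose(torque, np.cross(xa[0], fvec), rtol=1e-9, atol=1e-12)


# ------------------------------------------------------------- repulsion
def test_repulsion_zero_beyond_contact():
    net = make_two_parallel(gap=0.2, crosslinked=False)  # 2x diameter
    f, e = M.repulsion_forces(net, small_config())
    assert np.allclose(f, 0.0)
    assert e == 0.0


def test_repulsion_antisymmetric_pair():
    net = make_two_parallel(gap=0.05, crosslinked=False)  # overlapping
    f, e = M.repulsion_forces(net, small_config())
    assert e > 0
    assert np.allclose(f.sum(axis=0), 0.0, atol=1e-12)
    assert np.allclose(f[0] + f[1], -(f[2] + f[3]), atol=1e-12)


def test_repulsion_energy_decreases_under_quasistatic_separation():
    cfg = small_config()
    energies = []
    for gap in np.linspace(0.02, 0.12, 8):
        net = make_two_parallel(gap=gap, crosslinked=False)
        _, e = M.repulsion_forces(net, cfg)
        energies.append(e)
    assert all(a >= b - 1e-15 for a, b in zip(energies, energies[1:]))
    assert energies[-1] == 0.0


# ------------------------------------------------- gradient consistency
def test_forces_equal_negative_numerical_gradient(desk_cfg, desk_net):
    """All potential-derived terms match central finite differences to
    relative error < 1e-4 on a perturbed random network."""
    net = desk_net.copy()
    rng = np.random.default_rng(0)
    net.positions = net.positions + rng.normal(0, 0.05, net.positions.shape)
    net.positions[:, 2] = np.clip(net.positions[:, 2], 0, net.l_z)
    pairs = M.repulsion_pairs(net, desk_cfg)

    def energy():
        _, es = M.network_forces(net, desk_cfg, repulsion_pair_list=pairs)
        return sum(es.values())

    fs, _ = M.network_forces(net, desk_cfg, repulsion_pair_list=pairs)
    F = fs.total()
    pos = net.positions.copy()
    h = 1e-6
    nodes = rng.choice(net.n_nodes, 12, replace=False)
    for node in nodes:
        for k in range(3):
            for sign in (1, -1):
                p = pos.copy()
                p[node, k] += sign * h
                net.positions = p
                if sign == 1:
                    ep = energy()
                else:
                    em = energy()
            fd = -(ep - em) / (2 * h)
            scale = max(np.abs(F[node]).max(), 1.0)
            assert abs(fd - F[node, k]) / scale < 1e-4
    net.positions = pos


def test_global_internal_force_balance(desk_cfg, desk_net):
    """Newton's third law: internal forces sum to zero over all nodes."""
    fs, _ = M.network_forces(desk_net, desk_cfg)
    total = fs.total()
    assert np.abs(total.sum(axis=0)).max() < 1e-8 * max(np.abs(total).max(), 1.0)


def test_kernel_matches_reference_forces(desk_cfg, desk_net):
    """The fused compiled kernel reproduces the numpy reference force field."""
    net = desk_net.copy()
    rng = np.random.default_rng(1)
    net.positions = net.positions + rng.normal(0, 0.02, net.positions.shape)
    net.positions[:, 2] = np.clip(net.positions[:, 2], 0, net.l_z)
    st = Stepper(net, desk_cfg)
    st.compute_forces()
    fs, es = M.network_forces(net, desk_cfg, repulsion_pair_list=np.asarray(st.pairs))
    ref = fs.total()
    assert np.abs(st.forces - ref).max() < 1e-8 * max(np.abs(ref).max(), 1.0)
    assert st.energy == pytest.approx(sum(es.values()), rel=1e-9)


# ------------------------------------------------------------ integration
def test_euler_zero_force_no_motion():
    net = make_chain([[5, 5, 5], [6, 5, 5]])
    cfg = small_config()
    fs = M.ForceSet(2)
    pos0 = net.positions.copy()
    M.euler_step(net, fs, cfg)
    assert np.allclose(net.positions, pos0)


def test_euler_constant_force_closed_form():
    """n steps under constant F displace exactly n·F·dt/zeta."""
    net = make_chain([[5.0, 5.0, 5.0], [6.0, 5.0, 5.0]])
    net.rest_length[:] = 10.0  # slack: no restoring force matters below
    cfg = small_config(dt=1e-3, zeta=2.0, max_step_displacement=1.0)
    fs = M.ForceSet(2)
    f = np.zeros((2, 3))
    f[:, 2] = 4.0
    fs.add("external", f)
    p0 = net.positions.copy()
    for _ in range(25):
        M.euler_step(net, fs, cfg)
    assert np.allclose(net.positions[:, 2] - p0[:, 2], 25 * 4.0 * 1e-3 / 2.0)


def test_fixed_node_never_moves():
    net = make_chain([[5, 5, 5], [6, 5, 5]], fixed=[1])
    cfg = small_config(max_step_displacement=10.0)
    fs = M.ForceSet(2)
    f = np.zeros((2, 3))
    f[:, 0] = 1000.0  # 1 nN
    fs.add("external", f)
    p0 = net.positions.copy()
    M.euler_step(net, fs, cfg)
    assert np.allclose(net.positions[1], p0[1])
    assert not np.allclose(net.positions[0], p0[0])


def test_step_cap_raises():
    net = make_chain([[5, 5, 5], [6, 5, 5]])
    cfg = small_config(dt=1.0, k_u0=0.01)
    fs = M.ForceSet(2)
    f = np.full((2, 3), 100.0)
    fs.add("external", f)
    with pytest.raises(M.StepTooLargeError):
        M.euler_step(net, fs, cfg)


def test_overdamped_spring_matches_analytic_relaxation():
    """A stretched spring with one pinned end relaxes as exp(-kappa t/zeta)
    within 2% of the continuous solution for dt·kappa/zeta <= 0.01."""
    kappa, zeta, dt = 10.0, 1.0, 1e-3  # dt*kappa/zeta = 0.01
    cfg = small_config(kappa_e=kappa, zeta=zeta, dt=dt, repulsion_stiffness=0.0)
    net = make_chain([[5.0, 5.0, 5.0], [6.1, 5.0, 5.0]], fixed=[0])
    net.rest_length[:] = 1.0
    n_steps = 200
    for _ in range(n_steps):
        f, _ = M.stretch_forces(net, cfg)
        fs = M.ForceSet(2)
        fs.add("stretch", f)
        M.euler_step(net, fs, cfg)
    dr = (net.positions[1, 0] - net.positions[0, 0]) - 1.0
    expected = 0.1 * np.exp(-kappa * n_steps * dt / zeta)
    assert dr == pytest.approx(expected, rel=0.02)


def test_energy_nonincreasing_without_load_or_unbinding(desk_cfg, desk_net):
    """Unloaded, kinetics-frozen dynamics dissipate elastic energy."""
    net = desk_net.copy()
    st = Stepper(net, desk_cfg)
    energies = []
    for _ in range(150):
        st.compute_forces()
        energies.append(st.energy)
        st.advance()
    diffs = np.diff(energies)
    assert np.all(diffs <= 1e-9 * max(energies))
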