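"""Shared fixtures: tiny hand-built networks and cached desk-scale runs.

The qualitative remodeling properties need full load→relax protocols over
several parameter values and replicate seeds; those runs are expensive, so
they are computed once per session here and shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from ecmdyn.config import SimConfig, desk_config
from ecmdyn.network import FiberNetwork, generate_network

REPLICATES = 3


def make_chain(
    positions,
    l_xy: float = 20.0,
    l_z: float = 20.0,
    fixed=None,
    diameter: float = 0.1,
    arm: float = 0.02,
) -> FiberNetwork:
    """Single straight-chain fiber through the given node positions."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    chain = np.arange(n, dtype=np.intp)
    seg_nodes = np.stack([chain[:-1], chain[1:]], axis=1)
    rest = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    fx = np.zeros(n, dtype=bool)
    if fixed is not None:
        fx[list(fixed)] = True
    return FiberNetwork(
        positions=positions,
        fixed=fx,
        seg_nodes=seg_nodes,
        seg_fiber=np.zeros(n - 1, dtype=np.intp),
        rest_length=rest,
        fiber_nodes=[chain],
        diameter=diameter,
        arm_length=arm,
        l_xy=l_xy,
        l_z=l_z,
    )


def add_crosslink(net: FiberNetwork, seg_a: int, seg_b: int, t_a: float, t_b: float,
                  rest: float | None = None) -> FiberNetwork:
    net.cl_seg = np.vstack([net.cl_seg, [[seg_a, seg_b]]]).astype(np.intp)
    net.cl_t = np.vstack([net.cl_t, [[t_a, t_b]]])
    net.cl_bound = np.append(net.cl_bound, True)
    net.cl_tension = np.append(net.cl_tension, 0.0)
    net.cl_rest = np.append(net.cl_rest, 2.0 * net.arm_length if rest is None else rest)
    return net


@pytest.fixture(scope="session")
def desk_cfg() -> SimConfig:
    return desk_config()


@pytest.fixture(scope="session")
def desk_net(desk_cfg) -> FiberNetwork:
    """A freshly generated (un-relaxed) desk-scale network."""
    return generate_network(desk_cfg, seed=1)


@pytest.fixture(scope="session")
def relaxed_desk(desk_cfg):
    """One prestress-relaxed desk network (never mutated by tests)."""
    from ecmdyn.loading import prepare_network

    return prepare_network(desk_cfg, seed=1)


@pytest.fixture(scope="session")
def baseline_run(desk_cfg, relaxed_desk):
    """Full protocol at the reference condition (100 pN, 1x kinetics)."""
    from ecmdyn.loading import simulate

    return simulate(desk_cfg, seed=1, network=relaxed_desk)


# ---- cached sweeps for the qualitative remodeling properties ---------
@pytest.fixture(scope="session")
def force_sweep(desk_cfg):
    """Force axis at the reference kinetic condition (mechanosensitivity
    0.3x as in the headline loading-force study)."""
    from ecmdyn.analysis import parameter_sweep

    cfg = desk_cfg.replace(lam=0.3 * desk_cfg.lam)
    table, summary = parameter_sweep(cfg, "force", [2.0, 60.0, 600.0], replicates=REPLICATES)
    return table, summary


@pytest.fixture(scope="session")
def density_sweep(desk_cfg):
    """Crosslink-density axis at 60 pN with slow zero-force unbinding, so
    the fully crosslinked network survives loading nearly intact."""
    from ecmdyn.analysis import parameter_sweep

    cfg = desk_cfg.replace(force_per_site=60.0, k_u0=0.1 * desk_cfg.k_u0,
                           lam=0.3 * desk_cfg.lam)
    table, summary = parameter_sweep(
        cfg, "crosslink_density", [0.1, 0.3, 1.0], replicates=REPLICATES
    )
    return table, summary


@pytest.fixture(scope="session")
def lam_sweep(desk_cfg):
    """Mechanosensitivity axis (relative multipliers of the 1x baseline)."""
    from ecmdyn.analysis import parameter_sweep

    cfg = desk_cfg.replace(force_per_site=100.0)
    table, summary = parameter_sweep(cfg, "lam", [0.1, 1.0, 10.0], replicates=REPLICATES)
    return table, summary


@pytest.fixture(scope="session")
def continuum_baseline_pair():
    """Baseline viscoplastic solutions with and without plastic softening."""
    from ecmdyn.config import continuum_baseline
    from ecmdyn.continuum import solve_sphere

    cfg = continuum_baseline()
    return (
        (cfg, solve_sphere(cfg)),
        (cfg.replace(softening_enabled=False), solve_sphere(cfg.replace(softening_enabled=False))),
    )


@pytest.fixture(scope="session")
def continuum_elastic_solution():
    from ecmdyn.config import continuum_elastic
    from ecmdyn.continuum import solve_sphere

    cfg = continuum_elastic()
    return cfg, solve_sphere(cfg)
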