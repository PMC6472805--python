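"""Time-stepping driver shared by prestress relaxation and the load protocol.

Wraps the fused force kernel (:mod:`ecmdyn._kernels`) with neighbor-list
management and the external-load scatter, advancing the network in place.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .config import SimConfig
from .mechanics import StepTooLargeError, crosslinked_pair_keys, repulsion_pairs
from .network import FiberNetwork


class Stepper:
    """Advances a :class:`FiberNetwork` with the compiled force kernel.

    The per-term numpy implementations in :mod:`ecmdyn.mechanics` remain the
    reference; this driver is asserted equivalent to them in the tests.
    """

    def __init__(self, net: FiberNetwork, config: SimConfig):
        self.net = net
        self.config = config
        self.kappa_e = config.resolved_kappa_e()
        self.kappa_b = config.resolved_kappa_b()
        self.dt = config.resolved_dt()
        self.cap = config.resolved_step_cap()
        trips = net.bend_triplets()
        self._trip_i = np.ascontiguousarray(trips[:, 0])
        self._trip_j = np.ascontiguousarray(trips[:, 1])
        self._trip_k = np.ascontiguousarray(trips[:, 2])
        self._seg_a = np.ascontiguousarray(net.seg_nodes[:, 0])
        self._seg_b = np.ascontiguousarray(net.seg_nodes[:, 1])
        self._cl_sa = np.ascontiguousarray(net.cl_seg[:, 0]) if net.n_crosslinks else np.empty(0, dtype=np.intp)
        self._cl_sb = np.ascontiguousarray(net.cl_seg[:, 1]) if net.n_crosslinks else np.empty(0, dtype=np.intp)
        self._cl_ta = np.ascontiguousarray(net.cl_t[:, 0]) if net.n_crosslinks else np.empty(0)
        self._cl_tb = np.ascontiguousarray(net.cl_t[:, 1]) if net.n_crosslinks else np.empty(0)
        self.forces = np.zeros((net.n_nodes, 3))
        net.positions = np.ascontiguousarray(net.positions, dtype=float)
        net.cl_tension = np.zeros(net.n_crosslinks)
        self._excl_keys = crosslinked_pair_keys(net)
        self.pairs = repulsion_pairs(net, config)
        self._steps_since_rebuild = 0
        self.energy = np.nan

    def rebuild_neighbors(self) -> None:
        net = self.net
        cutoff = float(net.rest_length.max()) * 1.2 + net.diameter + self.config.neighbor_skin
        contact = net.diameter + self.config.neighbor_skin
        max_pairs = max(4 * net.n_segments, 1024)
        while True:
            pairs, count = _kernels.build_repulsion_pairs(
                net.positions, self._seg_a, self._seg_b, net.l_xy, net.l_z,
                cutoff, contact, max_pairs, self._excl_keys,
                np.int64(net.n_segments),
            )
            if count >= 0:
                break
            max_pairs *= 4
        self.pairs = pairs[:count]
        self._steps_since_rebuild = 0

    def compute_forces(self, external: np.ndarray | None = None) -> np.ndarray:
        """Fill ``self.forces`` with the total force; refreshes tensions and
        the cached total elastic energy."""
        net = self.net
        if self._steps_since_rebuild >= self.config.neighbor_rebuild_every:
            self.rebuild_neighbors()
        self.forces[:] = 0.0
        self.energy = _kernels.fused_forces(
            net.positions,
            self._seg_a,
            self._seg_b,
            net.rest_length,
            self.kappa_e,
            self._trip_i,
            self._trip_j,
            self._trip_k,
            self.kappa_b,
            self._cl_sa,
            self._cl_sb,
            self._cl_ta,
            self._cl_tb,
            net.cl_bound,
            net.cl_rest,
            self.config.crosslink_stiffness,
            np.ascontiguousarray(self.pairs[:, 0]) if len(self.pairs) else np.empty(0, dtype=np.intp),
            np.ascontiguousarray(self.pairs[:, 1]) if len(self.pairs) else np.empty(0, dtype=np.intp),
            net.diameter,
            self.config.repulsion_stiffness,
            self.config.repulsion_cap,
            net.l_xy,
            self.forces,
            net.cl_tension,
        )
        if external is not None:
            self.forces += external
        return self.forces

    def external_zone_forces(self, force_per_site: float, zone_depth: float,
                             per_fiber: bool = False) -> np.ndarray:
        """Filopodial zone loading as a per-node force array (−z pull)."""
        net = self.net
        ext = np.zeros((net.n_nodes, 3))
        mid_z = 0.5 * (net.positions[self._seg_a, 2] + net.positions[self._seg_b, 2])
        in_zone = mid_z < zone_depth
        if not np.any(in_zone):
            return ext
        idx = np.flatnonzero(in_zone)
        if per_fiber:
            fibers = net.seg_fiber[idx]
            counts = np.bincount(fibers)
            per_seg = force_per_site / counts[fibers]
        else:
            per_seg = np.full(len(idx), force_per_site)
        half = 0.5 * per_seg
        n = net.n_nodes
        ext[:, 2] -= np.bincount(self._seg_a[idx], weights=half, minlength=n)
        ext[:, 2] -= np.bincount(self._seg_b[idx], weights=half, minlength=n)
        return ext

    def advance(self) -> float:
        """One Euler step with the currently computed forces."""
        max_d = _kernels.euler_update(
            self.net.positions,
            self.forces,
            self.net.fixed,
            self.dt / self.config.zeta,
            self.net.l_xy,
            self.net.l_z,
            self.cap,
        )
        if max_d > self.cap:
            raise StepTooLargeError(
                f"max displacement {max_d:.3g} μm exceeds stability cap "
                f"{self.cap:.3g} μm; reduce dt or the applied force"
            )
        self._steps_since_rebuild += 1
        return max_d

    def max_free_force(self) -> float:
        """Largest unbalanced force on a mobile node; the wall-normal
        component of nodes pressed against a z boundary is constrained by
        the clamp and does not count as residual."""
        f = self.forces.copy()
        f[self.net.fixed] = 0.0
        z = self.net.positions[:, 2]
        at_floor = (z <= 1e-9) & (f[:, 2] < 0.0)
        at_top = (z >= self.net.l_z - 1e-9) & (f[:, 2] > 0.0)
        f[at_floor, 2] = 0.0
        f[at_top, 2] = 0.0
        return float(np.sqrt((f**2).sum(axis=1)).max()) if len(f) else 0.0
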