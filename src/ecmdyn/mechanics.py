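"""Internal forces of the fiber network and the overdamped Euler update.

All force terms derive from potentials: harmonic stretching of each segment,
harmonic bending of each interior fiber angle about the straight
configuration, a quadratic volume-exclusion overlap penalty between
non-adjacent segments, and harmonic crosslink springs between attachment
points.  The dynamics is athermal and overdamped: free nodes move by
(F/ζ)·Δt per step, fixed nodes never move, and x/y are wrapped periodically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import minimum_image, wrap_xy, segment_closest_points, midpoint_cell_pairs
from .config import SimConfig
from .network import FiberNetwork


class DegenerateGeometryError(RuntimeError):
    pass


class StepTooLargeError(RuntimeError):
    pass


@dataclass
class ForceSet:
    """Per-node force vectors partitioned by origin (pN)."""

    n_nodes: int
    components: dict = field(default_factory=dict)

    def add(self, name: str, forces: np.ndarray) -> None:
        if name in self.components:
            self.components[name] = self.components[name] + forces
        else:
            self.components[name] = forces

    def get(self, name: str) -> np.ndarray:
        return self.components.get(name, np.zeros((self.n_nodes, 3)))

    def total(self, include_external: bool = True) -> np.ndarray:
        out = np.zeros((self.n_nodes, 3))
        for name, f in self.components.items():
            if not include_external and name == "external":
                continue
            out += f
        return out


def _scatter_add(out: np.ndarray, idx: np.ndarray, vals: np.ndarray) -> None:
    n = len(out)
    for k in range(3):
        out[:, k] += np.bincount(idx, weights=vals[:, k], minlength=n)


# ----------------------------------------------------------------------
def stretch_forces(net: FiberNetwork, config: SimConfig):
    """Axial harmonic forces U_s = ½ κ_e Δr² per segment.

    Returns (forces (N,3), energy).  Raises on coincident segment nodes
    (degenerate direction).
    """
    kappa = config.resolved_kappa_e()
    d = net.segment_vectors()
    length = np.linalg.norm(d, axis=1)
    if np.any(length < 1e-9):
        raise DegenerateGeometryError("zero-length segment (coincident nodes)")
    dr = length - net.rest_length
    fmag = kappa * dr
    fvec = (fmag / length)[:, None] * d  # pulls a toward b when stretched
    forces = np.zeros((net.n_nodes, 3))
    _scatter_add(forces, net.seg_nodes[:, 0], fvec)
    _scatter_add(forces, net.seg_nodes[:, 1], -fvec)
    energy = float(0.5 * kappa * np.sum(dr**2))
    return forces, energy


def bend_forces(net: FiberNetwork, config: SimConfig):
    """Angular harmonic forces U_b = ½ κ_b Δθ² per interior fiber node.

    Δθ is the angle between consecutive segment directions (zero when the
    fiber is straight).  Each triplet contributes zero net force and zero net
    torque.  Raises on an exactly folded triplet (bend plane undefined).
    """
    kappa = config.resolved_kappa_b()
    trips = net.bend_triplets()
    forces = np.zeros((net.n_nodes, 3))
    if len(trips) == 0:
        return forces, 0.0
    pi_, pj, pk = (net.positions[trips[:, m]] for m in range(3))
    a = minimum_image(pj - pi_, net.l_xy)
    b = minimum_image(pk - pj, net.l_xy)
    la = np.linalg.norm(a, axis=1)
    lb = np.linalg.norm(b, axis=1)
    if np.any(la < 1e-9) or np.any(lb < 1e-9):
        raise DegenerateGeometryError("zero-length segment in bend triplet")
    ah = a / la[:, None]
    bh = b / lb[:, None]
    cos_t = np.clip(np.einsum("ij,ij->i", ah, bh), -1.0, 1.0)
    theta = np.arccos(cos_t)
    if np.any(theta > np.pi - 1e-6):
        raise DegenerateGeometryError("folded fiber triplet (bend plane undefined)")
    sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
    # θ/sinθ is smooth at θ=0; switch to its series value where sinθ underflows
    ratio = np.where(sin_t > 1e-8, theta / np.where(sin_t > 1e-8, sin_t, 1.0), 1.0)
    g = kappa * ratio
    f_i = -(g / la)[:, None] * (bh - cos_t[:, None] * ah)
    f_k = (g / lb)[:, None] * (ah - cos_t[:, None] * bh)
    f_j = -(f_i + f_k)
    _scatter_add(forces, trips[:, 0], f_i)
    _scatter_add(forces, trips[:, 1], f_j)
    _scatter_add(forces, trips[:, 2], f_k)
    energy = float(0.5 * kappa * np.sum(theta**2))
    return forces, energy


# ----------------------------------------------------------------------
def crosslinked_pair_keys(net: FiberNetwork) -> np.ndarray:
    """Sorted encoded keys (lo·S + hi) of segment pairs joined by a
    crosslink; such bonded pairs are excluded from volume exclusion — the
    crosslinker occupies the contact, and letting repulsion fight the
    crosslink spring would build permanent frustrated prestress."""
    if net.n_crosslinks == 0:
        return np.empty(0, dtype=np.int64)
    lo = np.minimum(net.cl_seg[:, 0], net.cl_seg[:, 1]).astype(np.int64)
    hi = np.maximum(net.cl_seg[:, 0], net.cl_seg[:, 1]).astype(np.int64)
    return np.unique(lo * np.int64(net.n_segments) + hi)


def repulsion_pairs(net: FiberNetwork, config: SimConfig) -> np.ndarray:
    """Shortlist of non-adjacent segment pairs within contact + skin distance.

    Candidates come from a spatial hash over segment midpoints; pairs sharing
    a node (consecutive segments of one fiber) and crosslinked (bonded)
    pairs are excluded.
    """
    mids = net.segment_midpoints()
    # two segments can touch only if midpoints are within half-length sums
    cutoff = float(net.rest_length.max()) * 1.2 + net.diameter + config.neighbor_skin
    cand = midpoint_cell_pairs(mids, cutoff, net.l_xy, net.l_z)
    if len(cand) == 0:
        return cand
    sn = net.seg_nodes
    shares_node = (
        (sn[cand[:, 0], 0][:, None] == sn[cand[:, 1]]).any(axis=1)
        | (sn[cand[:, 0], 1][:, None] == sn[cand[:, 1]]).any(axis=1)
    )
    cand = cand[~shares_node]
    excl = crosslinked_pair_keys(net)
    if len(excl) and len(cand):
        keys = cand[:, 0].astype(np.int64) * np.int64(net.n_segments) + cand[:, 1]
        pos = np.searchsorted(excl, keys)
        pos = np.minimum(pos, len(excl) - 1)
        cand = cand[excl[pos] != keys]
    if len(cand) == 0:
        return cand
    p1 = net.positions[sn[cand[:, 0], 0]]
    d1 = minimum_image(net.positions[sn[cand[:, 0], 1]] - p1, net.l_xy)
    p2 = net.positions[sn[cand[:, 1], 0]]
    d2 = minimum_image(net.positions[sn[cand[:, 1], 1]] - p2, net.l_xy)
    dist, _, _, _ = segment_closest_points(p1, d1, p2, d2, net.l_xy)
    return cand[dist < net.diameter + config.neighbor_skin]


def repulsion_forces(net: FiberNetwork, config: SimConfig, pairs: np.ndarray | None = None):
    """Soft volume exclusion between segments closer than one fiber diameter.

    Quadratic overlap penalty: |F| = k_rep·(d_contact − dist), continuous and
    zero at/beyond contact, saturating at ``repulsion_cap`` for deep overlaps.
    Forces act along the closest-approach direction and are distributed to
    segment end nodes with lever-arm weights, so the pair exchange is exactly
    antisymmetric.
    """
    if pairs is None:
        pairs = repulsion_pairs(net, config)
    forces = np.zeros((net.n_nodes, 3))
    if len(pairs) == 0:
        return forces, 0.0
    sn = net.seg_nodes
    p1 = net.positions[sn[pairs[:, 0], 0]]
    d1 = minimum_image(net.positions[sn[pairs[:, 0], 1]] - p1, net.l_xy)
    p2 = net.positions[sn[pairs[:, 1], 0]]
    d2 = minimum_image(net.positions[sn[pairs[:, 1], 1]] - p2, net.l_xy)
    dist, t, s, sep = segment_closest_points(p1, d1, p2, d2, net.l_xy)
    contact = net.diameter
    overlap = contact - dist
    active = overlap > 0
    if not np.any(active):
        return forces, 0.0
    pairs = pairs[active]
    t = t[active]
    s = s[active]
    sep = sep[active]
    dist = dist[active]
    overlap = overlap[active]
    k = config.repulsion_stiffness
    cap_depth = config.repulsion_cap / k if k > 0 else np.inf
    fmag = k * np.minimum(overlap, cap_depth)
    safe = dist > 1e-9
    nhat = np.zeros_like(sep)
    nhat[safe] = sep[safe] / dist[safe, None]
    nhat[~safe] = np.array([0.0, 0.0, 1.0])  # arbitrary but fixed for full overlap
    f1 = -fmag[:, None] * nhat  # pushes segment 1 away from segment 2
    _scatter_add(forces, sn[pairs[:, 0], 0], (1.0 - t)[:, None] * f1)
    _scatter_add(forces, sn[pairs[:, 0], 1], t[:, None] * f1)
    _scatter_add(forces, sn[pairs[:, 1], 0], -(1.0 - s)[:, None] * f1)
    _scatter_add(forces, sn[pairs[:, 1], 1], -s[:, None] * f1)
    quad = np.minimum(overlap, cap_depth)
    energy = float(np.sum(0.5 * k * quad**2 + config.repulsion_cap * np.maximum(overlap - cap_depth, 0.0)))
    return forces, energy


# ----------------------------------------------------------------------
def crosslink_forces(net: FiberNetwork, config: SimConfig):
    """Linear-spring crosslink forces; updates the per-crosslink tension cache.

    Each bound crosslink is a spring of rest length 2·arm_length (or the
    geometry it rebound at) between its attachment points; the point forces
    are distributed to segment end nodes with lever-arm weights of the arc
    coordinate, which reproduces both the resultant force and its torque.
    The cached tension is max(0, extensional force): compressed crosslinks
    contribute nothing to the unbinding kinetics.
    """
    forces = np.zeros((net.n_nodes, 3))
    net.cl_tension = np.zeros(net.n_crosslinks)
    if net.n_crosslinks == 0:
        return forces, 0.0
    xa, xb = net.crosslink_points()
    d = xb - xa
    length = np.linalg.norm(d, axis=1)
    ext = length - net.cl_rest
    bound = net.cl_bound
    k = config.crosslink_stiffness
    fmag = np.where(bound, k * ext, 0.0)
    net.cl_tension = np.maximum(fmag, 0.0)
    safe = length > 1e-9
    dhat = np.zeros_like(d)
    dhat[safe] = d[safe] / length[safe, None]
    fvec = fmag[:, None] * dhat  # force on attachment a, toward b when stretched
    sn = net.seg_nodes
    ta = net.cl_t[:, 0]
    tb = net.cl_t[:, 1]
    _scatter_add(forces, sn[net.cl_seg[:, 0], 0], (1.0 - ta)[:, None] * fvec)
    _scatter_add(forces, sn[net.cl_seg[:, 0], 1], ta[:, None] * fvec)
    _scatter_add(forces, sn[net.cl_seg[:, 1], 0], -(1.0 - tb)[:, None] * fvec)
    _scatter_add(forces, sn[net.cl_seg[:, 1], 1], -tb[:, None] * fvec)
    energy = float(0.5 * k * np.sum(np.where(bound, ext**2, 0.0)))
    return forces, energy


# ----------------------------------------------------------------------
def network_forces(
    net: FiberNetwork,
    config: SimConfig,
    repulsion_pair_list: np.ndarray | None = None,
    external: np.ndarray | None = None,
):
    """Assemble the full :class:`ForceSet` and the per-term elastic energies."""
    fs = ForceSet(net.n_nodes)
    energies = {}
    f, e = stretch_forces(net, config)
    fs.add("stretch", f)
    energies["stretch"] = e
    f, e = bend_forces(net, config)
    fs.add("bend", f)
    energies["bend"] = e
    f, e = repulsion_forces(net, config, repulsion_pair_list)
    fs.add("repulsion", f)
    energies["repulsion"] = e
    f, e = crosslink_forces(net, config)
    fs.add("crosslink", f)
    energies["crosslink"] = e
    if external is not None:
        fs.add("external", external)
    return fs, energies


def euler_step(net: FiberNetwork, forces: ForceSet, config: SimConfig) -> np.ndarray:
    """Forward-Euler update of the overdamped equation of motion.

    Each free node moves by F·Δt/ζ; fixed nodes are pinned; x,y wrap
    periodically and z is confined to [0, l_z] (the loading boundary acts as
    a wall).  Raises :class:`StepTooLargeError` when any displacement exceeds
    the stability cap (default: segment length / 10).
    """
    dt = config.resolved_dt()
    disp = forces.total() * (dt / config.zeta)
    disp[net.fixed] = 0.0
    new_pos = net.positions + disp
    np.clip(new_pos[:, 2], 0.0, net.l_z, out=new_pos[:, 2])
    actual = new_pos - net.positions
    cap = config.resolved_step_cap()
    max_disp = float(np.linalg.norm(actual, axis=1).max()) if len(actual) else 0.0
    if max_disp > cap:
        raise StepTooLargeError(
            f"max displacement {max_disp:.3g} μm exceeds stability cap {cap:.3g} μm; "
            "reduce dt or the applied force"
        )
    net.positions = wrap_xy(new_pos, net.l_xy)
    return net.positions
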