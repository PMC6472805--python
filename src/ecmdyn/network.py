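"""Discrete fiber-network data model, generation and prestress relaxation.

A network mimicking a fibrin/collagen gel lives in a box that is periodic in
x and y and bounded in z; the cell-side (loading) boundary is z = 0 and fiber
ends near z = l_z are pinned to mimic the resistance of the far-away matrix.
Fibers are chains of equal-rest-length cylindrical segments nucleated at
random positions in random directions; pairs of segments from distinct fibers
whose closest approach is within the two-armed crosslinker reach are
candidate crosslink sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from ._geometry import minimum_image, wrap_xy, segment_closest_points, midpoint_cell_pairs
from .config import SimConfig


class NetworkGenerationError(RuntimeError):
    pass


class RelaxationError(RuntimeError):
    pass


@dataclass
class FiberNetwork:
    """Structure-of-arrays container for the network state.

    ``positions`` is the only array mutated by the dynamics; everything else
    is fixed topology (crosslink ``bound`` flags and tension caches are state
    updated by the kinetics).
    """

    positions: np.ndarray          # (N, 3) float, μm
    fixed: np.ndarray              # (N,) bool
    seg_nodes: np.ndarray          # (S, 2) int
    seg_fiber: np.ndarray          # (S,) int
    rest_length: np.ndarray        # (S,) float, μm
    fiber_nodes: list              # per fiber: int array of chain node ids
    diameter: float
    arm_length: float
    l_xy: float
    l_z: float
    # crosslinks -------------------------------------------------------
    cl_seg: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.intp))
    cl_t: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    cl_bound: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    cl_tension: np.ndarray = field(default_factory=lambda: np.empty(0))
    cl_rest: np.ndarray = field(default_factory=lambda: np.empty(0))

    # derived topology (built lazily) ---------------------------------
    _triplets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        n = len(self.positions)
        s = len(self.seg_nodes)
        if self.seg_nodes.size and (self.seg_nodes.min() < 0 or self.seg_nodes.max() >= n):
            raise ValueError("segment node reference out of range")
        if len(self.seg_fiber) != s or len(self.rest_length) != s:
            raise ValueError("segment arrays inconsistent")
        if np.any(self.rest_length <= 0):
            raise ValueError("rest_length must be > 0")
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        c = len(self.cl_seg)
        if self.cl_seg.size and (self.cl_seg.min() < 0 or self.cl_seg.max() >= s):
            raise ValueError("crosslink segment reference out of range")
        for arr, name in ((self.cl_t, "cl_t"),):
            if len(arr) != c:
                raise ValueError(f"{name} inconsistent with cl_seg")
        if len(self.cl_bound) != c or len(self.cl_tension) != c or len(self.cl_rest) != c:
            raise ValueError("crosslink state arrays inconsistent")

    # -- views ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    @property
    def n_segments(self) -> int:
        return len(self.seg_nodes)

    @property
    def n_crosslinks(self) -> int:
        return len(self.cl_seg)

    @property
    def domain(self) -> tuple:
        return (self.l_xy, self.l_xy, self.l_z)

    def segment_vectors(self) -> np.ndarray:
        """Minimum-image vectors from node_a to node_b of each segment."""
        return minimum_image(
            self.positions[self.seg_nodes[:, 1]] - self.positions[self.seg_nodes[:, 0]],
            self.l_xy,
        )

    def segment_midpoints(self) -> np.ndarray:
        a = self.positions[self.seg_nodes[:, 0]]
        return a + 0.5 * self.segment_vectors()

    def bend_triplets(self) -> np.ndarray:
        """(T, 3) node triplets centered on fiber-interior nodes."""
        if self._triplets is None:
            trips = []
            for chain in self.fiber_nodes:
                if len(chain) >= 3:
                    trips.append(np.stack([chain[:-2], chain[1:-1], chain[2:]], axis=1))
            self._triplets = (
                np.concatenate(trips, axis=0) if trips else np.empty((0, 3), dtype=np.intp)
            )
        return self._triplets

    def total_rest_length(self) -> float:
        return float(self.rest_length.sum())

    def crosslink_points(self) -> tuple:
        """Current attachment points (x_a, x_b) of all crosslinks; x_b is the
        minimum image relative to x_a."""
        pa = self.positions[self.seg_nodes[self.cl_seg[:, 0], 0]]
        va = minimum_image(
            self.positions[self.seg_nodes[self.cl_seg[:, 0], 1]] - pa, self.l_xy
        )
        xa = pa + self.cl_t[:, 0, None] * va
        pb = self.positions[self.seg_nodes[self.cl_seg[:, 1], 0]]
        vb = minimum_image(
            self.positions[self.seg_nodes[self.cl_seg[:, 1], 1]] - pb, self.l_xy
        )
        xb = pb + self.cl_t[:, 1, None] * vb
        xb = xa + minimum_image(xb - xa, self.l_xy)
        return xa, xb

    def copy(self) -> "FiberNetwork":
        return FiberNetwork(
            positions=self.positions.copy(),
            fixed=self.fixed.copy(),
            seg_nodes=self.seg_nodes.copy(),
            seg_fiber=self.seg_fiber.copy(),
            rest_length=self.rest_length.copy(),
            fiber_nodes=[c.copy() for c in self.fiber_nodes],
            diameter=self.diameter,
            arm_length=self.arm_length,
            l_xy=self.l_xy,
            l_z=self.l_z,
            cl_seg=self.cl_seg.copy(),
            cl_t=self.cl_t.copy(),
            cl_bound=self.cl_bound.copy(),
            cl_tension=self.cl_tension.copy(),
            cl_rest=self.cl_rest.copy(),
        )


# ----------------------------------------------------------------------
def _grow_fibers(config: SimConfig, rng: np.random.Generator):
    """Polymerize straight chains of segments in random directions.

    x and y are periodic, so fibers simply wrap.  For z the placement is
    drawn as if z were periodic too — which makes the initial density
    exactly uniform — and a fiber whose straight line crosses a z face is
    cut there into two independent straight pieces, one ending exactly on
    the face it left and one starting on the opposite face.  Cutting
    conserves the total rest length exactly (the straddling segment is
    split into two sub-segments) and introduces no bending prestress.
    """
    n_seg = max(1, int(round(config.fiber_length / config.segment_rest_length)))
    seg_len = config.segment_rest_length
    if n_seg * seg_len > config.l_z:
        raise NetworkGenerationError(
            f"fiber length {n_seg * seg_len} μm exceeds the domain height {config.l_z} μm"
        )
    positions = []
    seg_nodes = []
    seg_fiber = []
    rest_lengths = []
    fiber_nodes = []
    node_count = 0
    fiber_id = 0

    def emit(pts, rests):
        nonlocal node_count, fiber_id
        n = len(pts)
        if n < 2:
            return
        chain = np.arange(node_count, node_count + n, dtype=np.intp)
        fiber_nodes.append(chain)
        seg_nodes.append(np.stack([chain[:-1], chain[1:]], axis=1))
        seg_fiber.append(np.full(n - 1, fiber_id, dtype=np.intp))
        rest_lengths.append(np.asarray(rests, dtype=float))
        positions.append(np.asarray(pts, dtype=float))
        node_count += n
        fiber_id += 1

    eps = 1e-9 * seg_len
    for _ in range(config.fiber_count):
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        z0 = rng.uniform(0.0, config.l_z)
        start = np.array([
            rng.uniform(0.0, config.l_xy), rng.uniform(0.0, config.l_xy), z0,
        ])
        pts = start[None, :] + np.arange(n_seg + 1)[:, None] * (seg_len * d[None, :])
        z = pts[:, 2]
        inside = (z >= -eps) & (z <= config.l_z + eps)
        if inside.all():
            emit(pts, np.full(n_seg, seg_len))
            continue
        # straight line crosses one z face exactly once (fiber < domain height)
        j = int(np.flatnonzero(~inside)[0]) - 1  # segment j straddles the face
        face = config.l_z if d[2] > 0 else 0.0
        t_star = (face - z[j]) / (z[j + 1] - z[j])
        t_star = min(max(t_star, 0.0), 1.0)
        crossing = pts[j] + t_star * (pts[j + 1] - pts[j])
        shift = np.array([0.0, 0.0, -config.l_z if d[2] > 0 else config.l_z])
        # Sliver sub-segments shorter than 0.3 segment lengths are merged
        # into the collinear neighbor (exact, since the fiber is straight):
        # a very short segment inside a bending triplet would otherwise make
        # the angular forces (which scale as 1/arm length) stiff beyond the
        # stable time step.  Unmergeable end slivers below 0.05 segment
        # lengths are dropped (total loss well under one segment length).
        merge_frac, drop_frac = 0.3, 0.05
        # piece A: nodes 0..j plus the crossing point on the face it left
        pts_a = np.vstack([pts[: j + 1], crossing])
        rests_a = [seg_len] * j + [t_star * seg_len]
        if t_star < merge_frac and j >= 1:
            pts_a = np.vstack([pts[:j], crossing])
            rests_a = [seg_len] * (j - 1) + [(1.0 + t_star) * seg_len]
        if not (t_star < drop_frac and j == 0):
            emit(pts_a, rests_a)
        # piece B: the crossing point on the opposite face plus the rest
        u = 1.0 - t_star
        pts_b = np.vstack([crossing[None, :], pts[j + 1:]]) + shift[None, :]
        rests_b = [u * seg_len] + [seg_len] * (n_seg - j - 1)
        if u < merge_frac and j + 2 <= n_seg:
            pts_b = np.vstack([crossing[None, :] + shift[None, :], pts[j + 2:] + shift[None, :]])
            rests_b = [(1.0 + u) * seg_len] + [seg_len] * (n_seg - j - 2)
        if not (u < drop_frac and j + 1 == n_seg):
            emit(pts_b, rests_b)

    positions = np.vstack(positions) if positions else np.empty((0, 3))
    positions[:, 2] = np.clip(positions[:, 2], 0.0, config.l_z)
    positions = wrap_xy(positions, config.l_xy)
    seg_nodes = (
        np.concatenate(seg_nodes, axis=0) if seg_nodes else np.empty((0, 2), dtype=np.intp)
    )
    seg_fiber = np.concatenate(seg_fiber) if seg_fiber else np.empty(0, dtype=np.intp)
    rest_lengths = (
        np.concatenate(rest_lengths) if rest_lengths else np.empty(0)
    )
    return positions, seg_nodes, seg_fiber, rest_lengths, fiber_nodes


def crosslink_candidates(
    positions: np.ndarray,
    seg_nodes: np.ndarray,
    seg_fiber: np.ndarray,
    reach: float,
    l_xy: float,
    l_z: float,
    seg_len: float,
):
    """All segment pairs from distinct fibers with closest approach <= reach.

    Returns (pairs (m,2) segment ids, t (m,2) arc coordinates of the closest
    points).  Used both by the generator and as a brute-force oracle target.
    """
    mids = positions[seg_nodes[:, 0]] + 0.5 * minimum_image(
        positions[seg_nodes[:, 1]] - positions[seg_nodes[:, 0]], l_xy
    )
    cutoff = seg_len + reach
    cand = midpoint_cell_pairs(mids, cutoff, l_xy, l_z)
    if len(cand) == 0:
        return np.empty((0, 2), dtype=np.intp), np.empty((0, 2))
    mask = seg_fiber[cand[:, 0]] != seg_fiber[cand[:, 1]]
    cand = cand[mask]
    if len(cand) == 0:
        return np.empty((0, 2), dtype=np.intp), np.empty((0, 2))
    p1 = positions[seg_nodes[cand[:, 0], 0]]
    d1 = minimum_image(positions[seg_nodes[cand[:, 0], 1]] - p1, l_xy)
    p2 = positions[seg_nodes[cand[:, 1], 0]]
    d2 = minimum_image(positions[seg_nodes[cand[:, 1], 1]] - p2, l_xy)
    dist, t, s, _ = segment_closest_points(p1, d1, p2, d2, l_xy)
    hit = dist <= reach
    pairs = cand[hit]
    tcoords = np.stack([t[hit], s[hit]], axis=1)
    return pairs, tcoords, dist[hit]


def generate_network(config: SimConfig, seed: int | None = None) -> FiberNetwork:
    """Build a random crosslinked fiber network for the given conditions.

    Crosslinks are placed at the closest-approach points of candidate segment
    pairs (reach = 2·arm_length) and subsampled so their count scales linearly
    with ``crosslink_density_rel`` (1x keeps every geometric candidate).
    Deterministic for a fixed seed.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    positions, seg_nodes, seg_fiber, rest_length, fiber_nodes = _grow_fibers(config, rng)

    fixed = np.zeros(len(positions), dtype=bool)
    margin = config.resolved_capture_margin()
    for chain in fiber_nodes:
        for end in (chain[0], chain[-1]):
            if positions[end, 2] > config.l_z - margin:
                fixed[end] = True

    reach = 2.0 * config.arm_length
    pairs, tcoords, dists = crosslink_candidates(
        positions, seg_nodes, seg_fiber, reach, config.l_xy, config.l_z,
        config.segment_rest_length,
    )
    n_cand = len(pairs)
    want = int(round(config.crosslink_density_rel * n_cand))
    if want > n_cand:
        raise NetworkGenerationError(
            f"requested crosslink density {config.crosslink_density_rel}x needs "
            f"{want} crosslinks but only {n_cand} candidate pairs exist "
            f"(achievable maximum density {1.0 if n_cand else 0.0}x = {n_cand} links)"
        )
    keep = np.sort(rng.choice(n_cand, size=want, replace=False)) if want < n_cand else np.arange(n_cand)
    pairs = pairs[keep]
    tcoords = tcoords[keep]
    # a crosslinker binds unstressed at whatever span its arms have at
    # formation (same rule as rebinding), up to the full two-arm reach
    rests = np.clip(dists[keep], 1e-3, reach)

    net = FiberNetwork(
        positions=positions,
        fixed=fixed,
        seg_nodes=seg_nodes,
        seg_fiber=seg_fiber,
        rest_length=rest_length,
        fiber_nodes=fiber_nodes,
        diameter=config.diameter,
        arm_length=config.arm_length,
        l_xy=config.l_xy,
        l_z=config.l_z,
        cl_seg=pairs,
        cl_t=tcoords,
        cl_bound=np.ones(len(pairs), dtype=bool),
        cl_tension=np.zeros(len(pairs)),
        cl_rest=rests,
    )
    return net


def largest_cluster_fraction(net: FiberNetwork) -> float:
    """Fraction of fibers in the largest crosslink-connected cluster
    (union-find on the fiber graph); 1.0 means fully percolated."""
    n_f = len(net.fiber_nodes)
    if n_f == 0:
        return 0.0
    if net.n_crosslinks == 0:
        return 1.0 / n_f
    fa = net.seg_fiber[net.cl_seg[:, 0]]
    fb = net.seg_fiber[net.cl_seg[:, 1]]
    g = coo_matrix((np.ones(len(fa)), (fa, fb)), shape=(n_f, n_f))
    n_comp, labels = connected_components(g, directed=False)
    counts = np.bincount(labels, minlength=n_comp)
    return float(counts.max()) / n_f


# ----------------------------------------------------------------------
def relax_network(
    net: FiberNetwork,
    config: SimConfig,
    energy_rtol: float = 1e-3,
    force_tol: float = 1.0,
    window: int = 100,
    max_steps: int = 20_000,
):
    """Integrate the unloaded dynamics (unbinding disabled) until the
    formation prestress has decayed to a plateau.

    Convergence requires both (i) the relative change of total elastic energy
    over a sliding window below ``energy_rtol`` and (ii) the maximum per-node
    net internal force below ``force_tol`` (pN).  Returns the relaxed network
    (mutated in place) and a trace of (step, energy, max_force).

    Raises :class:`RelaxationError` on non-convergence, reporting residuals.
    """
    from .integrate import Stepper

    stepper = Stepper(net, config)
    trace = []
    prev_energy = None
    for step in range(0, max_steps + 1, window):
        stepper.compute_forces()
        max_f = stepper.max_free_force()
        energy = float(stepper.energy)
        trace.append((step, energy, max_f))
        scale = max(energy, 1.0)
        plateau = (
            prev_energy is not None and abs(energy - prev_energy) / scale < energy_rtol
        )
        # a residual force well under tolerance is itself a plateau: soft
        # bending modes keep draining tiny energies long after force balance
        if max_f < 0.5 * force_tol or (max_f < force_tol and plateau):
            return net, np.array(trace)
        if step == max_steps:
            break
        prev_energy = energy
        stepper.advance()
        for _ in range(window - 1):
            stepper.compute_forces()
            stepper.advance()
    raise RelaxationError(
        f"prestress relaxation did not converge in {max_steps} steps: "
        f"energy={trace[-1][1]:.4g} pN·μm, max force={trace[-1][2]:.4g} pN"
    )
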