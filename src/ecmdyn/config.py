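"""Configuration objects for the discrete-network and continuum engines.

Unit system: pN - μm - s, so pN/μm² is identical to Pa and the thermal energy
k_B·T at 310 K is 4.28e-3 pN·μm.

Several baseline constants of the fiber model (drag, kinetic rates, absolute
crosslink density) and of the continuum model (yield stress, Norton-Hoff
creep constants, softening slope, Poisson ratio) are not fixed by published
measurements; they are exposed here as ordinary defaults but flagged in
``ASSUMED_SIM_PARAMS`` / ``ASSUMED_CONTINUUM_PARAMS`` so that config loading
can warn about them.  See docs/methods.md for the rationale behind each.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

KB = 1.380649e-5  # Boltzmann constant, pN·μm/K
KBT_310 = KB * 310.0  # 4.28e-3 pN·μm

#: parameters whose defaults are modeling assumptions, not measured values
ASSUMED_SIM_PARAMS = frozenset(
    {
        "zeta",
        "k_u0",
        "lam",
        "crosslink_stiffness",
        "repulsion_stiffness",
        "fiber_count",
        "fiber_length",
        "segment_rest_length",
        "rebind_rate",
        "rebind_reach",
    }
)

ASSUMED_CONTINUUM_PARAMS = frozenset(
    {
        "nu",
        "sigma_y0",
        "softening_slope",
        "eps_p_crit",
        "sigma_y_min",
        "nh_coefficient",
        "nh_exponent",
        "sigma_ref",
        "cell_radius",
    }
)


@dataclass
class SimConfig:
    """Parameters of the discrete crosslinked-fiber network simulation.

    Mechanical stiffnesses default to beam theory for a cylindrical fiber of
    Young's modulus ``E_fiber`` and diameter ``diameter``:
    ``kappa_e = E·A/l0`` and ``kappa_b = E·I/l0`` with ``A = π d²/4`` and
    ``I = π d⁴/64``; both can be overridden directly.
    """

    # --- domain / network structure ---
    l_xy: float = 20.0           # periodic box edge, μm
    l_z: float = 20.0            # loading axis extent, μm
    fiber_count: int = 1400
    fiber_length: float = 8.0    # mean fiber contour length, μm
    segment_rest_length: float = 0.5  # μm
    diameter: float = 0.1        # fiber diameter, μm (~100 nm)
    arm_length: float = 0.02     # crosslink arm, μm (two 20 nm arms)
    capture_margin: float | None = None  # fiber ends within this of z=l_z are fixed

    # --- fiber mechanics ---
    E_fiber: float = 125e6       # Pa; fiber material Young's modulus
    kappa_e: float | None = None  # pN/μm, override of E·A/l0
    kappa_b: float | None = None  # pN·μm, override of E·I/l0
    crosslink_stiffness: float = 300.0  # pN/μm
    repulsion_stiffness: float = 500.0  # pN/μm per unit overlap
    repulsion_cap: float = 200.0  # pN, force saturation for deep overlaps
    zeta: float = 1.0            # pN·s/μm drag per node
    dt: float | None = None      # s; derived from stability if None

    # --- crosslink kinetics (1x baselines) ---
    T: float = 310.0             # K
    k_u0: float = 2.0            # 1/s zero-force unbinding rate at 1x
    lam: float = 3e-4            # μm mechanosensitivity at 1x (0.3 nm)
    crosslink_density_rel: float = 1.0  # fraction of geometric candidates kept
    bell_exponent_cap: float = 40.0
    rebinding_enabled: bool = False
    rebind_rate: float = 10.0    # 1/s
    rebind_reach: float = 0.06   # μm

    # --- loading protocol ---
    force_per_site: float = 100.0  # pN per loaded fiber segment
    per_fiber_loading: bool = False  # alternative: one force per fiber in zone
    zone_depth: float = 2.0        # μm from the z=0 (cell-side) boundary
    load_duration: float | None = None   # s; 50000·dt if None
    relax_duration: float | None = None  # s; 1.05× load duration if None
    snapshots_per_phase: int = 50

    # --- numerics ---
    neighbor_rebuild_every: int = 15
    neighbor_skin: float = 0.2   # μm, shortlist margin for repulsion pairs
    max_step_displacement: float | None = None  # μm; segment length/10 if None

    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {
            "l_xy": self.l_xy,
            "l_z": self.l_z,
            "fiber_length": self.fiber_length,
            "segment_rest_length": self.segment_rest_length,
            "diameter": self.diameter,
            "arm_length": self.arm_length,
            "E_fiber": self.E_fiber,
            "zeta": self.zeta,
            "T": self.T,
        }
        for name, val in positive.items():
            if not val > 0:
                raise ValueError(f"{name} must be > 0, got {val}")
        nonneg = {
            "k_u0": self.k_u0,
            "lam": self.lam,
            "crosslink_density_rel": self.crosslink_density_rel,
            "force_per_site": self.force_per_site,
            "zone_depth": self.zone_depth,
            "rebind_rate": self.rebind_rate,
            "crosslink_stiffness": self.crosslink_stiffness,
            "repulsion_stiffness": self.repulsion_stiffness,
        }
        for name, val in nonneg.items():
            if val < 0:
                raise ValueError(f"{name} must be >= 0, got {val}")
        if self.fiber_count < 0:
            raise ValueError("fiber_count must be >= 0")
        for name in ("dt", "load_duration", "relax_duration"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise ValueError(f"{name} must be > 0 when given, got {val}")
        if self.dt is not None and self.k_u0 * self.dt >= 0.1:
            raise ValueError(
                "dt too large for the unbinding kinetics: "
                f"k_u0*dt = {self.k_u0 * self.dt:.3g} >= 0.1"
            )

    # --- derived quantities -------------------------------------------
    @property
    def area(self) -> float:
        return math.pi * self.diameter**2 / 4.0

    @property
    def second_moment(self) -> float:
        return math.pi * self.diameter**4 / 64.0

    def resolved_kappa_e(self) -> float:
        if self.kappa_e is not None:
            return self.kappa_e
        return self.E_fiber * self.area / self.segment_rest_length

    def resolved_kappa_b(self) -> float:
        if self.kappa_b is not None:
            return self.kappa_b
        return self.E_fiber * self.second_moment / self.segment_rest_length

    def resolved_dt(self) -> float:
        """Explicit-Euler stable step: a small fraction of the fastest
        relaxation time ζ/κ among the stiff elements."""
        if self.dt is not None:
            return self.dt
        kappa_max = max(
            self.resolved_kappa_e(), self.crosslink_stiffness, self.repulsion_stiffness
        )
        return 0.05 * self.zeta / kappa_max

    def resolved_load_duration(self) -> float:
        if self.load_duration is not None:
            return self.load_duration
        return 50_000 * self.resolved_dt()

    def resolved_relax_duration(self) -> float:
        if self.relax_duration is not None:
            return self.relax_duration
        return 1.05 * self.resolved_load_duration()

    def resolved_capture_margin(self) -> float:
        if self.capture_margin is not None:
            return self.capture_margin
        return self.segment_rest_length

    def resolved_step_cap(self) -> float:
        if self.max_step_displacement is not None:
            return self.max_step_displacement
        return self.segment_rest_length / 10.0

    @property
    def kbt(self) -> float:
        return KB * self.T

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def desk_config(**overrides) -> SimConfig:
    """Desk-scale study conditions used throughout the test suite.

    A 10×10×10 μm³ box with 500 fibers of 6 μm (1 μm segments) and a
    generous crosslinker reach gives a fully percolating network with ~5
    crosslinks per fiber at the 1x density.  Fibers are softer (E = 0.32
    MPa) than the full-scale 125 MPa so that an explicit time step of
    5×10⁻⁵ s resolves both the stiffest springs and micrometers of fiber
    transport within a 0.25 s loading phase, while the crosslink springs
    are stiff enough (2 nN/μm) that a fully bound network barely yields
    elastically under the loading-zone forces.  The kinetic baselines put
    an unloaded crosslink safely through the loading phase
    (k_u0·T_load ≈ 0.013) while a loaded one at ~100 pN unbinds within it
    (λF/k_BT ≈ 7 at the 1x mechanosensitivity).
    """
    params = dict(
        l_xy=10.0,
        l_z=10.0,
        fiber_count=500,
        fiber_length=6.0,
        segment_rest_length=1.0,
        E_fiber=3.2e5,
        kappa_b=10.0,
        crosslink_stiffness=2000.0,
        repulsion_stiffness=1000.0,
        arm_length=0.075,
        rebind_rate=300.0,
        rebind_reach=0.5,
        capture_margin=1.6,
        zeta=1.0,
        dt=6e-5,
        k_u0=0.05,
        lam=3e-4,
        force_per_site=100.0,
        load_duration=0.25,
        relax_duration=0.26,
        snapshots_per_phase=25,
        max_step_displacement=0.25,
    )
    params.update(overrides)
    return SimConfig(**params)


# ----------------------------------------------------------------------
@dataclass
class KineticParams:
    """Force-sensitive crosslink kinetics (Bell slip-bond model)."""

    k_u0: float = 2.0        # 1/s
    lam: float = 3e-4        # μm
    T: float = 310.0         # K
    dt: float = 1e-4         # s
    rebind_rate: float = 0.0  # 1/s
    rebind_reach: float = 0.06  # μm
    exponent_cap: float = 40.0

    def __post_init__(self) -> None:
        if self.k_u0 < 0 or self.lam < 0:
            raise ValueError("k_u0 and lam must be >= 0")
        if not self.T > 0:
            raise ValueError("T must be > 0")

    @property
    def kbt(self) -> float:
        return KB * self.T

    @classmethod
    def from_sim_config(cls, config: SimConfig) -> "KineticParams":
        return cls(
            k_u0=config.k_u0,
            lam=config.lam,
            T=config.T,
            dt=config.resolved_dt(),
            rebind_rate=config.rebind_rate if config.rebinding_enabled else 0.0,
            rebind_reach=config.rebind_reach,
            exponent_cap=config.bell_exponent_cap,
        )


# ----------------------------------------------------------------------
@dataclass
class ContinuumConfig:
    """Spherically symmetric viscoplastic continuum around a contracting cell.

    Elasticity: Young's modulus degrades exponentially with the running
    maximum tensile principal elastic strain between the anchor points
    (eps_1s, E_s) and (eps_1e, E_e); damage is irreversible.  Plasticity:
    von Mises yield with Norton-Hoff power-law overstress creep,
    rate = nh_coefficient · ⟨(σ_vm − σ_y)/σ_ref⟩^nh_exponent, and linear
    softening of the yield stress beyond a critical equivalent plastic
    strain, floored at sigma_y_min.
    """

    E_s: float = 1000.0      # Pa undamaged modulus
    E_e: float = 200.0       # Pa fully damaged modulus
    eps_1s: float = 0.02     # damage onset principal strain
    eps_1e: float = 0.06     # damage saturation principal strain
    nu: float = 0.30         # Poisson ratio
    sigma_y0: float = 45.0   # Pa initial yield stress
    softening_slope: float = -300.0  # Pa per unit plastic strain (< 0 softens)
    eps_p_crit: float = 0.02  # plastic strain at softening onset
    sigma_y_min: float = 25.0  # Pa floor for the softened yield stress
    nh_coefficient: float = 1e-4  # 1/s creep rate scale
    nh_exponent: float = 2.0
    sigma_ref: float = 45.0  # Pa overstress normalization
    cell_radius: float = 10.0  # μm
    outer_radius: float = 100.0  # μm, fixed outer boundary
    load: float = 100.0      # Pa boundary traction magnitude (0.1 kPa)
    ramp_duration: float = 60.0   # s load ramp 0 -> p
    creep_duration: float = 1500.0  # s constant-load hold
    unload_duration: float = 60.0   # s ramp p -> 0
    settle_duration: float = 240.0  # s zero-load hold after unload

    damage_enabled: bool = True
    softening_enabled: bool = True
    plasticity_enabled: bool = True

    # numerics
    n_r: int = 160
    dt_max: float = 20.0
    dt_min: float = 0.25
    deps_p_cap: float = 1.5e-3  # max equivalent plastic increment per step
    damage_tol: float = 1e-3   # fixed-point tolerance on E/E_s per step
    max_inner_iter: int = 400

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0 < self.E_e <= self.E_s):
            raise ValueError("need 0 < E_e <= E_s")
        if not (0 <= self.eps_1s < self.eps_1e):
            raise ValueError("need 0 <= eps_1s < eps_1e")
        if not (0 < self.nu < 0.5):
            raise ValueError("nu must lie in (0, 0.5)")
        if not self.sigma_y_min > 0:
            raise ValueError("sigma_y_min must be > 0 (yield stress floor)")
        if self.sigma_y0 < self.sigma_y_min:
            raise ValueError("sigma_y0 must be >= sigma_y_min")
        if not self.cell_radius > 0 or not self.outer_radius > self.cell_radius:
            raise ValueError("need outer_radius > cell_radius > 0")
        for name in ("ramp_duration", "creep_duration", "unload_duration", "settle_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_r < 8:
            raise ValueError("n_r too small")

    def replace(self, **kw) -> "ContinuumConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def continuum_baseline(**overrides) -> ContinuumConfig:
    """Baseline viscoplastic run: p = 0.1 kPa, 1500 s creep, damage + softening."""
    return ContinuumConfig(**overrides)


def continuum_elastic(**overrides) -> ContinuumConfig:
    """Pure linear-elastic preset (damage and plasticity off, far outer
    boundary) used for the pressurized-cavity checks."""
    params = dict(
        damage_enabled=False,
        softening_enabled=False,
        plasticity_enabled=False,
        outer_radius=500.0,
        n_r=220,
        creep_duration=300.0,
        settle_duration=120.0,
    )
    params.update(overrides)
    return ContinuumConfig(**params)


# ----------------------------------------------------------------------
@dataclass
class LoadSchedule:
    """Load→relax schedule on the normalized time axis (0 = load onset,
    1 = load cessation)."""

    force_per_site: float
    zone_depth: float
    load_duration: float
    relax_duration: float
    per_fiber: bool = False

    def __post_init__(self) -> None:
        if self.load_duration <= 0 or self.relax_duration <= 0:
            raise ValueError("phase durations must be > 0")
        if self.zone_depth < 0 or self.force_per_site < 0:
            raise ValueError("zone_depth and force_per_site must be >= 0")

    @classmethod
    def from_config(cls, config: SimConfig) -> "LoadSchedule":
        return cls(
            force_per_site=config.force_per_site,
            zone_depth=config.zone_depth,
            load_duration=config.resolved_load_duration(),
            relax_duration=config.resolved_relax_duration(),
            per_fiber=config.per_fiber_loading,
        )

    def normalized_time(self, elapsed_since_load_onset: float) -> float:
        return elapsed_since_load_onset / self.load_duration
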