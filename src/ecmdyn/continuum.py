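"""Spherically symmetric viscoplastic continuum model of the pericellular ECM.

A contracting cell of radius ``a`` pulls the surrounding matrix inward with a
radial traction ``p`` at the cell-ECM interface; the matrix occupies the
spherical shell a <= r <= R with the outer boundary held fixed.  The material
is elastic-viscoplastic:

* linear isotropic elasticity whose Young's modulus degrades exponentially,
  E = A·exp(−B·ε₁), with the running maximum tensile principal elastic
  strain ε₁ between the anchors (ε_1s, E_s) and (ε_1e, E_e) — irreversible
  "elastic damage" standing in for force-driven crosslink unbinding;
* Norton-Hoff power-law overstress creep with von Mises flow,
  dε_p/dt = k·⟨(σ_vm − σ_y)/σ_ref⟩ⁿ;
* linear softening of the yield stress with accumulated equivalent plastic
  strain beyond a critical value ("plastic damage").

The quasi-static radial equilibrium d σ_rr/dr + 2(σ_rr − σ_θθ)/r = 0 is
solved on a 1D finite-element grid (linear elements, one-point quadrature,
element-midpoint state) at every time step; plastic flow and damage are
updated in a staggered explicit scheme with adaptive time steps that bound
the plastic increment per step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .config import ContinuumConfig

__all__ = [
    "ContinuumSolution",
    "damage_modulus",
    "yield_stress",
    "creep_rate",
    "solve_sphere",
    "recoverability_index_model",
    "damage_radius",
    "apparent_true_stress_ratio",
    "elastic_decay_exponent",
]


class ContinuumSolverError(RuntimeError):
    pass


# ----------------------------------------------------------------------
def damage_modulus(eps1_max, config: ContinuumConfig):
    """Damaged Young's modulus for a running-max principal strain (Pa).

    E = E_s below the onset strain, E = A·exp(−B·ε₁) between the anchors
    (continuous at both), and E = E_e at/after saturation.
    """
    eps1_max = np.asarray(eps1_max, dtype=float)
    if np.any(eps1_max < 0):
        raise ValueError("eps1_max must be >= 0")
    if not config.damage_enabled:
        return np.broadcast_to(config.E_s, eps1_max.shape).copy()
    b = np.log(config.E_s / config.E_e) / (config.eps_1e - config.eps_1s)
    a = config.E_s * np.exp(b * config.eps_1s)
    e = a * np.exp(-b * np.clip(eps1_max, config.eps_1s, config.eps_1e))
    return np.clip(e, config.E_e, config.E_s)


def yield_stress(eps_p_eq, config: ContinuumConfig):
    """Current yield stress (Pa): constant up to the critical plastic strain,
    then linear softening floored at ``sigma_y_min``."""
    eps_p_eq = np.asarray(eps_p_eq, dtype=float)
    if np.any(eps_p_eq < 0):
        raise ValueError("eps_p_eq must be >= 0")
    if not config.softening_enabled:
        return np.broadcast_to(config.sigma_y0, eps_p_eq.shape).copy()
    excess = np.maximum(eps_p_eq - config.eps_p_crit, 0.0)
    return np.maximum(config.sigma_y0 + config.softening_slope * excess, config.sigma_y_min)


def creep_rate(sigma_vm, config: ContinuumConfig, sigma_y=None):
    """Norton-Hoff equivalent plastic strain rate (1/s).

    rate = nh_coefficient·⟨(σ_vm − σ_y)/σ_ref⟩^nh_exponent, zero below yield.
    """
    sigma_vm = np.asarray(sigma_vm, dtype=float)
    if np.any(sigma_vm < 0):
        raise ValueError("sigma_vm must be >= 0")
    if not config.plasticity_enabled:
        return np.zeros_like(sigma_vm)
    if sigma_y is None:
        sigma_y = config.sigma_y0
    over = np.maximum((sigma_vm - sigma_y) / config.sigma_ref, 0.0)
    return config.nh_coefficient * over**config.nh_exponent


# ----------------------------------------------------------------------
@dataclass
class ContinuumSolution:
    """Radial fields over time from :func:`solve_sphere`."""

    r: np.ndarray            # (n_r,) node radii, μm
    r_mid: np.ndarray        # (n_el,) element midpoints, μm
    times: np.ndarray        # (T,) s
    load: np.ndarray         # (T,) applied traction, Pa
    u: np.ndarray            # (T, n_r) radial displacement, μm (negative = inward)
    sigma_rr: np.ndarray     # (T, n_el) Pa
    sigma_tt: np.ndarray     # (T, n_el) Pa
    sigma_vm: np.ndarray     # (T, n_el) Pa
    eps_p_eq: np.ndarray     # (T, n_el)
    eps1_max: np.ndarray     # (T, n_el)
    modulus: np.ndarray      # (T, n_el) current damaged Young's modulus, Pa
    i_end_creep: int         # snapshot index at the end of the creep hold
    config: dict = field(default_factory=dict)

    @property
    def cell_radius(self) -> float:
        return float(self.r[0])

    def u_cell(self) -> np.ndarray:
        """Interface displacement history u(a, t)."""
        return self.u[:, 0]


def _elastic_matrix(e_mod: np.ndarray, nu: float):
    lam = e_mod * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    mu = e_mod / (2.0 * (1.0 + nu))
    return lam, mu


def _stresses(eps_rr, eps_tt, epsp_rr, eps_p_tt, e_mod, nu):
    lam, mu = _elastic_matrix(e_mod, nu)
    ee_rr = eps_rr - epsp_rr
    ee_tt = eps_tt - eps_p_tt
    tr = ee_rr + 2.0 * ee_tt
    s_rr = lam * tr + 2.0 * mu * ee_rr
    s_tt = lam * tr + 2.0 * mu * ee_tt
    return s_rr, s_tt, ee_rr, ee_tt


def _solve_equilibrium(r, e_mod, nu, epsp_rr, epsp_tt, p_load):
    """One linear solve of radial equilibrium for given modulus field and
    plastic (eigen)strain; returns nodal u with u(R) = 0."""
    n = len(r)
    h = np.diff(r)
    rm = 0.5 * (r[:-1] + r[1:])
    w = rm**2 * h
    lam, mu = _elastic_matrix(e_mod, nu)
    c11 = lam + 2.0 * mu
    c12 = 2.0 * lam
    c22 = 4.0 * (lam + mu)
    # element B-matrix entries: eps_rr = (u2-u1)/h ; eps_tt = (u1+u2)/(2 rm)
    b1 = -1.0 / h
    b2 = 1.0 / h
    g = 1.0 / (2.0 * rm)
    k11 = w * (c11 * b1 * b1 + c12 * b1 * g + c12 * g * b1 + c22 * g * g)
    k12 = w * (c11 * b1 * b2 + c12 * b1 * g + c12 * g * b2 + c22 * g * g)
    k22 = w * (c11 * b2 * b2 + c12 * b2 * g + c12 * g * b2 + c22 * g * g)

    diag = np.zeros(n)
    off = np.zeros(n - 1)
    diag[:-1] += k11
    diag[1:] += k22
    off[:] = k12

    # eigenstrain load from plastic strain: f = B^T M eps_p per element
    s_rr_p = c11 * epsp_rr + c12 * epsp_tt
    s_tt_gen = c12 * epsp_rr + c22 * epsp_tt  # = 2*sigma_tt_p
    f = np.zeros(n)
    fe1 = w * (b1 * s_rr_p + g * s_tt_gen)
    fe2 = w * (b2 * s_rr_p + g * s_tt_gen)
    np.add.at(f, np.arange(n - 1), fe1)
    np.add.at(f, np.arange(1, n), fe2)

    # boundary traction at the cell surface: sigma_rr(a) = p_load
    f[0] += -(r[0] ** 2) * p_load

    # Dirichlet u(R) = 0: drop the last dof
    m = n - 1
    ab = np.zeros((3, m))
    ab[0, 1:] = off[: m - 1]
    ab[1, :] = diag[:m]
    ab[2, : m - 1] = off[: m - 1]
    u = np.zeros(n)
    u[:m] = solve_banded((1, 1), ab, f[:m])
    return u


def _strains(r, u):
    h = np.diff(r)
    rm = 0.5 * (r[:-1] + r[1:])
    eps_rr = np.diff(u) / h
    eps_tt = 0.5 * (u[:-1] + u[1:]) / rm
    return eps_rr, eps_tt


def default_load_history(config: ContinuumConfig):
    """Piecewise-linear load schedule (duration, p_start, p_end) in Pa:
    ramp to p, creep hold at p, unload to 0, settle at 0."""
    p = config.load
    return [
        (config.ramp_duration, 0.0, p),
        (config.creep_duration, p, p),
        (config.unload_duration, p, 0.0),
        (config.settle_duration, 0.0, 0.0),
    ]


def solve_sphere(
    config: ContinuumConfig,
    load_history=None,
    saves_per_phase: int = 40,
) -> ContinuumSolution:
    """Integrate the viscoplastic damage model through the load schedule.

    Within each time step the equilibrium problem is re-solved and the damage
    modulus iterated to a fixed point (damage is evaluated on the running
    maximum tensile principal elastic strain, so it can only grow); plastic
    flow is then advanced explicitly with the step size adapted to cap the
    equivalent plastic increment.
    """
    if load_history is None:
        load_history = default_load_history(config)
    r = np.geomspace(config.cell_radius, config.outer_radius, config.n_r)
    n_el = config.n_r - 1
    epsp_rr = np.zeros(n_el)
    epsp_tt = np.zeros(n_el)
    epsp_eq = np.zeros(n_el)
    eps1_max = np.zeros(n_el)
    e_mod = np.full(n_el, config.E_s)

    recs: dict[str, list] = {k: [] for k in (
        "t", "p", "u", "s_rr", "s_tt", "s_vm", "epsp_eq", "eps1", "E")}
    i_end_creep = -1

    def record(t, p, u, s_rr, s_tt):
        recs["t"].append(t)
        recs["p"].append(p)
        recs["u"].append(u.copy())
        recs["s_rr"].append(s_rr.copy())
        recs["s_tt"].append(s_tt.copy())
        recs["s_vm"].append(np.abs(s_rr - s_tt))
        recs["epsp_eq"].append(epsp_eq.copy())
        recs["eps1"].append(eps1_max.copy())
        recs["E"].append(e_mod.copy())

    def equilibrate(p_now):
        """Fixed-point between equilibrium and the damage modulus."""
        nonlocal e_mod, eps1_max
        residual = np.inf
        for _ in range(config.max_inner_iter):
            u = _solve_equilibrium(r, e_mod, config.nu, epsp_rr, epsp_tt, p_now)
            eps_rr, eps_tt = _strains(r, u)
            s_rr, s_tt, ee_rr, ee_tt = _stresses(
                eps_rr, eps_tt, epsp_rr, epsp_tt, e_mod, config.nu
            )
            eps1_trial = np.maximum(eps1_max, np.maximum(np.maximum(ee_rr, ee_tt), 0.0))
            e_new = damage_modulus(eps1_trial, config)
            residual = float(np.max(np.abs(e_new - e_mod))) / config.E_s
            eps1_max = eps1_trial
            e_mod = e_new
            if residual < config.damage_tol:
                return u, eps_rr, eps_tt, s_rr, s_tt
        raise ContinuumSolverError(
            f"damage fixed point did not converge: residual {residual:.3g}"
        )

    t = 0.0
    u, eps_rr, eps_tt, s_rr, s_tt = equilibrate(load_history[0][1])
    record(t, load_history[0][1], u, s_rr, s_tt)

    for phase_idx, (duration, p0, p1) in enumerate(load_history):
        if duration <= 0:
            continue
        t_phase_end = t + duration
        save_dt = duration / saves_per_phase
        next_save = t + save_dt
        while t < t_phase_end - 1e-9:
            s_vm = np.abs(s_rr - s_tt)
            sy = yield_stress(epsp_eq, config)
            rate = creep_rate(s_vm, config, sy)
            rmax = float(rate.max())
            dt = config.dt_max if rmax <= 0 else min(config.dt_max, config.deps_p_cap / rmax)
            dt = max(dt, config.dt_min)
            dt = min(dt, t_phase_end - t, max(next_save - t, config.dt_min))
            # explicit von Mises flow: eps_p_rr grows along sign(s_rr - s_tt)
            sign = np.sign(s_rr - s_tt)
            inc = rate * dt
            epsp_rr += inc * sign
            epsp_tt -= 0.5 * inc * sign
            epsp_eq += inc
            t += dt
            frac = np.clip((t - (t_phase_end - duration)) / duration, 0.0, 1.0)
            p_now = p0 + (p1 - p0) * frac
            u, eps_rr, eps_tt, s_rr, s_tt = equilibrate(p_now)
            if t >= next_save - 1e-9 or t >= t_phase_end - 1e-9:
                record(t, p_now, u, s_rr, s_tt)
                next_save = t + save_dt
        if phase_idx == 1:
            i_end_creep = len(recs["t"]) - 1
    if i_end_creep < 0:  # no creep phase in a custom history: use the load peak
        i_end_creep = int(np.argmax(np.abs(np.asarray(recs["p"]))))

    return ContinuumSolution(
        r=r,
        r_mid=0.5 * (r[:-1] + r[1:]),
        times=np.asarray(recs["t"]),
        load=np.asarray(recs["p"]),
        u=np.asarray(recs["u"]),
        sigma_rr=np.asarray(recs["s_rr"]),
        sigma_tt=np.asarray(recs["s_tt"]),
        sigma_vm=np.asarray(recs["s_vm"]),
        eps_p_eq=np.asarray(recs["epsp_eq"]),
        eps1_max=np.asarray(recs["eps1"]),
        modulus=np.asarray(recs["E"]),
        i_end_creep=i_end_creep,
        config=config.to_dict(),
    )


# ----------------------------------------------------------------------
def recoverability_index_model(solution: ContinuumSolution) -> float:
    """Recoverability index at the cell-ECM interface, percent.

    100 × (displacement recovered on unload) / (displacement at the end of
    creep), both measured at r = a.  NaN when the total displacement is zero.
    """
    u_a = solution.u_cell()
    u_creep = abs(float(u_a[solution.i_end_creep]))
    u_final = abs(float(u_a[-1]))
    if u_creep <= 0.0:
        return float("nan")
    return 100.0 * (u_creep - u_final) / u_creep


def damage_radius(solution: ContinuumSolution, half: float = 0.5):
    """Radial extent of the damaged zone at the end of the run.

    The damage variable D(r) = (E_s − E(r))/(E_s − E_e) is scaled to its
    maximum attained value; the damage radius is the outermost radius
    (measured from the cell edge) where the scaled damage is >= ``half``.
    Returns (radius_μm, radius_in_cell_diameters); (0, 0) without damage.
    """
    cfg = solution.config
    e_s, e_e = cfg["E_s"], cfg["E_e"]
    d = (e_s - solution.modulus[-1]) / (e_s - e_e)
    dmax = float(d.max(initial=0.0))
    if dmax <= 1e-9:
        return 0.0, 0.0
    thresh = half * dmax
    above = d >= thresh
    idx = int(np.max(np.flatnonzero(above)))
    r_mid = solution.r_mid
    if idx < len(d) - 1:
        # linear interpolation to the crossing between midpoints idx, idx+1
        d0, d1 = d[idx], d[idx + 1]
        frac = (d0 - thresh) / (d0 - d1) if d0 != d1 else 0.0
        r_half = r_mid[idx] + frac * (r_mid[idx + 1] - r_mid[idx])
    else:
        r_half = r_mid[idx]
    a = solution.cell_radius
    dist = max(float(r_half - a), 0.0)
    return dist, dist / (2.0 * a)


@dataclass
class StressRatioProfile:
    r_mid: np.ndarray
    ratio_total: np.ndarray   # apparent (from total deformation) / true
    ratio_relax: np.ndarray   # apparent (from unload recovery, TFM-style) / true
    peak_total: float
    peak_relax: float


def apparent_true_stress_ratio(
    solution: ContinuumSolution, config: ContinuumConfig, support: float = 0.05
) -> StressRatioProfile:
    """Error made by back-calculating stress with undamaged linear elasticity.

    Two apparent stresses are formed from the model's own displacement
    fields, both evaluated with the pristine modulus E_s and no plasticity:
    from the total deformation at the end of creep, and from the deformation
    recovered on unload (the traction-force-microscopy protocol).  The
    comparison uses the radial stress component — the normal stress a
    traction reconstruction actually reports — so that in the damage-only
    limit the ratio reduces exactly to the modulus degradation E_s/E(r),
    while the von Mises ratio would additionally fold in deviatoric plastic
    relaxation of the true stress.  Each apparent stress is divided by the
    model's true radial stress at the end of creep; the profile is reported
    where the true stress exceeds ``support`` times its maximum, and the
    peak over that region is returned.
    """
    i = solution.i_end_creep
    r = solution.r
    zeros = np.zeros(len(r) - 1)

    def srr_from_u(u):
        eps_rr, eps_tt = _strains(r, u)
        s_rr, _, _, _ = _stresses(eps_rr, eps_tt, zeros, zeros, config.E_s, config.nu)
        return np.abs(s_rr)

    rr_true = np.abs(solution.sigma_rr[i])
    rr_total = srr_from_u(solution.u[i])
    rr_relax = srr_from_u(solution.u[i] - solution.u[-1])
    mask = rr_true > support * rr_true.max()
    ratio_total = np.full_like(rr_true, np.nan)
    ratio_relax = np.full_like(rr_true, np.nan)
    ratio_total[mask] = rr_total[mask] / rr_true[mask]
    ratio_relax[mask] = rr_relax[mask] / rr_true[mask]
    return StressRatioProfile(
        r_mid=solution.r_mid,
        ratio_total=ratio_total,
        ratio_relax=ratio_relax,
        peak_total=float(np.nanmax(ratio_total)),
        peak_relax=float(np.nanmax(ratio_relax)),
    )


def elastic_decay_exponent(
    solution: ContinuumSolution, fit_range: tuple = (2.0, 5.0)
) -> float:
    """Log-log slope of |u(r)| vs r over the far field, at full load.

    ``fit_range`` is in cell radii.  For an isotropic linear elastic medium
    the pressurized-cavity solution u ∝ r⁻² gives a slope of −2.
    """
    a = solution.cell_radius
    i = solution.i_end_creep
    mask = (solution.r >= fit_range[0] * a) & (solution.r <= fit_range[1] * a)
    uu = np.abs(solution.u[i][mask])
    if np.any(uu <= 0):
        raise ValueError("displacement vanishes inside the fit range")
    slope = np.polyfit(np.log(solution.r[mask]), np.log(uu), 1)[0]
    return float(slope)
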