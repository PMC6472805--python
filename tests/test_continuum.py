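"""Spherical viscoplastic solver: constitutive laws, the pressurized-cavity
elastic oracle, damage/softening behavior and the back-calculation error."""

import numpy as np
import pytest

from ecmdyn.config import ContinuumConfig, continuum_baseline, continuum_elastic
from ecmdyn.continuum import (
    apparent_true_stress_ratio,
    creep_rate,
    damage_modulus,
    damage_radius,
    elastic_decay_exponent,
    recoverability_index_model,
    solve_sphere,
    yield_stress,
)


# ------------------------------------------------------- damage modulus
def test_damage_anchor_values():
    cfg = continuum_baseline()
    assert damage_modulus(cfg.eps_1s, cfg) == pytest.approx(1000.0)
    assert damage_modulus(cfg.eps_1e, cfg) == pytest.approx(200.0)
    assert damage_modulus(0.0, cfg) == pytest.approx(1000.0)
    assert damage_modulus(1.0, cfg) == pytest.approx(200.0)


def test_damage_exponential_between_anchors():
    """E = A·exp(−B·ε₁) with B solving the two anchor conditions."""
    cfg = continuum_baseline()
    b = np.log(cfg.E_s / cfg.E_e) / (cfg.eps_1e - cfg.eps_1s)
    a = cfg.E_s * np.exp(b * cfg.eps_1s)
    eps = np.linspace(cfg.eps_1s, cfg.eps_1e, 17)
    assert np.allclose(damage_modulus(eps, cfg), a * np.exp(-b * eps), rtol=1e-12)
    # continuity at both anchors
    h = 1e-9
    for anchor in (cfg.eps_1s, cfg.eps_1e):
        assert damage_modulus(anchor - h, cfg) == pytest.approx(
            damage_modulus(anchor + h, cfg), rel=1e-6
        )


def test_damage_monotone_nonincreasing():
    cfg = continuum_baseline()
    eps = np.linspace(0, 0.1, 200)
    e = damage_modulus(eps, cfg)
    assert np.all(np.diff(e) <= 1e-12)


# ---------------------------------------------------------- yield stress
def test_yield_constant_before_critical_strain():
    cfg = continuum_baseline()
    assert yield_stress(0.0, cfg) == cfg.sigma_y0
    assert yield_stress(cfg.eps_p_crit, cfg) == pytest.approx(cfg.sigma_y0)


def test_yield_perfect_plasticity_with_zero_slope():
    cfg = continuum_baseline(softening_slope=0.0)
    assert np.allclose(yield_stress(np.linspace(0, 2, 9), cfg), cfg.sigma_y0)


def test_yield_piecewise_linear_and_floored():
    cfg = continuum_baseline()
    eps = cfg.eps_p_crit + 0.01
    expected = cfg.sigma_y0 + cfg.softening_slope * 0.01
    assert yield_stress(eps, cfg) == pytest.approx(expected)
    assert yield_stress(10.0, cfg) == cfg.sigma_y_min


# ------------------------------------------------------------ creep law
def test_no_creep_below_yield():
    cfg = continuum_baseline()
    assert creep_rate(cfg.sigma_y0 - 1.0, cfg) == 0.0


def test_bingham_limit_linear_in_overstress():
    cfg = continuum_baseline(nh_exponent=1.0)
    r1 = creep_rate(cfg.sigma_y0 + 10.0, cfg)
    r2 = creep_rate(cfg.sigma_y0 + 20.0, cfg)
    assert r2 == pytest.approx(2.0 * r1)


def test_power_law_doubling_identity():
    cfg = continuum_baseline(nh_exponent=2.0)
    r1 = creep_rate(cfg.sigma_y0 + 30.0, cfg)
    r2 = creep_rate(cfg.sigma_y0 + 60.0, cfg)
    assert r2 == pytest.approx(2.0**cfg.nh_exponent * r1)


# -------------------------------------------------- elastic cavity oracle
def test_elastic_displacement_matches_cavity_closed_form(continuum_elastic_solution):
    """u(r) = −p a³/(4G r²) for an inward traction p on the cavity wall."""
    cfg, sol = continuum_elastic_solution
    g = cfg.E_s / (2.0 * (1.0 + cfg.nu))
    i = sol.i_end_creep
    analytic = -cfg.load * cfg.cell_radius**3 / (4.0 * g * sol.r**2)
    # compare where the fixed outer boundary (at 50a) has negligible effect
    inner = sol.r < 5.0 * cfg.cell_radius
    assert np.allclose(sol.u[i][inner], analytic[inner], rtol=5e-3)


def test_elastic_full_recovery_and_unit_stress_ratio(continuum_elastic_solution):
    cfg, sol = continuum_elastic_solution
    assert recoverability_index_model(sol) == pytest.approx(100.0, abs=1e-6)
    ratio = apparent_true_stress_ratio(sol, cfg)
    assert np.nanmax(np.abs(ratio.ratio_total - 1.0)) < 1e-6
    assert np.nanmax(np.abs(ratio.ratio_relax - 1.0)) < 1e-6
    assert damage_radius(sol) == (0.0, 0.0)


def test_elastic_decay_exponent_on_solver_field(continuum_elastic_solution):
    _, sol = continuum_elastic_solution
    assert elastic_decay_exponent(sol) == pytest.approx(-2.0, abs=0.02)


def test_decay_exponent_independent_of_load():
    sols = []
    for p in (10.0, 50.0):
        cfg = continuum_elastic(load=p, n_r=160)
        sols.append(elastic_decay_exponent(solve_sphere(cfg)))
    assert sols[0] == pytest.approx(sols[1], abs=1e-6)


def test_analytic_profile_fit_is_exactly_minus_two():
    """Sampling the closed form on the grid and fitting recovers −2.000."""
    r = np.geomspace(10.0, 500.0, 200)
    u = 1.0 / r**2
    slope = np.polyfit(np.log(r[(r > 20) & (r < 50)]), np.log(u[(r > 20) & (r < 50)]), 1)[0]
    assert slope == pytest.approx(-2.0, abs=1e-10)


# ------------------------------------------------- damage and softening
def test_softening_reduces_recoverability(continuum_baseline_pair):
    (cfg_s, sol_s), (cfg_n, sol_n) = continuum_baseline_pair
    ri_soft = recoverability_index_model(sol_s)
    ri_nosoft = recoverability_index_model(sol_n)
    assert ri_soft < ri_nosoft
    assert 0.0 < ri_soft < 100.0


def test_damage_irreversibility_pointwise(continuum_baseline_pair):
    (_, sol), _ = continuum_baseline_pair
    assert np.all(np.diff(sol.modulus, axis=0) <= 1e-9)
    assert np.all((sol.modulus >= 200.0 - 1e-9) & (sol.modulus <= 1000.0 + 1e-9))


def test_plastic_strain_monotone_nondecreasing(continuum_baseline_pair):
    (_, sol), _ = continuum_baseline_pair
    assert np.all(np.diff(sol.eps_p_eq, axis=0) >= -1e-12)


def test_damage_radius_grows_with_creep_time():
    cfg = continuum_baseline()
    radii = []
    for creep in (300.0, 3600.0):
        sol = solve_sphere(cfg.replace(creep_duration=creep))
        radii.append(damage_radius(sol)[0])
    assert radii[1] > radii[0] > 0.0


def test_damage_radius_grows_with_earlier_onset_strain():
    cfg = continuum_baseline()
    r_early = damage_radius(solve_sphere(cfg.replace(eps_1s=0.01)))[0]
    r_late = damage_radius(solve_sphere(cfg.replace(eps_1s=0.03)))[0]
    assert r_early > r_late


def test_damage_radius_shrinks_with_higher_end_strain():
    cfg = continuum_baseline()
    r_low = damage_radius(solve_sphere(cfg.replace(eps_1e=0.04)))[0]
    r_high = damage_radius(solve_sphere(cfg.replace(eps_1e=0.10)))[0]
    assert r_high < r_low


def test_increasing_load_decreases_recoverability():
    cfg = continuum_baseline(creep_duration=600.0)
    ri = [recoverability_index_model(solve_sphere(cfg.replace(load=p)))
          for p in (50.0, 150.0)]
    assert ri[1] < ri[0]


def test_stress_ratio_exceeds_one_wherever_damage_occurred():
    """With damage alone (no plasticity) the apparent and true stresses come
    from the same strain field, so their ratio is exactly E_s/E(r) >= 1."""
    cfg = continuum_baseline(plasticity_enabled=False)
    sol = solve_sphere(cfg)
    ratio = apparent_true_stress_ratio(sol, cfg)
    damaged = sol.modulus[-1] < 0.99 * cfg.E_s
    vals = ratio.ratio_relax[damaged]
    vals = vals[~np.isnan(vals)]
    assert len(vals) > 0
    assert np.all(vals >= 1.0 - 1e-9)
    assert vals.max() == pytest.approx(cfg.E_s / cfg.E_e, rel=1e-3)


def test_stress_ratio_profile_decays_with_distance(continuum_baseline_pair):
    (cfg, sol), _ = continuum_baseline_pair
    ratio = apparent_true_stress_ratio(sol, cfg)
    vals = ratio.ratio_relax[~np.isnan(ratio.ratio_relax)]
    assert vals[0] == pytest.approx(ratio.peak_relax)
    assert vals[-1] < 0.4 * vals[0]
    assert abs(vals[-1] - 1.0) < 0.3


def test_dissipated_work_nonnegative(continuum_baseline_pair):
    """Cumulative plastic dissipation sigma_vm·dε_p is non-negative."""
    (_, sol), _ = continuum_baseline_pair
    deps = np.diff(sol.eps_p_eq, axis=0)
    svm = 0.5 * (sol.sigma_vm[1:] + sol.sigma_vm[:-1])
    w = np.sum(deps * svm, axis=0)
    assert np.all(w >= -1e-12)


def test_convergence_under_refinement():
    """Halving the grid spacing and plastic step changes RI and the damage
    radius by less than 1%."""
    coarse = continuum_baseline(n_r=120)
    fine = continuum_baseline(n_r=240, deps_p_cap=7.5e-4, dt_max=10.0)
    sol_c = solve_sphere(coarse)
    sol_f = solve_sphere(fine)
    ri_c, ri_f = (recoverability_index_model(s) for s in (sol_c, sol_f))
    dr_c, dr_f = (damage_radius(s)[0] for s in (sol_c, sol_f))
    assert abs(ri_f - ri_c) / ri_f < 0.01
    assert abs(dr_f - dr_c) / dr_f < 0.01


def test_config_validation():
    with pytest.raises(ValueError):
        ContinuumConfig(E_e=0.0)
    with pytest.raises(ValueError):
        ContinuumConfig(eps_1s=0.06, eps_1e=0.02)
    with pytest.raises(ValueError):
        ContinuumConfig(outer_radius=5.0, cell_radius=10.0)
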