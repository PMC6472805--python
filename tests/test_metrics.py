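"""Remodeling metrics on synthetic fields with known ground truth."""

import numpy as np
import pytest

from ecmdyn import metrics as mm


@pytest.fixture(scope="module")
def clean_fixture():
    return mm.synth_fixture(seed=3, decay_exponent=2.0, elastic_fraction=0.5,
                            densification_ratio=2.0)


# ----------------------------------------------------- displacement length
def test_uniform_field_mean_magnitude():
    data = np.zeros((41, 41, 41, 3))
    data[..., 0] = 2.0
    f = mm.DisplacementField(data, spacing=1.0)
    assert mm.displacement_length(f, [20, 20, 20], 30.0) == pytest.approx(2.0)


def test_zero_field():
    f = mm.DisplacementField(np.zeros((21, 21, 21, 3)), 1.0)
    assert mm.displacement_length(f, [10, 10, 10], 10.0) == 0.0


def test_displacement_length_matches_voxel_loop():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(31, 31, 31, 3))
    f = mm.DisplacementField(data, spacing=1.0)
    got = mm.displacement_length(f, [15, 15, 15], 20.0)
    total, count = 0.0, 0
    for i in range(5, 26):
        for j in range(5, 26):
            for k in range(5, 26):
                total += np.sqrt((data[i, j, k] ** 2).sum())
                count += 1
    assert got == pytest.approx(total / count, abs=1e-12)


def test_roi_exceeding_grid_fails():
    f = mm.DisplacementField(np.zeros((21, 21, 21, 3)), 1.0)
    with pytest.raises(ValueError, match="exceeds"):
        mm.displacement_length(f, [10, 10, 10], 60.0)


def test_metric_linearity(clean_fixture):
    """Scaling the field by c scales the length by c; RI and the normalized
    decay profile are scale invariant."""
    fx = clean_fixture
    c = fx.cell_center
    l1 = mm.displacement_length(fx.overall, c, 60.0)
    scaled = mm.DisplacementField(3.0 * fx.overall.data, fx.overall.spacing)
    assert mm.displacement_length(scaled, c, 60.0) == pytest.approx(3.0 * l1)
    _, p1 = mm.radial_decay_profile(fx.overall, c, 10.0)
    _, p2 = mm.radial_decay_profile(scaled, c, 10.0)
    assert np.allclose(p1, p2)


# ------------------------------------------------------------------- DF
def test_uniform_intensity_df_is_one(clean_fixture):
    mask = clean_fixture.intensity.cell_mask
    vol = mm.IntensityVolume(np.ones(mask.shape), 1.0, mask)
    assert mm.densification_factor(vol) == pytest.approx(1.0, abs=1e-9)


def test_df_recovers_shell_ratio(clean_fixture):
    assert mm.densification_factor(clean_fixture.intensity) == pytest.approx(2.0, rel=0.02)


def test_df_invariant_to_global_rescale(clean_fixture):
    vol = clean_fixture.intensity
    scaled = mm.IntensityVolume(5.0 * vol.data, vol.spacing, vol.cell_mask)
    assert mm.densification_factor(scaled) == pytest.approx(
        mm.densification_factor(vol), rel=1e-12
    )


def test_df_zero_far_field_fails(clean_fixture):
    mask = clean_fixture.intensity.cell_mask
    data = np.zeros(mask.shape)
    rr_shell = clean_fixture.intensity.data > 1.5
    data[rr_shell] = 2.0  # densified shell but background-free far field
    vol = mm.IntensityVolume(data, 1.0, mask)
    with pytest.raises(ValueError, match="far-field"):
        mm.densification_factor(vol)


# ------------------------------------------------------------------- RI
@pytest.mark.parametrize("ld,lo,expected", [(4.0, 4.0, 100.0), (1.0, 4.0, 25.0)])
def test_ri_substitution(ld, lo, expected):
    assert mm.recoverability_index(ld, lo) == pytest.approx(expected)


def test_ri_zero_overall_flagged():
    with pytest.warns(RuntimeWarning, match="undefined"):
        assert np.isnan(mm.recoverability_index(1.0, 0.0))


def test_ri_above_100_reported_with_warning():
    with pytest.warns(RuntimeWarning, match="exceeds 100"):
        assert mm.recoverability_index(5.0, 4.0) == pytest.approx(125.0)


# ------------------------------------------------------------ decay profile
def test_profile_matches_closed_form(clean_fixture):
    fx = clean_fixture
    ds, prof = mm.radial_decay_profile(fx.overall, fx.cell_center, 10.0,
                                       max_distance=15.0)
    expected = (10.0 / (10.0 + ds)) ** 2
    assert prof[0] == pytest.approx(1.0)
    assert np.allclose(prof, expected, atol=5e-3)


def test_profile_log_slope(clean_fixture):
    fx = clean_fixture
    ds, prof = mm.radial_decay_profile(fx.overall, fx.cell_center, 10.0,
                                       max_distance=15.0)
    slope = np.polyfit(np.log(10.0 + ds), np.log(prof), 1)[0]
    assert slope == pytest.approx(-2.0, abs=0.02)


def test_zero_membrane_value_flagged():
    f = mm.DisplacementField(np.zeros((41, 41, 41, 3)), 1.0)
    with pytest.warns(RuntimeWarning, match="membrane"):
        _, prof = mm.radial_decay_profile(f, [20, 20, 20], 5.0, max_distance=5.0)
    assert np.all(np.isnan(prof))


# ------------------------------------------------------------- fixture
def test_fixture_field_identity(clean_fixture):
    """plastic = overall − decell holds per voxel by construction."""
    fx = clean_fixture
    assert np.allclose(fx.plastic.data, fx.overall.data - fx.decell.data)


def test_fully_elastic_fixture_gives_ri_100():
    fx = mm.synth_fixture(seed=0, elastic_fraction=1.0)
    c = fx.cell_center
    lo = mm.displacement_length(fx.overall, c, 60.0)
    ld = mm.displacement_length(fx.decell, c, 60.0)
    assert mm.recoverability_index(ld, lo) == pytest.approx(100.0)


def test_parameter_recovery_under_noise():
    """Random (n, f, densification ratio) are recovered within 3% at
    displacement noise of 5% of u0, across 20 seeds."""
    rng = np.random.default_rng(99)
    dirs = rng.normal(size=(64, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    u0 = 2.0
    noise = 0.05 * u0
    errs = []
    for seed in range(20):
        draw = np.random.default_rng(seed)
        n = draw.uniform(1.5, 2.5)
        f = draw.uniform(0.3, 0.9)
        ratio = draw.uniform(1.5, 3.0)
        fx = mm.synth_fixture(seed=seed, decay_exponent=n, elastic_fraction=f,
                              densification_ratio=ratio, u0=u0, noise_sd=noise,
                              intensity_noise_sd=0.02)
        c = fx.cell_center
        lo = mm.displacement_length(fx.overall, c, 60.0)
        ld = mm.displacement_length(fx.decell, c, 60.0)
        ri = mm.recoverability_index(ld, lo)
        df = mm.densification_factor(fx.intensity, directions=dirs[:16])
        n_hat = mm.fit_decay_exponent(fx.overall, c, 10.0, directions=dirs,
                                      noise_sd=noise)
        errs.append([abs(n_hat - n) / n, abs(ri / 100.0 - f) / f,
                     abs(df - ratio) / ratio])
    errs = np.array(errs)
    assert np.all(errs.max(axis=0) < 0.03)
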