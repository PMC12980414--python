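"""SAXS core: Debye profiles, chi^2, averaging, Guinier, P(r)."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sbmsaxs as sx
from sbmsaxs import synthetic as syn
from sbmsaxs.saxs import (ELEMENT_F0, angle_from_q, form_factors,
                          sphere_profile)
from conftest import random_cloud_structure, two_atom_structure


# -- q conversion ------------------------------------------------------

def test_q_zero_at_zero_angle():
    assert sx.q_from_angle(0.0, 1.548) == 0.0


def test_q_at_backscattering_with_instrument_wavelength():
    """Full backscattering (2theta = pi) gives q = 4 pi / lambda."""
    lam = 1.548
    assert sx.q_from_angle(np.pi, lam) == pytest.approx(4 * np.pi / lam)


@given(st.floats(0.01, 3.0))
def test_angle_q_roundtrip(two_theta):
    lam = 1.548
    assert angle_from_q(sx.q_from_angle(two_theta, lam), lam) == \
        pytest.approx(two_theta, rel=1e-12)


def test_four_gaussian_form_factors_hit_electron_count_at_zero():
    f = form_factors(np.array(["C", "N", "O", "S", "H"]), np.zeros(1),
                     model="four_gaussian")[:, 0]
    for val, elem in zip(f, ("C", "N", "O", "S", "H")):
        assert val == pytest.approx(ELEMENT_F0[elem], abs=0.05)


# -- Debye profile -----------------------------------------------------

def test_single_atom_unit_form_factor(q_grid):
    s = two_atom_structure().subset(np.array([True, False]))
    c = sx.debye_profile(s, q_grid, form_factor_model="unit")
    np.testing.assert_allclose(c.I, 1.0)


def test_two_scatterer_closed_form(q_grid):
    d = 10.0
    c = sx.debye_profile(two_atom_structure(d), q_grid,
                         form_factor_model="unit")
    np.testing.assert_allclose(c.I, 2 + 2 * np.sin(q_grid * d) / (q_grid * d),
                               atol=1e-12)


def debye_double_loop(coord, f, q):
    """Literal O(N^2) double-sum oracle."""
    out = np.zeros_like(q)
    for a, qv in enumerate(q):
        total = 0.0
        for i in range(len(coord)):
            for j in range(len(coord)):
                r = np.linalg.norm(coord[i] - coord[j])
                x = qv * r
                total += f[i] * f[j] * (np.sin(x) / x if x > 0 else 1.0)
        out[a] = total
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_debye_matches_double_loop_oracle(seed, q_grid):
    s = random_cloud_structure(20, seed=seed)
    c = sx.debye_profile(s, q_grid)
    f = form_factors(s.element, np.zeros(1))[:, 0]
    oracle = debye_double_loop(s.coord, f, q_grid)
    np.testing.assert_allclose(c.I, oracle, rtol=1e-10)


def test_binned_profiles_match_exact_path(q_grid):
    """The radial-binning acceleration agrees with the exact Debye sum
    to well below counting noise."""
    from sbmsaxs.saxs import debye_profiles
    rng = np.random.default_rng(11)
    frames = rng.uniform(0, 15, (8, 25, 3))
    elements = np.array(["C"] * 25)
    exact = debye_profiles(frames, elements, q_grid)
    binned = debye_profiles(frames, elements, q_grid, method="binned")
    np.testing.assert_allclose(binned, exact, rtol=1e-5)
    single = sx.debye_profile(sx.MolecularStructure(
        serial=np.arange(1, 26), name=np.array(["X"] * 25),
        element=elements, res_index=np.arange(1, 26),
        res_name=np.array(["GLY"] * 25), chain_id=np.array(["A"] * 25),
        coord=frames[0]), q_grid)
    np.testing.assert_allclose(exact[0], single.I, rtol=1e-12)


def test_debye_invariant_under_rigid_motion(q_grid):
    s = random_cloud_structure(15, seed=3)
    I0 = sx.debye_profile(s, q_grid).I
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    moved = s.with_coord(s.coord @ R.T + np.array([5.0, -3.0, 2.0]))
    I1 = sx.debye_profile(moved, q_grid).I
    np.testing.assert_allclose(I1, I0, rtol=1e-10)


def test_intensity_positive_and_maximal_at_low_q(q_grid):
    s = random_cloud_structure(25, seed=4)
    c = sx.debye_profile(s, q_grid)
    assert np.all(c.I > 0)
    assert np.argmax(c.I) == 0
    # I(0) equals (sum f)^2
    f = form_factors(s.element, np.zeros(1))[:, 0]
    i0 = sx.debye_profile(s, np.array([1e-9, 1e-8]))
    assert i0.I[0] == pytest.approx(f.sum() ** 2, rel=1e-8)


# -- chi^2 -------------------------------------------------------------

def test_perfect_fit_gives_unit_scale_zero_chi2(q_grid):
    s = random_cloud_structure(20, seed=5)
    th = sx.debye_profile(s, q_grid)
    exp = sx.ScatteringCurve(q_grid, th.I.copy(), 0.03 * th.I)
    fit = sx.chi_square(exp, th)
    assert fit.scale == pytest.approx(1.0, rel=1e-12)
    assert fit.chi2 == pytest.approx(0.0, abs=1e-20)
    np.testing.assert_allclose(sx.residual_curve(fit).residuals, 0, atol=1e-9)


@given(st.floats(0.1, 30.0))
def test_scale_recovered_exactly(factor):
    q = np.linspace(0.02, 0.3, 40)
    s = random_cloud_structure(12, seed=6)
    th = sx.debye_profile(s, q)
    exp = sx.ScatteringCurve(q, factor * th.I, 0.01 * th.I + 1.0)
    fit = sx.chi_square(exp, th)
    assert fit.scale == pytest.approx(factor, rel=1e-9)
    assert fit.chi2 == pytest.approx(0.0, abs=1e-16)


def test_chi2_invariant_to_theoretical_rescaling(q_grid):
    s = random_cloud_structure(20, seed=7)
    th = sx.debye_profile(s, q_grid)
    exp = syn.synth_saxs(s, q_grid, seed=7)
    f1 = sx.chi_square(exp, th)
    f2 = sx.chi_square(exp, sx.ScatteringCurve(q_grid, 7.5 * th.I))
    assert f2.chi2 == pytest.approx(f1.chi2, rel=1e-9)
    assert f2.scale == pytest.approx(f1.scale / 7.5, rel=1e-9)


def test_chi2_calibration_and_scale_error(two_domain, q_grid):
    """Poisson-count synthetic curves against their generating model:
    mean chi^2 near 1 and the known scale inside 3 standard errors."""
    s = two_domain[0]
    th = sx.debye_profile(s, q_grid)
    chis, scales = [], []
    for seed in range(25):
        exp = syn.synth_saxs(s, q_grid, mean_counts=1e4, seed=seed)
        fit = sx.chi_square(exp, th)
        chis.append(fit.chi2)
        scales.append(fit.scale)
    assert 0.85 < np.mean(chis) < 1.15
    se = np.std(scales) / np.sqrt(len(scales))
    assert abs(np.mean(scales) - 1.0) < 3 * se + 1e-3


def test_zero_sigma_rejected(q_grid):
    th = sx.ScatteringCurve(q_grid, np.ones_like(q_grid))
    exp = sx.ScatteringCurve(q_grid, np.ones_like(q_grid),
                             np.ones_like(q_grid))
    exp.sigma[3] = 1.0
    exp.sigma = np.where(np.arange(len(q_grid)) == 3, 0.0, 1.0)
    with pytest.raises(sx.SAXSError):
        sx.chi_square(exp, th)


def test_non_overlapping_q_ranges_rejected():
    th = sx.ScatteringCurve(np.linspace(0.3, 0.5, 10), np.ones(10))
    exp = sx.ScatteringCurve(np.linspace(0.01, 0.1, 10), np.ones(10),
                             np.ones(10))
    with pytest.raises(sx.SAXSError, match="extrapolation"):
        sx.chi_square(exp, th)


# -- residual diagnostics ----------------------------------------------

def test_systematic_offset_flagged_by_runs_statistic(two_domain, q_grid):
    s = two_domain[0]
    th = sx.debye_profile(s, q_grid)
    exp = syn.synth_saxs(s, q_grid, mean_counts=1e4, seed=1)
    shifted = sx.ScatteringCurve(exp.q, exp.I + 40 * exp.sigma, exp.sigma)
    summary = sx.residual_curve(sx.chi_square(shifted, th))
    # a constant additive offset leaves one-signed blocks of residuals
    assert summary.systematic


def test_pure_noise_residual_mean_within_clt_bound(two_domain, q_grid):
    s = two_domain[0]
    th = sx.debye_profile(s, q_grid)
    means = []
    for seed in range(10):
        exp = syn.synth_saxs(s, q_grid, mean_counts=1e4, seed=100 + seed)
        summary = sx.residual_curve(sx.chi_square(exp, th))
        means.append(summary.mean)
        assert abs(summary.mean) < 3.0 / np.sqrt(len(q_grid))
    assert np.mean(np.abs(means)) < 3.0 / np.sqrt(len(q_grid))


# -- averaging ---------------------------------------------------------

def test_average_identical_curves_shrinks_sigma(q_grid):
    c = sx.ScatteringCurve(q_grid, np.ones_like(q_grid),
                           0.5 * np.ones_like(q_grid))
    avg = sx.average_curves([c, c, c])
    np.testing.assert_allclose(avg.I, 1.0)
    np.testing.assert_allclose(avg.sigma, 0.5 / np.sqrt(3))


def test_average_ignores_infinite_uncertainty_curve(q_grid):
    good = sx.ScatteringCurve(q_grid, np.full_like(q_grid, 2.0),
                              np.ones_like(q_grid))
    bad = sx.ScatteringCurve(q_grid, np.full_like(q_grid, 99.0),
                             np.full_like(q_grid, 1e12))
    avg = sx.average_curves([good, bad])
    np.testing.assert_allclose(avg.I, 2.0, rtol=1e-12)


def test_average_two_points_hand_arithmetic():
    q = np.array([0.1])
    a = sx.ScatteringCurve(q, np.array([0.0]), np.array([1.0]))
    b = sx.ScatteringCurve(q, np.array([2.0]), np.array([1.0]))
    avg = sx.average_curves([a, b])
    assert avg.I[0] == pytest.approx(1.0)
    assert avg.sigma[0] == pytest.approx(1 / np.sqrt(2))


# -- Guinier -----------------------------------------------------------

def test_exact_gaussian_curve_recovers_rg():
    rg = 20.0
    q = np.linspace(0.002, 0.2, 300)
    c = sx.ScatteringCurve(q, 5.0 * np.exp(-(q * rg) ** 2 / 3.0))
    res = sx.guinier_fit(c)
    assert res.rg == pytest.approx(rg, abs=1e-6)
    assert res.i0 == pytest.approx(5.0, rel=1e-9)


def test_sphere_oracle_rg():
    """Analytic sphere: Rg = sqrt(3/5) R (conservative q window, since
    the Guinier expansion overestimates Rg by ~2% already at qRg=1.3)."""
    R = 20.0
    q = np.linspace(0.005, 0.2, 400)
    res = sx.guinier_fit(sphere_profile(R, q), qmax_rg_limit=0.9)
    assert res.rg == pytest.approx(np.sqrt(3 / 5) * R, rel=0.01)


def test_noisy_gaussian_rg_within_5_percent():
    rg = 20.0
    q = np.linspace(0.004, 0.15, 120)
    errs = []
    for seed in range(25):
        rng = np.random.default_rng(seed)
        I = np.exp(-(q * rg) ** 2 / 3.0)
        noisy = I * (1 + rng.normal(0, 0.02, len(q)))
        res = sx.guinier_fit(sx.ScatteringCurve(q, noisy))
        errs.append(abs(res.rg - rg) / rg)
    assert np.mean(errs) < 0.05


def test_no_guinier_region_raises():
    q = np.linspace(0.01, 0.1, 30)
    rising = sx.ScatteringCurve(q, 1.0 + 10 * q ** 2)
    with pytest.raises(sx.SAXSError, match="Guinier"):
        sx.guinier_fit(rising)


# -- P(r) --------------------------------------------------------------

def test_two_atom_pr_single_bin():
    s = two_atom_structure(10.0)
    pr = sx.pr_from_structure(s, bin_width=1.0)
    assert pr.dmax == pytest.approx(10.0)
    assert pr.p[0] == 0.0
    occupied = pr.r[pr.p > 0]
    assert len(occupied) == 1
    assert abs(occupied[0] - 10.0) <= 0.5


def test_dmax_equals_bruteforce_max_distance(two_domain):
    from scipy.spatial.distance import pdist
    s = two_domain[0]
    pr = sx.pr_from_structure(s, bin_width=0.5)
    assert pr.dmax == pytest.approx(pdist(s.coord).max())


def test_pr_second_moment_rg_matches_coordinates(two_domain):
    """Rg from P(r) moments agrees with the direct coordinate formula."""
    s = two_domain[0]
    pr = sx.pr_from_structure(s, bin_width=0.5, form_factor_model="unit")
    assert pr.rg == pytest.approx(s.radius_of_gyration(), abs=0.5)


def test_ift_recovers_planted_two_gaussian_pr():
    """Forward-synthesize I(q) from a known P(r), invert, compare."""
    r = np.linspace(0, 40, 81)
    p_true = (np.exp(-((r - 12) / 4.0) ** 2) +
              0.6 * np.exp(-((r - 25) / 5.0) ** 2))
    p_true[0] = p_true[-1] = 0.0
    q = np.linspace(0.01, 0.45, 120)
    A = np.sinc(np.outer(q, r) / np.pi)
    I = A @ p_true * (r[1] - r[0])
    sigma = 0.002 * I.max() * np.ones_like(I)
    rng = np.random.default_rng(0)
    curve = sx.ScatteringCurve(q, I + rng.normal(0, sigma), sigma)
    rec = sx.pr_from_curve(curve, dmax_guess=40.0, n_r=81)
    p_interp = np.interp(r, rec.r, rec.p)
    corr = np.corrcoef(p_interp, p_true)[0, 1]
    assert corr > 0.99


def test_sphere_pr_support_bounded_by_diameter():
    R = 15.0
    q = np.linspace(0.008, 0.5, 200)
    c = sphere_profile(R, q)
    curve = sx.ScatteringCurve(c.q, c.I, 0.001 * c.I.max()
                               * np.ones_like(c.I))
    rec = sx.pr_from_curve(curve, dmax_guess=2.5 * R, n_r=70)
    beyond = rec.p[rec.r > 2 * R + 2.0]
    assert np.all(beyond <= 0.02 * rec.p.max() + 1e-12)


def test_pr_curve_structure_roundtrip_rg(two_domain, q_grid):
    s = two_domain[0]
    exp = syn.synth_saxs(s, q_grid, mean_counts=1e6, seed=0)
    direct = sx.pr_from_structure(s, bin_width=1.0)
    inverted = sx.pr_from_curve(exp, dmax_guess=1.4 * direct.dmax)
    assert inverted.rg == pytest.approx(direct.rg, rel=0.05)


# -- file I/O ----------------------------------------------------------

def test_curve_file_roundtrip(tmp_path, q_grid, two_domain):
    exp = syn.synth_saxs(two_domain[0], q_grid, seed=0)
    path = tmp_path / "curve.dat"
    sx.save_curve(exp, path, header="test")
    back = sx.load_curve(path)
    np.testing.assert_allclose(back.q, exp.q, rtol=1e-7)
    np.testing.assert_allclose(back.I, exp.I, rtol=1e-6)
    np.testing.assert_allclose(back.sigma, exp.sigma, rtol=1e-6)
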