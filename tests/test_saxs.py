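"""saxs: q conversion, Guinier analysis, Mw calibration, form factors,
indirect Fourier transform p(r), Dmax scan, ASCII I/O."""

import numpy as np
import pytest

from bundlestab.saxs import (GuinierResult, NoGuinierRegimeError, SAXSProfile,
                             cylinder_form_factor, dmax_scan, form_factor,
                             guinier_fit, ift_pr, mw_from_forward_scattering,
                             read_dat, scattering_vector, sphere_form_factor,
                             sphere_pr, write_dat, write_pr)
from bundlestab.synthetic_data import gen_saxs

SPHERE_R = 3.0
SPHERE_RG = SPHERE_R * np.sqrt(3.0 / 5.0)  # 2.32379 nm


def _gaussian_profile(i0=5.0, rg=2.0, qmax=0.6, n=50, c=1.0):
    q = np.linspace(0.01, qmax, n)
    i = i0 * np.exp(-(q * rg) ** 2 / 3.0)
    return SAXSProfile(q, i, 0.01 * i, concentration=c)


def _sphere_profile():
    return form_factor("sphere", {"radius": SPHERE_R},
                       np.linspace(0.05, 5.0, 200), i0=1.0)


# --- q conversion ---------------------------------------------------------

def test_scattering_vector_zero_angle():
    assert scattering_vector(0.0, 1.542) == 0.0


def test_scattering_vector_cu_kalpha():
    # q = (4π/λ)·sin(θ/2); 2° total angle, Cu Kα 1.542 Å = 0.1542 nm
    expected = 4 * np.pi / 0.1542 * np.sin(np.deg2rad(1.0))
    assert scattering_vector(2.0, 1.542) == pytest.approx(expected, rel=1e-12)
    # halving the wavelength doubles q
    assert scattering_vector(2.0, 0.771) == pytest.approx(2 * expected,
                                                          rel=1e-12)


def test_scattering_vector_validation():
    with pytest.raises(ValueError):
        scattering_vector(2.0, 0.0)


# --- Guinier --------------------------------------------------------------

def test_guinier_exact_on_ideal_profile():
    res = guinier_fit(_gaussian_profile())
    assert res.rg == pytest.approx(2.0, rel=1e-10)
    assert res.i0 == pytest.approx(5.0, rel=1e-10)
    assert res.fit_r2 == pytest.approx(1.0, abs=1e-10)


def test_guinier_i0_over_c():
    res = guinier_fit(_gaussian_profile(c=4.0))
    assert res.i0_over_c == pytest.approx(res.i0 / 4.0, rel=1e-12)


def test_guinier_sphere_noiseless():
    res = guinier_fit(_sphere_profile())
    assert res.rg == pytest.approx(SPHERE_RG, rel=0.01)
    assert res.i0 == pytest.approx(1.0, rel=0.01)
    assert res.qrg_max <= 1.3 + 1e-9


def test_guinier_sphere_noisy():
    prof = gen_saxs("sphere", {"radius": SPHERE_R}, seed=49)
    res = guinier_fit(prof)
    assert res.rg == pytest.approx(SPHERE_RG, rel=0.02)


def test_guinier_scale_equivariance():
    p1 = _sphere_profile()
    k = 37.5
    p2 = SAXSProfile(p1.q, k * p1.intensity, k * p1.sigma)
    r1, r2 = guinier_fit(p1), guinier_fit(p2)
    # exact in exact arithmetic; floating point leaves ~1e-14
    assert r2.rg == pytest.approx(r1.rg, rel=1e-10)
    assert r2.i0 == pytest.approx(k * r1.i0, rel=1e-10)
    assert r2.n_points == r1.n_points


def test_guinier_upturn_raises():
    q = np.linspace(0.01, 0.5, 40)
    i = np.exp((q * 2.0) ** 2)  # aggregation-like low-q upturn
    with pytest.raises(NoGuinierRegimeError):
        guinier_fit(SAXSProfile(q, i, 0.01 * i))


def test_guinier_too_few_points():
    q = np.linspace(0.01, 0.2, 6)
    i = np.exp(-(q * 2.0) ** 2 / 3.0)
    with pytest.raises(NoGuinierRegimeError):
        guinier_fit(SAXSProfile(q, i, 0.01 * i))


# --- Mw calibration -------------------------------------------------------

def test_mw_identity_is_reference():
    assert mw_from_forward_scattering(0.02657, 0.02657) == 44.3


def test_mw_proportionality_and_rounding():
    assert mw_from_forward_scattering(0.015, 0.02657) == pytest.approx(
        round(0.015 / 0.02657 * 44.3, 1))


def test_mw_validation():
    with pytest.raises(ValueError):
        mw_from_forward_scattering(-1.0, 0.02657)
    with pytest.raises(ValueError):
        mw_from_forward_scattering(0.01, 0.0)


# --- form factors ---------------------------------------------------------

def test_sphere_forward_limit():
    assert sphere_form_factor(np.array([1e-12]), 3.0, i0=7.0)[0] == \
        pytest.approx(7.0, rel=1e-9)


def test_sphere_first_minimum():
    # first zero of 3(sin x − x cos x)/x³ is at x = qR = 4.4934
    q = np.linspace(0.5, 2.5, 20001)
    i = sphere_form_factor(q, SPHERE_R)
    band = (q * SPHERE_R > 3.0) & (q * SPHERE_R < 6.0)
    qmin = q[band][np.argmin(i[band])]
    assert qmin * SPHERE_R == pytest.approx(4.4934, abs=0.01)


def test_cylinder_rod_limit_cross_section():
    """ln(qI) vs q² slope gives the cross-section Rg = R/√2 in the rod
    limit; the finite-length bias decays as the rod grows."""
    target = 1.0 / np.sqrt(2.0)
    q = np.linspace(0.3, 0.8, 30)
    errs = []
    for length in (40.0, 60.0, 80.0, 120.0):
        i = cylinder_form_factor(q, 1.0, length)
        slope = np.polyfit(q ** 2, np.log(q * i), 1)[0]
        rc = np.sqrt(-2.0 * slope)
        errs.append(abs(rc - target) / target)
    assert all(b < a for a, b in zip(errs, errs[1:]))
    assert errs[-1] < 0.05


def test_form_factor_unknown_shape():
    with pytest.raises(ValueError):
        form_factor("torus", {}, np.linspace(0.1, 1.0, 10))


def test_sphere_pr_support_and_shape():
    r = np.linspace(0.0, 8.0, 400)
    p = sphere_pr(r, SPHERE_R)
    assert np.all(p[r > 2 * SPHERE_R] == 0.0)
    assert np.all(p >= 0.0)
    # analytic mode of the sphere p(r) lies near r ≈ 1.05 R
    assert r[np.argmax(p)] == pytest.approx(1.05 * SPHERE_R, abs=0.1)


# --- indirect Fourier transform -------------------------------------------

@pytest.fixture(scope="module")
def sphere_ift():
    return ift_pr(_sphere_profile(), dmax=6.0)


def test_ift_recovers_sphere_pr(sphere_ift):
    res = sphere_ift
    ref = sphere_pr(res.r_grid, SPHERE_R)
    scale = res.p_values.max() / ref.max()
    assert np.max(np.abs(res.p_values - scale * ref)) < 0.03 * res.p_values.max()
    assert res.negativity < 0.01


def test_ift_rg_and_i0_consistency(sphere_ift):
    res = sphere_ift
    assert res.rg_pr == pytest.approx(SPHERE_RG, rel=0.01)
    g = guinier_fit(_sphere_profile())
    assert res.i0_pr == pytest.approx(g.i0, rel=0.02)
    assert res.chi2_reduced < 2.0


def test_ift_endpoints_pinned(sphere_ift):
    assert sphere_ift.p_values[0] == 0.0
    assert sphere_ift.p_values[-1] == 0.0
    assert sphere_ift.r_grid[0] == 0.0
    assert sphere_ift.r_grid[-1] == 6.0


def test_ift_undersized_dmax_bad_fit():
    res = ift_pr(_sphere_profile(), dmax=4.0)
    assert res.chi2_reduced > 2.0


def test_ift_validation():
    prof = _sphere_profile()
    with pytest.raises(ValueError):
        ift_pr(prof, dmax=-1.0)
    with pytest.raises(ValueError):
        ift_pr(prof, dmax=6.0, n_r=10)


def test_dmax_scan_sphere():
    best, diags = dmax_scan(_sphere_profile(), np.arange(4.0, 8.01, 0.3))
    assert 5.7 <= best <= 6.6
    assert len(diags) == len(np.arange(4.0, 8.01, 0.3))
    assert all(set(d) >= {"dmax", "chi2_reduced", "score"} for d in diags)


def test_dmax_scan_single_grid_point():
    best, diags = dmax_scan(_sphere_profile(), [6.0])
    assert best == 6.0 and len(diags) == 1


def test_dmax_scan_rod_exceeds_equal_rg_sphere():
    # cylinder R=1, L=√58.8 has the same Rg as the R=3 sphere but is longer
    length = np.sqrt(58.8)
    rod = form_factor("cylinder", {"radius": 1.0, "length": length},
                      np.linspace(0.05, 5.0, 200))
    grid = np.arange(4.0, 10.01, 0.3)
    best_rod, _ = dmax_scan(rod, grid)
    best_sph, _ = dmax_scan(_sphere_profile(), grid)
    assert best_rod > best_sph


def test_dmax_scan_length_monotonic_low_noise():
    """At low noise the estimated Dmax tracks the true rod length.

    This ordering is only robust at ~1e-4 relative noise; at percent-level
    noise the chi-square keeps rewarding oversized dmax (documented
    limitation for elongated particles)."""
    grid = np.arange(5.0, 26.01, 1.0)
    best = []
    for length in (6.0, 12.0, 20.0):
        prof = gen_saxs("cylinder", {"radius": 1.5, "length": length},
                        noise_model=(1e-4, 1e-9), seed=5)
        best.append(dmax_scan(prof, grid)[0])
    assert best[0] < best[1] < best[2]


def test_dmax_scan_validation():
    with pytest.raises(ValueError):
        dmax_scan(_sphere_profile(), [])
    with pytest.raises(ValueError):
        dmax_scan(_sphere_profile(), [-1.0, 5.0])


# --- ASCII I/O ------------------------------------------------------------

def test_dat_round_trip(tmp_path):
    prof = gen_saxs("sphere", {"radius": SPHERE_R}, seed=2,
                    concentration=2.5, label="demo")
    p = tmp_path / "x.dat"
    write_dat(prof, p)
    back = read_dat(p, concentration=2.5, label="demo")
    np.testing.assert_allclose(back.q, prof.q, rtol=1e-6)
    np.testing.assert_allclose(back.intensity, prof.intensity, rtol=1e-6)
    assert back.concentration == 2.5


def test_read_dat_angstrom_units(tmp_path):
    p = tmp_path / "ang.dat"
    p.write_text("# comment\n0.01 1.0 0.01\n0.02 0.9 0.01\n0.03 0.8 0.01\n")
    prof = read_dat(p, q_unit="ang")
    np.testing.assert_allclose(prof.q, [0.1, 0.2, 0.3])


def test_write_pr_header(tmp_path, sphere_ift):
    p = tmp_path / "pr.txt"
    write_pr(sphere_ift, p)
    text = p.read_text()
    assert "# dmax_nm 6.0000" in text
    assert "# r(nm)  p(r)" in text


def test_profile_validation():
    with pytest.raises(ValueError):
        SAXSProfile(np.array([0.2, 0.1]), np.ones(2), np.ones(2))
    with pytest.raises(ValueError):
        SAXSProfile(np.array([0.1, 0.2]), np.ones(2), np.zeros(2))
    with pytest.raises(ValueError):
        SAXSProfile(np.array([0.1, 0.2]), np.ones(3), np.ones(2))
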