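"""Forward-model tests: boundary condition, semi-infinite closed forms,
Bessel basis, and the layered cylinder series against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, special

from layerflow import models as M

from conftest import FD_DISTANCES


# ---------------------------------------------------------------------------
# boundary condition
# ---------------------------------------------------------------------------


def test_effective_reflection_values():
    # polynomial evaluated by hand at the two anchor indices
    assert M.effective_reflection(1.0) == pytest.approx(0.0016, abs=1e-4)
    assert M.effective_reflection(1.4) == pytest.approx(0.5295, abs=1e-3)
    with pytest.raises(ValueError):
        M.effective_reflection(0.9)


@given(st.floats(1.0, 1.9))
def test_effective_reflection_monotone(n):
    assert M.effective_reflection(n + 0.1) > M.effective_reflection(n)


def test_extrapolation_length():
    assert M.extrapolation_length(0.1, 10.0, 1.4) == pytest.approx(0.2146, abs=2e-3)
    # formula reduction: stripping the boundary factor leaves (2/3)/mu_t'
    zb = M.extrapolation_length(0.1, 10.0, 1.4)
    reff = M.effective_reflection(1.4)
    assert zb * (1 - reff) / (1 + reff) == pytest.approx((2 / 3) / 10.1, rel=1e-12)
    # more scattering -> shorter extrapolation length
    assert M.extrapolation_length(0.1, 12.0, 1.4) < zb
    with pytest.raises(ValueError):
        M.extrapolation_length(-0.1, 10.0, 1.4)


# ---------------------------------------------------------------------------
# semi-infinite closed forms
# ---------------------------------------------------------------------------


def test_si_wavenumbers(si_medium):
    k_cw = M._si_k(si_medium, omega=0.0)
    assert k_cw == pytest.approx(math.sqrt(3 * 0.1 * 10.1), rel=1e-12)
    k_fd = M._si_k(si_medium, omega=2 * math.pi * 110e6)
    assert k_fd.real == pytest.approx(1.763, abs=2e-3)
    assert k_fd.imag == pytest.approx(0.277, abs=1e-3)


def test_si_green_fd(si_medium, fd_source):
    phi2 = M.si_green_fd(si_medium, fd_source, 2.0)
    phi3 = M.si_green_fd(si_medium, fd_source, 3.0)
    assert abs(phi3) < abs(phi2)
    cw = M.si_green_fd(si_medium, M.SourceSpec("DCS", wavelength=785e-7), 2.0)
    assert cw.imag == 0 and cw.real > 0
    with pytest.raises(ValueError):
        M.si_green_fd(si_medium, fd_source, 0.0)


def test_si_g1(si_medium, dcs_source):
    taus = np.array([0.0, 1e-6, 1e-5, 1e-4])
    g1 = M.si_g1(si_medium, dcs_source, 2.5, taus)
    assert g1[0] == pytest.approx(1.0, rel=1e-12)
    assert np.all(np.diff(g1) < 0)
    # frozen value at the reference operating point (depends on the
    # adopted Reff polynomial; computed with this implementation's zb)
    assert g1[2] == pytest.approx(0.80, abs=0.01)
    # static medium: no decay
    static = M.SemiInfiniteMedium(M.TissueLayer(0.1, 10.0, 0.0))
    assert np.allclose(M.si_g1(static, dcs_source, 2.5, taus), 1.0)
    # faster dynamics decay faster
    fast = M.SemiInfiniteMedium(M.TissueLayer(0.1, 10.0, 2e-8))
    assert np.all(M.si_g1(fast, dcs_source, 2.5, taus)[1:] < g1[1:])


# ---------------------------------------------------------------------------
# Bessel basis
# ---------------------------------------------------------------------------


def test_bessel_basis_roots():
    basis = M.bessel_basis(30.2, (0.8, 2.5), 500)
    assert basis.n_roots == 500
    assert basis.roots[0] == pytest.approx(2.404826 / 30.2, rel=1e-6)
    assert np.all(np.diff(basis.roots) > 0)
    # McMahon asymptotics: spacing tends to pi/a'
    spacing = np.diff(basis.roots)[-50:]
    assert np.allclose(spacing, math.pi / 30.2, rtol=1e-4)
    # the cached J0 factors really vanish at the rim
    assert np.max(np.abs(special.j0(30.2 * basis.roots))) < 1e-10


def test_bessel_basis_validation_and_cache():
    with pytest.raises(ValueError):
        M.bessel_basis(2.0, (2.5,), 10)  # distance beyond the rim
    b1 = M.bessel_basis(30.2, (0.8,), 200)
    b2 = M.bessel_basis(30.2, (0.8,), 200)
    assert b1 is b2  # cached and reused


def test_layer_wavenumber(homog_layer):
    k_cw = M.layer_wavenumber(homog_layer, 0.0, mode="FD", omega=0.0)
    assert k_cw == pytest.approx(math.sqrt(3 * 0.1 * 10.1), rel=1e-12)
    k_dcs0 = M.layer_wavenumber(homog_layer, 0.0, mode="DCS", tau=0.0, k0=2 * math.pi / 785e-7)
    assert k_dcs0 == pytest.approx(k_cw, rel=1e-12)
    k_dcs1 = M.layer_wavenumber(homog_layer, 0.0, mode="DCS", tau=1e-5, k0=2 * math.pi / 785e-7)
    assert k_dcs1 > k_dcs0


# ---------------------------------------------------------------------------
# layered cylinder vs oracles
# ---------------------------------------------------------------------------


def test_homogeneous_limit_fd(homog_medium, si_medium, fd_source):
    """With identical layers the cylinder series must collapse onto the
    semi-infinite Fick's-law reflectance (amplitude 1%, phase 0.1 deg)."""
    ac, th = M.fd_amp_phase_2L(homog_medium, fd_source, FD_DISTANCES)
    r_si = M.si_reflectance_fd(si_medium, fd_source, FD_DISTANCES)
    assert np.max(np.abs(np.abs(r_si) / ac - 1)) < 0.01
    assert np.max(np.abs(np.degrees(np.unwrap(-np.angle(r_si)) - th))) < 0.1


def test_homogeneous_limit_g1(homog_medium, si_medium, dcs_source, tau_grid):
    for rho in (0.8, 2.5):
        g_2l = M.g1_2L(homog_medium, dcs_source, rho, tau_grid.taus)
        g_si = M.si_g1(si_medium, dcs_source, rho, tau_grid.taus)
        mask = g_si > 1e-3
        assert np.max(np.abs(g_2l[mask] / g_si[mask] - 1)) < 0.01


def _slab_kernel(s, l1, l2, ell, n, omega):
    """Bessel/Hankel-domain surface reflectance of a laterally infinite
    two-layer slab, derived independently from the Kienle-form layered
    fluence (cosh/sinh interface combination), exponent-scaled."""
    v = M.C_LIGHT_CM_S / n
    D1 = v / (3 * (l1.mu_a + l1.mu_s_prime))
    D2 = v / (3 * (l2.mu_a + l2.mu_s_prime))
    z0 = 1.0 / (l1.mu_a + l1.mu_s_prime)
    zb = M.extrapolation_length(l1.mu_a, l1.mu_s_prime, n)
    a1 = np.sqrt(v * l1.mu_a / D1 + s**2 + 1j * omega / D1)
    a2 = np.sqrt(v * l2.mu_a / D2 + s**2 + 1j * omega / D2)
    L = np.exp(-2 * a1 * ell)
    E = np.exp(-2 * a1 * (ell + zb))
    B = D1 * a1 * (1 - L) + D2 * a2 * (1 + L)
    A = D1 * a1 * (1 + E) + D2 * a2 * (1 - E)
    return 0.5 * v * (
        np.exp(-a1 * z0)
        + np.exp(-a1 * (z0 + 2 * zb)) * B / A
        + np.exp(a1 * z0) * (D1 * a1 - D2 * a2) * (E + L) / A
    )


def _slab_reflectance(rho, l1, l2, ell, n, omega):
    z0 = 1.0 / (l1.mu_a + l1.mu_s_prime)
    s_max = 35.0 / z0

    def integrand(s, part):
        val = _slab_kernel(s, l1, l2, ell, n, omega) * special.j0(s * rho) * s
        return val.real if part == "re" else val.imag

    re, _ = integrate.quad(integrand, 0, s_max, args=("re",), limit=800)
    im, _ = integrate.quad(integrand, 0, s_max, args=("im",), limit=800)
    return (re + 1j * im) / (2 * math.pi)


def test_slab_oracle(fd_source):
    """The a = 30 cm cylinder solution agrees within 1% with the laterally
    infinite two-layer slab computed by numerical inverse Hankel transform
    from an independently derived kernel."""
    rng = np.random.default_rng(20230523)
    omega = fd_source.omega
    for _ in range(6):
        mua1, mua2 = rng.uniform(0.08, 0.18, 2)
        mus1 = rng.uniform(6, 15)
        mus2 = mus1 * rng.uniform(0.8, 1.2)
        ell = rng.choice([1.0, 1.2, 1.4, 1.6])
        l1, l2 = M.TissueLayer(mua1, mus1), M.TissueLayer(mua2, mus2)
        med = M.TwoLayerMedium(l1, l2, thickness=ell, radius=30.0)
        for rho in (1.2, 2.5):
            r_cyl = M.reflectance_2L(med, fd_source, rho)
            r_slab = _slab_reflectance(rho, l1, l2, ell, 1.4, omega)
            assert abs(r_cyl - r_slab) / abs(r_slab) < 0.01


def test_kernel_z_derivative_oracle():
    """The analytic surface derivative entering the series matches a
    finite-difference derivative of the layered Green's function written
    in its plain (unscaled) textbook form."""
    l1, l2 = M.TissueLayer(0.10, 9.0), M.TissueLayer(0.15, 11.0)
    med = M.TwoLayerMedium(l1, l2, thickness=1.2, radius=30.0)
    n = med.refractive_index
    v = M.C_LIGHT_CM_S / n
    D1 = v / (3 * (l1.mu_a + l1.mu_s_prime))
    D2 = v / (3 * (l2.mu_a + l2.mu_s_prime))
    z0 = 1.0 / (l1.mu_a + l1.mu_s_prime)
    zb = M.extrapolation_length(l1.mu_a, l1.mu_s_prime, n)
    omega = 2 * math.pi * 110e6
    ell = med.thickness

    def g1_plain(s, z):
        a1 = np.sqrt(v * l1.mu_a / D1 + s**2 + 1j * omega / D1)
        a2 = np.sqrt(v * l2.mu_a / D2 + s**2 + 1j * omega / D2)
        den = D1 * a1 * np.cosh(a1 * (ell + zb)) + D2 * a2 * np.sinh(a1 * (ell + zb))
        first = (np.exp(-a1 * abs(z - z0)) - np.exp(-a1 * (z + z0 + 2 * zb))) / (2 * D1 * a1)
        second = (
            np.sinh(a1 * (z0 + zb)) * np.sinh(a1 * (z + zb))
            / (D1 * a1 * np.exp(a1 * (ell + zb)))
            * (D1 * a1 - D2 * a2) / den
        )
        return first + second

    h = 1e-5
    for s in (0.5, 5.0, 20.0, 60.0):
        numeric = v * D1 * (g1_plain(s, h) - g1_plain(s, 0.0)) / h
        a1 = np.sqrt(v * l1.mu_a / D1 + s**2 + 1j * omega / D1)
        a2 = np.sqrt(v * l2.mu_a / D2 + s**2 + 1j * omega / D2)
        analytic = v * M._kernel_2l(med, a1, a2, D1, D2, z0, zb)
        assert abs(numeric - analytic) / abs(analytic) < 1e-3


def test_series_truncation_stability(layered_medium, fd_source, dcs_source, tau_grid):
    """Doubling the root count beyond the default changes nothing at the
    1e-4 level: the adaptive rule has already converged the series."""
    n_def = M._basis_for(layered_medium, tuple(FD_DISTANCES), None).n_roots
    ac1, th1 = M.fd_amp_phase_2L(layered_medium, fd_source, FD_DISTANCES, n_roots=n_def)
    ac2, th2 = M.fd_amp_phase_2L(layered_medium, fd_source, FD_DISTANCES,
                                 n_roots=min(2 * n_def, M.SERIES_MAX_ROOTS))
    assert np.max(np.abs(ac2 / ac1 - 1)) < 1e-4
    assert np.max(np.abs(th2 - th1)) < 1e-4
    g1a = M.g1_2L(layered_medium, dcs_source, 2.5, tau_grid.taus, n_roots=n_def)
    g1b = M.g1_2L(layered_medium, dcs_source, 2.5, tau_grid.taus,
                  n_roots=min(2 * n_def, M.SERIES_MAX_ROOTS))
    assert np.max(np.abs(g1b - g1a)) < 1e-4


def test_radius_robustness(fd_source):
    """Results are border-independent: growing the cylinder radius from 30
    to 60 cm moves amplitude and phase by < 0.1%."""
    l1, l2 = M.TissueLayer(0.10, 10.0), M.TissueLayer(0.15, 11.0)
    m30 = M.TwoLayerMedium(l1, l2, 1.2, 30.0)
    m60 = M.TwoLayerMedium(l1, l2, 1.2, 60.0)
    ac30, th30 = M.fd_amp_phase_2L(m30, fd_source, FD_DISTANCES)
    ac60, th60 = M.fd_amp_phase_2L(m60, fd_source, FD_DISTANCES)
    assert np.max(np.abs(ac60 / ac30 - 1)) < 1e-3
    assert np.max(np.abs(th60 - th30) / np.abs(th30)) < 1e-3


def test_fd_amp_phase_properties(layered_medium, fd_source):
    ac, th = M.fd_amp_phase_2L(layered_medium, fd_source, FD_DISTANCES)
    assert np.all(ac > 0)
    assert np.all(np.diff(ac) < 0)          # diffusive attenuation
    assert th[-1] > th[0]                   # phase accumulates with pathlength
    # CW limit: real reflectance, zero phase
    cw = M.reflectance_2L(layered_medium, M.SourceSpec("DCS", wavelength=785e-7),
                          FD_DISTANCES, tau=0.0)
    assert np.allclose(cw.imag if np.iscomplexobj(cw) else 0.0, 0.0)


def test_g1_2L_properties(layered_medium, dcs_source, tau_grid):
    taus = tau_grid.taus
    g1 = M.g1_2L(layered_medium, dcs_source, 2.5, taus)
    assert np.all(np.diff(g1) < 0)
    assert 0.9 < g1[0] < 1.0
    # tau = 0 normalizes exactly through the same code path
    g1z = M.g1_2L(layered_medium, dcs_source, 2.5, np.array([0.0, 1e-6]))
    assert g1z[0] == 1.0
    # static layers: no decay at all
    static = M.TwoLayerMedium(
        M.TissueLayer(0.10, 10.0, 0.0), M.TissueLayer(0.15, 10.0, 0.0), 1.2, 30.0
    )
    assert np.allclose(M.g1_2L(static, dcs_source, 2.5, taus), 1.0)


def test_depth_sensitivity_of_flow(dcs_source, tau_grid):
    """Raising the deep flow lowers g1 fractionally more at the long
    separation than at the short one."""
    taus = tau_grid.taus[:60]
    base = M.TwoLayerMedium(
        M.TissueLayer(0.1, 10.0, 1e-8), M.TissueLayer(0.13, 10.0, 2e-8), 1.2, 30.0
    )
    fast = M.TwoLayerMedium(
        M.TissueLayer(0.1, 10.0, 1e-8), M.TissueLayer(0.13, 10.0, 8e-8), 1.2, 30.0
    )
    drop = {}
    for rho in (0.8, 2.5):
        g_b = M.g1_2L(base, dcs_source, rho, taus)
        g_f = M.g1_2L(fast, dcs_source, rho, taus)
        mid = np.argmin(np.abs(g_b - 0.5))
        drop[rho] = (g_b[mid] - g_f[mid]) / g_b[mid]
    assert drop[2.5] > drop[0.8]


def test_siegert():
    assert M.siegert(1.0, 0.5) == pytest.approx(1.5)
    assert M.siegert(0.5, 0.5) == pytest.approx(1.125)
    assert np.allclose(M.siegert(np.array([0.2, 0.9]), 0.0), 1.0)
    with pytest.raises(ValueError):
        M.siegert(1.0, 1.2)


def test_radius_warning(fd_source):
    small = M.TwoLayerMedium(
        M.TissueLayer(0.1, 10.0), M.TissueLayer(0.1, 10.0), 1.2, 6.0
    )
    with pytest.warns(UserWarning, match="radius"):
        M.fd_amp_phase_2L(small, fd_source, [0.8, 2.0, 4.0])


def test_series_convergence_error(layered_medium, fd_source):
    with pytest.raises(M.SeriesConvergenceError):
        M.fd_amp_phase_2L(layered_medium, fd_source, FD_DISTANCES, n_roots=60)
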