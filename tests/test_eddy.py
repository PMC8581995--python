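"""Spherical-harmonic eddy phase model, parity handling and unwrapping."""

import numpy as np
import pytest

from dippi.acquisition import fibonacci_directions
from dippi.eddy import (
    EddyCoefficients,
    SHBasis,
    eddy_phase,
    fit_eddy,
    tphase0_correction,
    unwrap_on_sphere,
)

DIRS = fibonacci_directions(60)


def test_basis_parity():
    """Y_lm(-g) = (-1)^l Y_lm(g) for every basis member."""
    basis = SHBasis(3)
    Y = basis.design_matrix(DIRS)
    Ym = basis.design_matrix(-DIRS)
    parity = (-1.0) ** basis.l_values
    assert np.abs(Ym - Y * parity).max() < 1e-12


def test_eddy_phase_parity_and_zero():
    basis = SHBasis(2)
    zero = EddyCoefficients.zeros(basis, [30.0])
    assert eddy_phase(zero, DIRS[0], 30.0) == 0.0
    c = np.zeros(basis.n_coeff)
    c[1:4] = [0.3, -0.2, 0.5]  # l = 1 only
    odd = EddyCoefficients(basis, [30.0], c[None])
    assert eddy_phase(odd, DIRS, 30.0) == pytest.approx(
        -eddy_phase(odd, -DIRS, 30.0))
    c2 = np.zeros(basis.n_coeff)
    c2[4:] = np.arange(5) / 10 + 0.1  # l = 2 only
    even = EddyCoefficients(basis, [30.0], c2[None])
    assert eddy_phase(even, DIRS, 30.0) == pytest.approx(
        eddy_phase(even, -DIRS, 30.0))


def test_eddy_phase_grid_lookup():
    basis = SHBasis(1)
    coeffs = EddyCoefficients(basis, [0.0, 30.0],
                              np.array([[0.0] * 4, [1.0, 0.5, 0.2, 0.1]]))
    with pytest.raises(ValueError):
        eddy_phase(coeffs, DIRS[0], 15.0)
    mid = eddy_phase(coeffs, DIRS[:5], 15.0, interpolate=True)
    ends = 0.5 * (eddy_phase(coeffs, DIRS[:5], 0.0)
                  + eddy_phase(coeffs, DIRS[:5], 30.0))
    assert mid == pytest.approx(ends)


class TestFitEddy:
    def test_l1_recovery(self):
        basis = SHBasis(3)
        c = np.zeros(basis.n_coeff)
        c[1:4] = [0.8, -0.4, 1.2]
        phases = basis.design_matrix(DIRS) @ c
        coeffs, resid = fit_eddy(phases, DIRS, basis, parity="odd_only")
        assert np.abs(coeffs.c[0] - c).max() < 1e-10
        assert np.abs(resid).max() < 1e-10

    def test_even_input_fitted_odd_only(self):
        """On an antipodal direction set (gradients plus reverses) the odd
        basis is exactly orthogonal to any even field: zero coefficients,
        all power left in the residual."""
        dirs2 = np.vstack([DIRS, -DIRS])
        basis = SHBasis(2)
        c = np.zeros(basis.n_coeff)
        c[4:] = 0.5
        phases = basis.design_matrix(dirs2) @ c
        coeffs, resid = fit_eddy(phases, dirs2, basis, parity="odd_only")
        assert np.abs(coeffs.c[0]).max() < 1e-10
        assert np.sum(resid**2) == pytest.approx(np.sum(phases**2), rel=1e-9)

    def test_power_partition(self):
        """With parity='all' the per-order powers account for the fitted
        signal power (orthonormal basis, least squares)."""
        rng = np.random.default_rng(5)
        basis = SHBasis(3)
        phases = rng.normal(size=len(DIRS))
        coeffs, resid = fit_eddy(phases, DIRS, basis, parity="all")
        fitted = basis.design_matrix(DIRS) @ coeffs.c[0]
        assert np.sum(fitted**2) + np.sum(resid**2) == pytest.approx(
            np.sum(phases**2), rel=1e-9)
        assert sum(coeffs.per_l_power().values()) == pytest.approx(
            np.sum(coeffs.c[0] ** 2))

    def test_too_few_directions(self):
        with pytest.raises(ValueError):
            fit_eddy(np.zeros(3), DIRS[:3], SHBasis(3), parity="all")


class TestUnwrap:
    def test_smooth_field_unchanged(self):
        smooth = 0.5 * DIRS[:, 2]
        assert np.allclose(unwrap_on_sphere(smooth, DIRS), smooth)

    def test_hemisphere_offset_removed(self):
        smooth = 0.4 * DIRS[:, 0]
        wrapped = smooth + 2 * np.pi * (DIRS[:, 2] > 0)
        out = unwrap_on_sphere(wrapped, DIRS, reference=int(
            np.argmin(DIRS[:, 2])))
        assert np.allclose(out - out[0], smooth - smooth[0], atol=1e-9)
        # congruence mod 2 pi with the input is preserved per direction
        assert np.allclose(np.angle(np.exp(1j * (out - wrapped))), 0,
                           atol=1e-12)

    def test_constant_near_pi_unchanged(self):
        const = np.full(len(DIRS), np.pi - 1e-3)
        assert np.allclose(unwrap_on_sphere(const, DIRS), const)


def test_parity_split_exact_on_antipodal_pairs():
    """For a scheme with reversed gradients, (phi(g) - phi(-g))/2 isolates
    the odd part exactly and the odd+even split reconstructs the field."""
    basis = SHBasis(3)
    rng = np.random.default_rng(6)
    c = rng.normal(size=basis.n_coeff)
    dirs2 = np.vstack([DIRS, -DIRS])
    phi = basis.design_matrix(dirs2) @ c
    n = len(DIRS)
    odd_part = 0.5 * (phi[:n] - phi[n:])
    even_part = 0.5 * (phi[:n] + phi[n:])
    Y = basis.design_matrix(DIRS)
    assert np.allclose(odd_part, Y[:, basis.odd_mask] @ c[basis.odd_mask],
                       atol=1e-12)
    assert np.allclose(odd_part + even_part, phi[:n], atol=1e-12)


class TestTphase0Correction:
    def test_zero_calibration_is_identity(self):
        basis = SHBasis(2)
        rng = np.random.default_rng(7)
        target = EddyCoefficients(basis, [30.0],
                                  rng.normal(size=(1, basis.n_coeff)))
        zero = EddyCoefficients.zeros(basis, [0.0])
        out = tphase0_correction(zero, target)
        assert np.allclose(out.c[:, basis.odd_mask],
                           target.c[:, basis.odd_mask])
        assert np.allclose(out.c[:, basis.even_mask], 0.0)

    def test_even_replaced_odd_untouched(self):
        basis = SHBasis(2)
        rng = np.random.default_rng(8)
        cal = EddyCoefficients(basis, [0.0],
                               rng.normal(size=(1, basis.n_coeff)))
        target = EddyCoefficients(basis, [30.0],
                                  rng.normal(size=(1, basis.n_coeff)))
        out = tphase0_correction(cal, target)
        assert np.allclose(out.c[0, basis.even_mask],
                           cal.c[0, basis.even_mask])
        assert np.allclose(out.c[0, basis.odd_mask],
                           target.c[0, basis.odd_mask])

    def test_forward_simulated_static_even_field(self):
        """A static even eddy field measured at t_phase = 0 is removed
        from the 30 ms shell, leaving only the odd part."""
        basis = SHBasis(2)
        c_static = np.zeros(basis.n_coeff)
        c_static[4:] = [0.2, -0.1, 0.4, 0.05, -0.3]
        c_odd = np.zeros(basis.n_coeff)
        c_odd[1:4] = [0.6, -0.2, 0.1]
        dirs2 = np.vstack([DIRS, -DIRS])  # antipodal, parity-orthogonal
        phases_t0 = basis.design_matrix(dirs2) @ c_static
        phases_t30 = basis.design_matrix(dirs2) @ (c_static + c_odd)
        cal, _ = fit_eddy(phases_t0, dirs2, basis, parity="all", t_phase=0.0)
        fit30, _ = fit_eddy(phases_t30, dirs2, basis, parity="odd_only",
                            t_phase=30.0)
        corrected = tphase0_correction(cal, fit30)
        model = basis.design_matrix(dirs2) @ corrected.c[0]
        assert np.allclose(model, phases_t30, atol=1e-9)

    def test_basis_mismatch(self):
        with pytest.raises(ValueError):
            tphase0_correction(EddyCoefficients.zeros(SHBasis(1), [0.0]),
                               EddyCoefficients.zeros(SHBasis(3), [30.0]))
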