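"""Staged voxel-model estimation: magnitude fit, phase stages, myelin
parameters."""

import numpy as np
import pytest

from dippi.acquisition import Scheme
from dippi.fitting import (
    estimate_phiSE,
    fit_magnitude,
    fit_phase_single_tphase,
    fit_voxel,
    interreadout_phase,
    myelin_freq_difference,
)
from dippi.signal import simulate_dataset


class TestMagnitudeFit:
    def test_single_population_exact(self, consts7t):
        from dippi.signal import FiberPopulation, VoxelModel
        n = np.array([0.0, 0.6, 0.8])
        voxel = VoxelModel([FiberPopulation(n, 1.3, 1.1)], omega_bulk=0.0,
                           consts=consts7t)
        scheme = Scheme.dippi_shell(20, b=2.0, t_phases=(20.0,))
        d = simulate_dataset(voxel, scheme, snr=None, seed=1)
        fit = fit_magnitude(np.abs(d.S_SE), np.abs(d.S_ASE), scheme, K=1,
                            seed=2)
        assert abs(fit.n_hat[0] @ n) > 1 - 1e-9
        assert fit.A_SE[0] == pytest.approx(1.3, rel=1e-7)
        assert fit.Delta_D[0] == pytest.approx(1.1, rel=1e-6)
        assert fit.residual < 1e-7

    def test_right_angle_crossing_recovered(self, xy_crossing_voxel):
        """Noise-free 90-degree crossing: both orientations within 1
        degree and widths/amplitudes exact."""
        scheme = Scheme.dippi_shell(30, b=3.0, t_phases=(20.0,))
        d = simulate_dataset(xy_crossing_voxel, scheme, snr=None, seed=3)
        fit = fit_magnitude(np.abs(d.S_SE), np.abs(d.S_ASE), scheme, K=2,
                            seed=4)
        truth = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        dots = np.abs(truth @ fit.n_hat.T)
        assert dots.max(axis=1).min() > np.cos(np.deg2rad(1.0))
        assert np.allclose(fit.Delta_D, 1.7, rtol=1e-5)

    def test_b0_only_flags_widths(self, xy_crossing_voxel):
        scheme = Scheme(np.zeros(6), np.zeros((6, 3)), 20.0)
        d = simulate_dataset(xy_crossing_voxel, scheme, snr=None, seed=5)
        fit = fit_magnitude(np.abs(d.S_SE), np.abs(d.S_ASE), scheme, K=2)
        assert not fit.widths_identifiable
        assert np.sum(fit.A_SE) == pytest.approx(2.0, rel=1e-9)

    def test_too_few_directions_rejected(self, xy_crossing_voxel):
        scheme = Scheme.dippi_shell(2, b=3.0, t_phases=(20.0,),
                                    reverse=False)
        d = simulate_dataset(xy_crossing_voxel, scheme, snr=None, seed=6)
        with pytest.raises(ValueError):
            fit_magnitude(np.abs(d.S_SE), np.abs(d.S_ASE), scheme, K=2)


class TestPhaseHelpers:
    def test_phiSE_is_principal_angle(self):
        s = np.array([2.0, 1.5 * np.exp(1j * np.pi / 3)])
        assert estimate_phiSE(s) == pytest.approx([0.0, np.pi / 3])

    def test_interreadout_identities(self):
        rng = np.random.default_rng(0)
        s_se = rng.normal(size=5) + 1j * rng.normal(size=5)
        assert interreadout_phase(s_se, s_se) == pytest.approx(np.zeros(5))
        rot = s_se * np.exp(0.7j)
        assert interreadout_phase(s_se, rot) == pytest.approx(np.full(5, 0.7))
        # common phase on both readouts cancels
        common = np.exp(1.3j)
        assert interreadout_phase(s_se * common, rot * common) == \
            pytest.approx(np.full(5, 0.7))

    def test_phiSE_variance_shrinks_with_snr(self, xy_crossing_voxel,
                                             single_tphase_scheme):
        errs = []
        for snr in (10, 1000):
            d = simulate_dataset(xy_crossing_voxel, single_tphase_scheme,
                                 snr=snr, seed=11)
            err = np.angle(np.exp(1j * (estimate_phiSE(d.S_SE)
                                        - d.truth.phi_SE)))
            errs.append(np.std(err))
        assert errs[1] < errs[0] / 10

    def test_freq_difference_arithmetic(self):
        d = myelin_freq_difference([0.3, 0.0], 30.0)
        assert d[0, 1] == pytest.approx(10.0)
        assert d[1, 0] == pytest.approx(-10.0)
        # common offset cancels
        d2 = myelin_freq_difference([0.3 + 1.1, 0.0 + 1.1], 30.0)
        assert d2[0, 1] == pytest.approx(d[0, 1])


class TestPhaseStage:
    def test_noise_free_phi_susc_recovery(self, xy_crossing_voxel, consts7t):
        """Zero eddy, noise-free: per-population susceptibility phases
        recovered to < 1e-6 rad."""
        from dippi.eddy import EddyCoefficients, SHBasis
        from dippi.physics import omega_myelin
        from dippi.signal import MS
        scheme = Scheme.dippi_shell(30, b=3.0, t_phases=(20.0,))
        xy_crossing_voxel.eddy = EddyCoefficients.zeros(SHBasis(1), [20.0])
        d = simulate_dataset(xy_crossing_voxel, scheme, snr=None, seed=12)
        mf = fit_magnitude(np.abs(d.S_SE), np.abs(d.S_ASE), scheme, K=2,
                           seed=13)
        pf = fit_phase_single_tphase(d.S_SE, d.S_ASE, scheme, mf)
        wb = d.truth.omega_bulk[0]
        w_my = omega_myelin(1.0, np.log(0.7), consts7t)
        from dippi.physics import MyelinPool, twopool_complex
        pool = MyelinPool(0.5, np.log(0.7))
        expected = np.angle(twopool_complex(pool, w_my, 20 * MS)
                            * np.exp(1j * wb * 20 * MS))
        for phi in pf.phi_susc:
            assert np.angle(np.exp(1j * (phi - expected))) == \
                pytest.approx(0.0, abs=1e-6)

    def test_pure_eddy_no_susceptibility(self, xy_crossing_voxel):
        """l=1 eddy only: susceptibility phases ~0, coefficients found."""
        from dippi.eddy import EddyCoefficients, SHBasis
        basis = SHBasis(1)
        c = np.array([[0.0, 0.9, -0.5, 0.3]])
        scheme = Scheme.dippi_shell(30, b=3.0, t_phases=(20.0,))
        xy_crossing_voxel.eddy = EddyCoefficients(basis, [20.0], c)
        xy_crossing_voxel.omega_bulk = 0.0
        for p in xy_crossing_voxel.populations:
            object.__setattr__(p, "pool", type(p.pool)(0.0, 0.0))
        d = simulate_dataset(xy_crossing_voxel, scheme, snr=None, seed=14)
        mf = fit_magnitude(np.abs(d.S_SE), np.abs(d.S_ASE), scheme, K=2,
                           seed=15)
        pf = fit_phase_single_tphase(d.S_SE, d.S_ASE, scheme, mf)
        assert np.allclose(pf.phi_susc, 0.0, atol=1e-6)
        assert np.allclose(pf.eddy.c[0], c[0], atol=1e-6)


class TestFullFit:
    def test_noise_free_identifiable_parameters(self, xy_crossing_voxel):
        """Single orientation, noise-free: orientations, widths,
        amplitudes, per-volume SE phases and the myelin frequency
        difference are all recovered to < 1e-6 relative."""
        scheme = Scheme.dippi_shell(30, b=3.0, t_phases=(20.0,))
        d = simulate_dataset(xy_crossing_voxel, scheme, snr=None, seed=16)
        fit = fit_voxel(d.S_SE, d.S_ASE, scheme, K=2, mode="single_pool",
                        seed=17)
        truth_ns = np.array([[1.0, 0, 0], [0, 1.0, 0]])
        fitted_ns = np.array([p["n_hat"] for p in fit.populations])
        assert np.abs(truth_ns @ fitted_ns.T).max(axis=1).min() > 1 - 1e-9
        for p in fit.populations:
            assert p["A_SE"] == pytest.approx(1.0, rel=1e-6)
            assert p["Delta_D"] == pytest.approx(1.7, rel=1e-5)
        err = np.angle(np.exp(1j * (fit.phi_SE - d.truth.phi_SE)))
        assert np.abs(err).max() < 1e-6
        # both populations perpendicular and identical: difference 0
        dmat = fit.myelin_freq_difference_matrix(0)
        assert abs(dmat[0, 1]) < 1e-6

    def test_two_pool_multi_orientation_noise_free(self, xy_crossing_voxel):
        """Multiple head orientations and t_phases: the myelinated
        fraction and g-ratio are recovered exactly on noise-free data."""
        t_phases = (15.0, 30.0, 45.0, 60.0)
        s0 = Scheme.dippi_shell(15, b=3.0, t_phases=t_phases).with_B0(
            [0, 0, 1], 0)
        s1 = Scheme.dippi_shell(15, b=3.0, t_phases=t_phases).with_B0(
            [1, 0, 0], 1)
        scheme = Scheme.concatenate([s0, s1])
        d = simulate_dataset(xy_crossing_voxel, scheme, snr=None, seed=18)
        fit = fit_voxel(d.S_SE, d.S_ASE, scheme, K=2, mode="two_pool",
                        seed=19)
        for p in fit.populations:
            assert p["f_myelin"] == pytest.approx(0.5, abs=1e-4)
            assert np.exp(p["log_g_myelin"]) == pytest.approx(0.7, abs=1e-4)

    def test_fully_myelinated_ridge_flagged_product_recovered(
            self, xy_crossing_voxel):
        """f = 1 data leaves (f, log g) on a ridge, but the product
        f * log g (the average log g) is still recovered."""
        from dataclasses import replace
        from dippi.physics import MyelinPool
        pool = MyelinPool(1.0, np.log(0.85))
        xy_crossing_voxel.populations = [
            replace(p, pool=pool) for p in xy_crossing_voxel.populations]
        t_phases = (15.0, 30.0, 45.0, 60.0)
        s0 = Scheme.dippi_shell(15, b=3.0, t_phases=t_phases).with_B0(
            [0, 0, 1], 0)
        s1 = Scheme.dippi_shell(15, b=3.0, t_phases=t_phases).with_B0(
            [1, 0, 0], 1)
        scheme = Scheme.concatenate([s0, s1])
        d = simulate_dataset(xy_crossing_voxel, scheme, snr=None, seed=20)
        fit = fit_voxel(d.S_SE, d.S_ASE, scheme, K=2, mode="two_pool",
                        seed=21)
        for p in fit.populations:
            assert p["log_g_mean"] == pytest.approx(np.log(0.85), abs=2e-3)

    def test_mode_validation(self, xy_crossing_voxel, single_tphase_scheme):
        d = simulate_dataset(xy_crossing_voxel, single_tphase_scheme,
                             snr=None, seed=22)
        with pytest.raises(ValueError):
            fit_voxel(d.S_SE, d.S_ASE, single_tphase_scheme, mode="two_pool")
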