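"""Crossing-cylinder substrate, random walk and DIPPI phase accumulation.

These use deliberately small spin counts; the quantitative extra-axonal
contamination checks live in the acceptance suite.
"""

import numpy as np
import pytest

from dippi.montecarlo import (
    build_substrate,
    dippi_phase_accumulation,
    offresonance_at,
    random_walk,
    summarize_vs_b,
)
from dippi.physics import omega_myelin


class TestSubstrate:
    @pytest.mark.parametrize("diameter,extra", [(0.98, 0.246), (0.5, 0.804)])
    def test_stated_volume_fraction_range(self, diameter, extra):
        sub = build_substrate(outer_diameter=diameter)
        assert sub.extra_volume_fraction == pytest.approx(extra, abs=5e-3)

    def test_analytic_fraction(self):
        sub = build_substrate(outer_diameter=0.74, spacing=1.0)
        assert sub.extra_volume_fraction == pytest.approx(
            1 - np.pi * 0.37**2, rel=1e-12)

    def test_half_myelinated(self):
        sub = build_substrate()
        assert sub.myelinated.sum() == len(sub.axis) // 2
        # one myelinated cylinder per plane
        for plane in np.unique(sub.c2):
            assert sub.myelinated[sub.c2 == plane].sum() == 1

    def test_no_straight_extracellular_channels(self):
        """Staggered planes block straight z-paths: every (x, y) line
        along z intersects at least one cylinder for d >= 0.5 um."""
        sub = build_substrate(outer_diameter=0.6)
        xs = np.linspace(0, sub.cells[0], 81, endpoint=False)
        blocked = np.zeros((81, 81), bool)
        for j in range(len(sub.axis)):
            lo, hi = sub.c1[j] - sub.r_outer, sub.c1[j] + sub.r_outer
            for off in (-sub.cells[0], 0.0, sub.cells[0]):
                sel = (xs >= lo + off) & (xs <= hi + off)
                if sub.axis[j] == 0:  # x-cylinder blocks a y-interval
                    blocked[:, sel] = True
                else:
                    blocked[sel, :] = True
        assert blocked.all()

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            build_substrate(outer_diameter=1.2, spacing=1.0)


class TestField:
    def test_unmyelinated_interior_small(self, consts7t):
        """Inside the unmyelinated axon only distant dipoles contribute."""
        sub = build_substrate(outer_diameter=0.74)
        # unmyelinated x-cylinder centre: (y, z) = (1.5, 0.5)
        w = offresonance_at([0.3, 1.5, 0.5], sub, consts7t)
        lumen = omega_myelin(1.0, np.log(0.7), consts7t)
        assert abs(w) < 0.3 * abs(lumen)

    def test_myelinated_interior_near_lumen_value(self, consts7t):
        sub = build_substrate(outer_diameter=0.74)
        w = offresonance_at([0.3, 0.5, 0.5], sub, consts7t)
        lumen = omega_myelin(1.0, np.log(0.7), consts7t)
        assert w == pytest.approx(lumen, rel=0.35)  # neighbours shift it

    def test_intra_field_bimodal(self, consts7t):
        """Across the substrate the intra-axonal frequency distribution is
        bimodal: a peak near zero (unmyelinated) and one near the lumen
        value (myelinated)."""
        sub = build_substrate(outer_diameter=0.74)
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 2, (6000, 3))
        w = offresonance_at(pts, sub, consts7t)
        # classify by geometry
        lumen = omega_myelin(1.0, np.log(0.7), consts7t)
        near_zero = np.abs(w) < 0.3 * abs(lumen)
        near_lumen = np.abs(w - lumen) < 0.3 * abs(lumen)
        assert near_zero.sum() > 1000
        assert near_lumen.sum() > 400

    def test_walker_tables_match_reference_field(self, consts7t):
        from dippi.montecarlo import _field_tables
        sub = build_substrate(outer_diameter=0.74)
        Fx, Fy, h = _field_tables(sub, consts7t)
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 2, (300, 3))
        ref = offresonance_at(pts, sub, consts7t)
        # table value via nearest grid sample (away from surfaces)
        n = Fx.shape[0]
        ix = np.minimum((pts / h).astype(int), n - 1)
        approx = Fx[ix[:, 1], ix[:, 2]] + Fy[ix[:, 0], ix[:, 2]]
        # add lumen term where geometry says myelinated interior
        lum = ref - approx
        # agreement: either matches directly (extra/unmyelinated) or
        # differs by exactly the lumen value (myelinated interior)
        lumen = omega_myelin(1.0, np.log(0.7), consts7t)
        close = np.minimum(np.abs(lum), np.abs(lum - lumen))
        assert np.median(close) < 1.0  # rad/s, grid-resolution level


class TestRandomWalk:
    def test_free_diffusion_msd(self):
        tr = random_walk(None, 400, D=2.0, dt=1e-3, duration=15.0, seed=1)
        disp = tr.positions[:, -1, :] - tr.positions[:, 0, :]
        msd = np.mean(np.sum(disp**2, axis=1))
        expected = 6 * 2.0 * 15.0
        assert msd == pytest.approx(expected, rel=0.12)

    def test_confinement_and_impermeability(self):
        sub = build_substrate(outer_diameter=0.74)
        tr = random_walk(sub, 300, D=2.0, duration=8.0, seed=2)
        intra = tr.compartment > 0
        assert intra.any() and (~intra).any()
        # intra spins never move further than a diameter across the axis
        span = tr.positions[intra].max(axis=1) - tr.positions[intra].min(axis=1)
        assert span[:, 2].max() <= 0.74 + 1e-9
        # extra spins never enter a cylinder (compartment fixed by design;
        # verify geometrically at the saved positions)
        extra_pos = tr.positions[~intra].reshape(-1, 3)
        sub_r2 = sub.r_outer**2
        cp, cz = sub.cells[0], sub.cells[2]
        ok = np.ones(len(extra_pos), bool)
        for j in range(len(sub.axis)):
            p1 = extra_pos[:, 1] if sub.axis[j] == 0 else extra_pos[:, 0]
            d1 = p1 - sub.c1[j]
            d1 -= cp * np.round(d1 / cp)
            d2 = extra_pos[:, 2] - sub.c2[j]
            d2 -= cz * np.round(d2 / cz)
            ok &= d1**2 + d2**2 >= sub_r2 - 1e-9
        assert ok.mean() > 0.999  # rare reflected overshoots only

    def test_step_size_guard(self):
        sub = build_substrate(outer_diameter=0.5)
        with pytest.raises(ValueError, match="step"):
            random_walk(sub, 10, D=2.0, dt=0.05, duration=1.0)


class TestPhaseAccumulation:
    def test_zero_susceptibility_zero_interreadout_phase(self, consts7t):
        """Fully unmyelinated substrate: mean inter-readout phase ~ 0."""
        sub = build_substrate(outer_diameter=0.98, fraction_myelinated=0.0)
        s = dippi_phase_accumulation(sub, [0.0], n_spins=400, seed=3,
                                     consts=consts7t)[0]
        assert abs(s.freq_total) < 1.0  # rad/s; lumen value is ~50

    def test_free_diffusion_attenuation(self):
        s = dippi_phase_accumulation(None, [1.0], n_spins=2000, dt=2e-3,
                                     seed=4)[0]
        assert abs(s.S_total) / s.n_spins == pytest.approx(np.exp(-2.0),
                                                           rel=0.12)

    def test_b0_fraction_matches_volume_and_additivity(self, consts7t):
        sub = build_substrate(outer_diameter=0.9)
        s = dippi_phase_accumulation(sub, [0.0], n_spins=900, seed=5,
                                     consts=consts7t)[0]
        assert s.S_total == pytest.approx(s.S_intra + s.S_extra, rel=1e-12)
        assert s.extra_fraction == pytest.approx(sub.extra_volume_fraction,
                                                 abs=0.04)

    def test_invalid_pulse_timing(self):
        sub = build_substrate()
        with pytest.raises(ValueError):
            dippi_phase_accumulation(sub, [1.0], 10, delta=40.0, Delta=30.0)

    def test_mc_error_scales_with_spin_count(self, consts7t):
        """Doubling the spin count shrinks the spread of the b=0 net phase
        roughly by sqrt(2) (averaged over repeats)."""
        sub = build_substrate(outer_diameter=0.98)
        def spread(n, seeds):
            vals = [dippi_phase_accumulation(sub, [0.0], n_spins=n, seed=s,
                                             consts=consts7t)[0].freq_total
                    for s in seeds]
            return np.std(vals)
        s_small = spread(100, range(4))
        s_big = spread(400, range(4, 8))
        assert s_big < s_small

    def test_summarize_table(self, consts7t):
        sub = build_substrate(outer_diameter=0.98)
        summ = dippi_phase_accumulation(sub, [0.0, 1.0], n_spins=300,
                                        seed=7, consts=consts7t)
        df = summarize_vs_b(summ)
        assert list(df.b) == [0.0, 1.0]
        assert {"extra_fraction", "shortfall_percent"} <= set(df.columns)
        # extra fraction decreases with b for this geometry
        assert df.extra_fraction.iloc[1] < df.extra_fraction.iloc[0]
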