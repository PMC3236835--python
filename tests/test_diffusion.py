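import math

import pytest

import amyvisc as av
from amyvisc._constants import AVOGADRO, BOLTZMANN

ETA0 = 0.89e-3


class TestClassicalStokesEinstein:
    @pytest.mark.parametrize(
        "radius_nm, expected",
        [(30.0, 8.18e-12), (80.0, 3.07e-12)],  # DLS-reported radius range
    )
    def test_against_direct_formula(self, thermo, radius_nm, expected):
        a = radius_nm * 1e-9
        direct = BOLTZMANN * 298.15 / (6 * math.pi * ETA0 * a)
        got = av.classical_stokes_einstein(a, thermo, ETA0)
        assert got == pytest.approx(direct, rel=1e-12)
        assert got == pytest.approx(expected, rel=1e-3)

    def test_inverse_in_radius(self, thermo):
        d1 = av.classical_stokes_einstein(30e-9, thermo, ETA0)
        d2 = av.classical_stokes_einstein(60e-9, thermo, ETA0)
        assert d2 == pytest.approx(d1 / 2, rel=1e-12)
        with pytest.raises(ValueError):
            av.classical_stokes_einstein(0.0, thermo, ETA0)


class TestSedimentation:
    def test_neutral_buoyancy_gives_zero(self):
        params = av.SedimentationParams(1e4, 1.0, 1.0, 1e-3, 2e-9)
        assert av.sedimentation_coefficient(params) == 0.0

    def test_closed_form_and_linearity(self):
        p = av.SedimentationParams(14300.0, 0.703, 1.0, 1.002e-3, 1.9e-9)
        expected = (
            14300.0
            * 1e-3
            * (1 - 0.703 * 1.0)
            / (AVOGADRO * 6 * math.pi * 1.002e-3 * 1.9e-9)
        )
        s = av.sedimentation_coefficient(p)
        assert s == pytest.approx(expected, rel=1e-12)
        # a compact globular protein sediments at a few Svedberg
        assert 1e-13 < s < 5e-13
        doubled = av.SedimentationParams(2 * 14300.0, 0.703, 1.0, 1.002e-3, 1.9e-9)
        assert av.sedimentation_coefficient(doubled) == pytest.approx(2 * s, rel=1e-12)

    def test_consistency_with_diffusion(self, thermo):
        # s / D = M (1 - vbar rho) / (N k_B T) when both use the same drag
        p = av.SedimentationParams(14300.0, 0.703, 1.0, ETA0, 1.9e-9)
        s = av.sedimentation_coefficient(p)
        d = av.classical_stokes_einstein(1.9e-9, thermo, ETA0)
        expected_ratio = (
            14300.0 * 1e-3 * (1 - 0.703) / (AVOGADRO * thermo.thermal_energy)
        )
        assert s / d == pytest.approx(expected_ratio, rel=1e-12)


class TestVolumeFractions:
    def test_zero_concentrations(self, base_shape):
        geoms = av.build_species_geometries(3, base_shape)
        comp = av.concentrations_to_volume_fractions(
            av.KineticState((0.0, 0.0, 0.0)), geoms
        )
        assert comp.phi0 == 1.0

    def test_unit_conversion_oracle(self, base_shape):
        # 5 uM of 1600-mers with the envelope volume: phi = N_A * C * V
        geoms = av.build_species_geometries(1, base_shape)
        comp = av.concentrations_to_volume_fractions(
            av.KineticState((5e-3,)), geoms
        )
        expected = AVOGADRO * 5e-3 * av.spheroid_volume(base_shape)
        assert comp.phi[0] == pytest.approx(expected, rel=1e-12)
        assert comp.phi[0] == pytest.approx(1.92e-2, rel=1e-2)
        assert comp.phi0 == pytest.approx(1 - expected, rel=1e-12)

    def test_solute_normalized_single_species(self, base_shape):
        geoms = av.build_species_geometries(1, base_shape)
        comp = av.concentrations_to_volume_fractions(
            av.KineticState((5e-3,)), geoms, mode="solute_normalized"
        )
        assert comp.solute_normalized() == (1.0,)

    def test_overfull_suspension_rejected(self, base_shape):
        geoms = av.build_species_geometries(1, base_shape)
        with pytest.raises(ValueError, match="unphysical"):
            av.concentrations_to_volume_fractions(av.KineticState((0.5,)), geoms)


class TestEffectiveDiffusionBounds:
    def test_dilute_limit_matches_pure_solvent_chwang_wu(
        self, base_shape, thermo, quemada
    ):
        geoms = av.build_species_geometries(1, base_shape)
        comp = av.concentrations_to_volume_fractions(
            av.KineticState((1e-12,)), geoms
        )
        (est,) = av.effective_diffusion_bounds(comp, geoms, thermo, quemada)
        d_upper = thermo.thermal_energy / av.spheroid_drag_parallel(
            base_shape, ETA0
        ).value
        d_lower = thermo.thermal_energy / av.spheroid_drag_perpendicular(
            base_shape, ETA0
        ).value
        assert est.k_upper == pytest.approx(d_upper, rel=1e-6)
        assert est.k_lower == pytest.approx(d_lower, rel=1e-6)
        # frozen: ~6.24e-12 / ~3.73e-12 m^2/s for the protofibril envelope
        assert est.k_upper == pytest.approx(6.240e-12, rel=1e-3)
        assert est.k_lower == pytest.approx(3.733e-12, rel=1e-3)

    def test_spherical_species_recovers_classical(self, thermo, quemada):
        sphere = av.SpeciesGeometry(
            1, av.SphereShape(30e-9), 4 / 3 * math.pi * (30e-9) ** 3
        )
        comp = av.MixtureComposition(1.0, (0.0,), "absolute")
        (est,) = av.effective_diffusion_bounds(comp, [sphere], thermo, quemada)
        classical = av.classical_stokes_einstein(30e-9, thermo, ETA0)
        assert est.k_lower == est.k_upper == pytest.approx(classical, rel=1e-14)

    def test_bounds_ordered_and_decreasing_in_viscosity(
        self, base_shape, thermo
    ):
        geoms = av.build_species_geometries(5, base_shape)
        comp = av.MixtureComposition(0.95, (0.01,) * 5, "absolute")
        thin = av.effective_diffusion_bounds(
            comp, geoms, thermo, av.QuemadaParams(eta0=ETA0)
        )
        thick = av.effective_diffusion_bounds(
            comp, geoms, thermo, av.QuemadaParams(eta0=2 * ETA0)
        )
        for lo, hi in zip(thin, thick):
            assert 0 < lo.k_lower <= lo.k_upper
            assert hi.k_upper < lo.k_upper  # more viscous -> slower
        # bigger species diffuse more slowly at fixed shape class
        uppers = [e.k_upper for e in thin]
        assert all(a > b for a, b in zip(uppers, uppers[1:]))

    def test_singularity_propagates(self, base_shape, thermo, quemada):
        geoms = av.build_species_geometries(1, base_shape)
        comp = av.MixtureComposition(0.3, (0.7,), "absolute")
        with pytest.raises(av.ViscositySingularityError):
            av.effective_diffusion_bounds(comp, geoms, thermo, quemada)


class TestOneSpeciesLimit:
    def test_classical_limit_exact(self, thermo):
        full = av.one_species_limit(0.0, 1.0, 30e-9, thermo, ETA0)
        assert full == av.classical_stokes_einstein(30e-9, thermo, ETA0)

    def test_expansion_matches_full_form_at_small_eps(self, thermo):
        eps = 1e-3
        phi0 = 1.0 / (1.0 + eps)
        phi = eps * phi0
        full = av.one_species_limit(phi, phi0, 30e-9, thermo, ETA0)
        approx = av.one_species_limit(
            phi, phi0, 30e-9, thermo, ETA0, expansion=True
        )
        assert abs(full - approx) / full < 1e-5

    def test_decreasing_in_volume_fraction(self, thermo):
        grid = [0.0, 0.05, 0.1, 0.2, 0.4]
        vals = [av.one_species_limit(p, 1.0 - p, 30e-9, thermo, ETA0) for p in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestSphereRodDiffusion:
    ROD = av.RodShape(400e-9, 20e-9)
    SPHERE = av.SphereShape(5e-9)

    def test_dilute_branch_ignores_rod_crowding(self, thermo, quemada):
        kwargs = dict(
            rod=self.ROD, sphere=self.SPHERE, params=quemada, thermo=thermo
        )
        d_dilute = av.diffusion.sphere_rod_diffusion(0.125, 0.05, **kwargs)
        factor = av.rod_shape_factor(self.ROD, "perpendicular")
        eta_bg = ETA0 * (1 - (0.05 / 0.875) / 0.6) ** -2
        expected = thermo.thermal_energy / (factor * eta_bg * self.ROD.length)
        assert d_dilute == pytest.approx(expected, rel=1e-12)
        # above the boundary the rod also senses other rods: slower
        d_crowded = av.diffusion.sphere_rod_diffusion(0.126, 0.05, **kwargs)
        assert d_crowded < d_dilute

    def test_parallel_faster_than_perpendicular(self, thermo, quemada):
        d_par = av.diffusion.sphere_rod_diffusion(
            0.01, 0.01, self.ROD, self.SPHERE, quemada, thermo, "parallel"
        )
        d_perp = av.diffusion.sphere_rod_diffusion(
            0.01, 0.01, self.ROD, self.SPHERE, quemada, thermo, "perpendicular"
        )
        assert d_par > d_perp
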