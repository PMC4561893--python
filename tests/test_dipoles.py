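"""Coupled-dipole assembly, solve, field evaluation and ensemble generation."""

import numpy as np
import pytest

from cytosers.dipoles import (
    DipoleSolution,
    Ensemble,
    EnhancementSummary,
    Particle,
    PlaneWave,
    _external_field_many,
    enhancement_summary,
    external_field,
    field_vs_height,
    generate_ensemble,
    solve_dipoles,
    total_field,
)
from cytosers.exceptions import GeometryError, InvalidInputError, PackingError
from cytosers.green import free_space_green, surface_self_term, total_green
from cytosers.materials import (
    OpticalConstants,
    fresnel_reflection,
    mie_dipole_polarizability,
)


def _background(optics, wave, points):
    empty = Ensemble(particles=(), optics=optics)
    return total_field(empty, DipoleSolution(np.zeros((0, 3)), 0.0, wave), points)


class TestGenerateEnsemble:
    def test_single_particle_rests_on_surface(self):
        ens = generate_ensemble(1, (20, 25), (500, 500), 2.0, seed=3)
        p = ens.particles[0]
        assert p.center[2] == p.radius

    def test_same_seed_is_bit_identical(self):
        a = generate_ensemble(20, (20, 25), (1000, 1000), 2.0, seed=11)
        b = generate_ensemble(20, (20, 25), (1000, 1000), 2.0, seed=11)
        assert a.particles == b.particles

    def test_pairwise_surface_gaps_respected(self):
        ens = generate_ensemble(50, (20, 25), (1000, 1000), 2.0, seed=7)
        c, r = ens.centers, ens.radii
        for i in range(50):
            d = np.linalg.norm(c[i + 1:] - c[i], axis=1)
            gaps = d - (r[i + 1:] + r[i])
            assert np.all(gaps >= 2.0 - 1e-9)

    def test_infeasible_packing_raises(self):
        with pytest.raises(PackingError):
            generate_ensemble(100, (40, 50), (300, 300), 2.0, seed=0)

    def test_overlapping_particles_rejected_by_ensemble(self, optics_silver):
        with pytest.raises(GeometryError):
            Ensemble(
                particles=(Particle((0, 0, 20), 20), Particle((10, 0, 20), 20)),
                optics=optics_silver,
            )


class TestExternalField:
    def test_pec_tangential_null_at_surface(self):
        optics = OpticalConstants(532.0, eps_substrate=-1e18 + 0.0j)
        for pol in ("TM", "TE"):
            E = external_field([13.0, -4.0, 0.0], PlaneWave(532.0, 0.0, pol), optics)
            assert np.max(np.abs(E[:2])) < 1e-6

    @pytest.mark.parametrize("angle", [0.0, 30.0, 65.0])
    def test_te_has_no_normal_component(self, angle, optics_silver):
        E = external_field([0, 0, 40.0], PlaneWave(532.0, angle, "TE"), optics_silver)
        assert E[2] == 0.0

    def test_oblique_tm_matches_two_wave_superposition(self, optics_silver):
        """65-degree TM over silver at z = 25 nm vs a standalone two-wave sum."""
        th = np.deg2rad(65.0)
        k = optics_silver.k_ambient
        r = np.array([37.0, 11.0, 25.0])
        rc = fresnel_reflection(65.0, "TM", 1.0, optics_silver.eps_substrate)
        # independent formulation: build polarization vectors from k x y-hat
        k_inc = k * np.array([np.sin(th), 0.0, -np.cos(th)])
        k_ref = k * np.array([np.sin(th), 0.0, np.cos(th)])
        yhat = np.array([0.0, 1.0, 0.0])
        e_inc = np.cross(k_inc / k, yhat)
        e_ref = -np.cross(yhat, k_ref / k)
        E_oracle = e_inc * np.exp(1j * np.dot(k_inc, r)) + rc * e_ref * np.exp(
            1j * np.dot(k_ref, r)
        )
        E = external_field(r, PlaneWave(532.0, 65.0, "TM"), optics_silver)
        assert np.linalg.norm(E - E_oracle) < 1e-12 * np.linalg.norm(E_oracle)

    def test_below_surface_rejected(self, optics_silver):
        with pytest.raises(GeometryError):
            external_field([0, 0, -5.0], PlaneWave(), optics_silver)


class TestSolveDipoles:
    def test_zero_external_field_gives_zero_moments(self, optics_silver):
        ens = generate_ensemble(5, (20, 25), (500, 500), 2.0, seed=1,
                                optics=optics_silver)
        sol = solve_dipoles(ens, PlaneWave(532.0, 65.0, "TM", amplitude=0.0))
        assert np.all(sol.moments == 0)

    def test_single_particle_no_substrate_closed_form(self, optics_matched):
        """p = alpha eps0 E_in exactly when decoupled from the surface."""
        ens = Ensemble(particles=(Particle((0, 0, 25), 25),), optics=optics_matched)
        wave = PlaneWave(532.0, 0.0, "TM")
        sol = solve_dipoles(ens, wave)
        alpha = mie_dipole_polarizability(25.0, 532.0, ens.eps_particle, 1.0)
        expected = optics_matched.eps0 * alpha * external_field(
            [0, 0, 25], wave, optics_matched
        )
        assert np.linalg.norm(sol.moments[0] - expected) <= 1e-12 * np.linalg.norm(expected)
        assert sol.residual_norm < 1e-10

    def test_weak_coupling_matches_born_series(self, optics_matched):
        """Three particles separated by many wavelengths: 2-term Born series."""
        parts = (
            Particle((0, 0, 20), 20),
            Particle((4000, 300, 20), 20),
            Particle((1500, 3500, 20), 20),
        )
        ens = Ensemble(particles=parts, optics=optics_matched)
        wave = PlaneWave(532.0, 30.0, "TM")
        sol = solve_dipoles(ens, wave)
        alpha = mie_dipole_polarizability(20.0, 532.0, ens.eps_particle, 1.0)
        eps0, k0 = optics_matched.eps0, optics_matched.k0
        E0 = _external_field_many(ens.centers, wave, optics_matched)
        p0 = eps0 * alpha * E0
        p1 = p0.copy()
        for i in range(3):
            for j in range(3):
                if i != j:
                    G = free_space_green(ens.centers[i], ens.centers[j],
                                         optics_matched.k_ambient)
                    p1[i] += alpha * k0**2 * (G @ p0[j])
        err = np.linalg.norm(sol.moments - p1) / np.linalg.norm(sol.moments)
        assert err < 1e-4

    def test_matches_independent_direct_inversion(self, optics_silver):
        """Alternative assembly (inverse-polarizability form) agrees to 1e-10."""
        ens = generate_ensemble(3, (20, 25), (300, 300), 2.0, seed=5,
                                optics=optics_silver)
        wave = PlaneWave(532.0, 65.0, "TM")
        sol = solve_dipoles(ens, wave)

        k, k0, eps0 = optics_silver.k_ambient, optics_silver.k0, optics_silver.eps0
        ea, es = optics_silver.eps_ambient, optics_silver.eps_substrate
        N = 3
        A = np.zeros((3 * N, 3 * N), dtype=complex)
        for i in range(N):
            a_i = mie_dipole_polarizability(ens.radii[i], 532.0, ens.eps_particle, ea)
            A[3 * i:3 * i + 3, 3 * i:3 * i + 3] = (
                np.eye(3) / (eps0 * a_i)
                - (k0**2 / eps0) * surface_self_term(ens.centers[i], k, ea, es)
            )
            for j in range(N):
                if i != j:
                    A[3 * i:3 * i + 3, 3 * j:3 * j + 3] = -(k0**2 / eps0) * total_green(
                        ens.centers[i], ens.centers[j], k, ea, es
                    )
        E_in = _external_field_many(ens.centers, wave, optics_silver).reshape(-1)
        p_oracle = (np.linalg.inv(A) @ E_in).reshape(N, 3)
        assert np.linalg.norm(sol.moments - p_oracle) / np.linalg.norm(p_oracle) < 1e-10

    def test_linearity_in_incident_amplitude(self, optics_silver):
        ens = generate_ensemble(6, (20, 25), (500, 500), 2.0, seed=2,
                                optics=optics_silver)
        s1 = solve_dipoles(ens, PlaneWave(532.0, 65.0, "TM", amplitude=1.0))
        s3 = solve_dipoles(ens, PlaneWave(532.0, 65.0, "TM", amplitude=3.0))
        assert np.allclose(s3.moments, 3.0 * s1.moments, rtol=1e-12, atol=0)

    def test_permutation_invariance_of_fields(self, optics_silver):
        ens = generate_ensemble(5, (20, 25), (500, 500), 2.0, seed=9,
                                optics=optics_silver)
        perm = [3, 0, 4, 1, 2]
        ens_p = Ensemble(
            particles=tuple(ens.particles[i] for i in perm), optics=optics_silver
        )
        wave = PlaneWave(532.0, 65.0, "TM")
        pts = np.array([[100.0, 200.0, 80.0], [400.0, 100.0, 60.0]])
        f1 = total_field(ens, solve_dipoles(ens, wave), pts)
        f2 = total_field(ens_p, solve_dipoles(ens_p, wave), pts)
        assert np.allclose(f1.field, f2.field, rtol=1e-10)

    def test_wavelength_mismatch_rejected(self, optics_silver):
        ens = generate_ensemble(2, (20, 25), (500, 500), 2.0, seed=0,
                                optics=optics_silver)
        with pytest.raises(InvalidInputError):
            solve_dipoles(ens, PlaneWave(633.0, 0.0, "TM"))


class TestTotalField:
    def test_no_particles_reproduces_external_field(self, optics_silver):
        wave = PlaneWave(532.0, 65.0, "TM")
        pts = np.array([[10.0, 20.0, 70.0], [0.0, 0.0, 100.0]])
        grid = _background(optics_silver, wave, pts)
        E_direct = np.array([external_field(p, wave, optics_silver) for p in pts])
        assert np.allclose(grid.field, E_direct)
        assert np.allclose(grid.intensity, np.sum(np.abs(E_direct) ** 2, axis=1))

    def test_far_point_relaxes_to_background(self, optics_silver):
        ens = Ensemble(particles=(Particle((0, 0, 25), 25),), optics=optics_silver)
        wave = PlaneWave(532.0, 65.0, "TM")
        sol = solve_dipoles(ens, wave)
        far = np.array([[50000.0, 50000.0, 5320.0]])
        grid = total_field(ens, sol, far)
        bg = _background(optics_silver, wave, far)
        assert grid.intensity[0] == pytest.approx(bg.intensity[0], rel=0.01)

    def test_single_vertical_dipole_superposition_oracle(self, optics_silver):
        """Total field = E_in + dipole + image fields at hand-picked probes."""
        ens = Ensemble(particles=(Particle((0, 0, 22), 22),), optics=optics_silver)
        wave = PlaneWave(532.0, 65.0, "TM")
        sol = solve_dipoles(ens, wave)
        p = sol.moments[0]
        k, k0, eps0 = optics_silver.k_ambient, optics_silver.k0, optics_silver.eps0
        beta = (optics_silver.eps_substrate - 1.0) / (optics_silver.eps_substrate + 1.0)
        mirror = np.diag([-1.0, -1.0, 1.0])
        probes = np.array([[0.0, 0.0, 90.0], [60.0, 0.0, 40.0], [-30.0, 45.0, 70.0]])
        grid = total_field(ens, sol, probes)
        for probe, E_pkg in zip(probes, grid.field):
            E = external_field(probe, wave, optics_silver)
            E = E + (k0**2 / eps0) * free_space_green(probe, [0, 0, 22], k) @ p
            E = E + (k0**2 / eps0) * beta * (
                free_space_green(probe, [0, 0, -22], k) @ (mirror @ p)
            )
            assert np.linalg.norm(E_pkg - E) < 1e-10 * np.linalg.norm(E)

    def test_points_inside_particles_are_masked(self, optics_silver):
        ens = Ensemble(particles=(Particle((0, 0, 25), 25),), optics=optics_silver)
        sol = solve_dipoles(ens, PlaneWave(532.0, 0.0, "TM"))
        with pytest.warns(UserWarning, match="masked"):
            grid = total_field(ens, sol, np.array([[0.0, 0.0, 25.0], [0.0, 0.0, 90.0]]))
        assert np.isnan(grid.intensity[0])
        assert np.isfinite(grid.intensity[1])


class TestEnhancement:
    def test_identical_grids_give_unity(self, optics_silver):
        wave = PlaneWave(532.0, 65.0, "TM")
        pts = np.column_stack([np.linspace(0, 500, 20),
                               np.zeros(20), np.full(20, 60.0)])
        bg = _background(optics_silver, wave, pts)
        s = enhancement_summary(bg, bg)
        assert s.mean_enhancement == pytest.approx(1.0)
        assert s.max_enhancement == pytest.approx(1.0)

    def test_oblique_tm_beats_normal_incidence(self):
        """Mean enhancement at the 60 nm plane: 65-deg TM > normal incidence."""
        xs = np.linspace(0.0, 1000.0, 31)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        pts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, 60.0)])
        for seed in range(3):
            ens = generate_ensemble(30, (20, 25), (1000, 1000), 2.0, seed=seed)
            means = {}
            for angle in (0.0, 65.0):
                wave = PlaneWave(532.0, angle, "TM")
                sol = solve_dipoles(ens, wave)
                grid = total_field(ens, sol, pts)
                bg = _background(ens.optics, wave, pts)
                means[angle] = enhancement_summary(grid, bg).mean_enhancement
            assert means[65.0] > means[0.0]

    def test_mirror_symmetric_configuration_gives_mirror_field(self, optics_silver):
        """Config symmetric about the plane of incidence -> symmetric map (TM)."""
        parts = (
            Particle((100.0, 80.0, 22.0), 22.0),
            Particle((100.0, -80.0, 22.0), 22.0),
            Particle((260.0, 0.0, 25.0), 25.0),
        )
        ens = Ensemble(particles=parts, optics=optics_silver)
        sol = solve_dipoles(ens, PlaneWave(532.0, 65.0, "TM"))
        pts_up = np.array([[50.0, 60.0, 70.0], [200.0, 130.0, 90.0]])
        pts_dn = pts_up * np.array([1.0, -1.0, 1.0])
        up = total_field(ens, sol, pts_up)
        dn = total_field(ens, sol, pts_dn)
        assert np.allclose(up.intensity, dn.intensity, rtol=1e-10)

    def test_stronger_dipoles_increase_enhancement(self, optics_silver):
        ens = Ensemble(particles=(Particle((500, 500, 25), 25),), optics=optics_silver,
                       region=(1000.0, 1000.0))
        wave = PlaneWave(532.0, 65.0, "TM")
        sol = solve_dipoles(ens, wave)
        pts = np.array([[500.0, 500.0, 60.0]])  # right above: scattering dominates
        bg = _background(optics_silver, wave, pts)
        e1 = enhancement_summary(total_field(ens, sol, pts), bg).max_enhancement
        sol2 = DipoleSolution(2.0 * sol.moments, sol.residual_norm, wave)
        e2 = enhancement_summary(total_field(ens, sol2, pts), bg).max_enhancement
        assert e2 > e1


@pytest.fixture(scope="module")
def solved():
    ens = generate_ensemble(20, (20, 25), (800, 800), 2.0, seed=4)
    wave = PlaneWave(532.0, 65.0, "TM")
    return ens, solve_dipoles(ens, wave), wave


class TestFieldVsHeight:

    def test_repeated_heights_identical(self, solved):
        ens, sol, _ = solved
        prof = field_vs_height(ens, sol, [10.0, 10.0, 10.0])
        assert prof["mean_intensity"].nunique() == 1

    def test_enhancement_decays_with_height(self, solved):
        """Mean intensity / background is non-increasing far above the layer."""
        ens, sol, wave = solved
        heights = np.array([30.0, 60.0, 120.0, 240.0])
        prof = field_vs_height(ens, sol, heights)
        z_top = float(np.max(ens.centers[:, 2] + ens.radii))
        bg = np.array([
            _background(ens.optics, wave,
                        np.array([[0.0, 0.0, z_top + h]])).intensity[0]
            for h in heights
        ])
        ratio = prof["mean_intensity"].to_numpy() / bg
        assert np.all(np.diff(ratio) <= 1e-9)

    def test_analyte_band_seven_exceeds_seventeen_nm(self, solved):
        """Intensity at 7 nm above the layer >= at 17 nm (analyte distance band)."""
        ens, sol, _ = solved
        prof = field_vs_height(ens, sol, [7.0, 17.0])
        assert prof["mean_intensity"].iloc[0] >= prof["mean_intensity"].iloc[1]

    def test_negative_height_rejected(self, solved):
        ens, sol, _ = solved
        with pytest.raises(InvalidInputError):
            field_vs_height(ens, sol, [-1.0])
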