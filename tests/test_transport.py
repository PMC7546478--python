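"""Transport engine: helix geometry, energy conservation, determinism,
Monte Carlo statistics, and photon attenuation."""

import math

import numpy as np
import pytest

from magbrachy import _kernels as K
from magbrachy.grids import VoxelPhantom
from magbrachy.materials import csda_range, get_material, photon_cross_sections
from magbrachy.phantoms import PhantomSpec, make_lung_cube
from magbrachy.sources import PointElectronSource
from magbrachy.transport import (
    FieldSpec,
    ParticleState,
    TransportParams,
    gyroradius,
    helical_step,
    run_histories,
)


def electron_state(direction=(1.0, 0.0, 0.0), energy=0.432):
    d = np.asarray(direction, float)
    return ParticleState("electron", np.zeros(3), d / np.linalg.norm(d),
                         energy)


class TestHelix:
    def test_zero_field_is_straight(self):
        s = helical_step(electron_state(), FieldSpec((0, 0, 0)), 3.7)
        assert np.allclose(s.position, [3.7, 0, 0], atol=1e-15)

    def test_gyroradius_432kev_3t(self):
        # r = √(T² + 2T·mc²)/(c q B): pc = 0.7926 MeV → 0.881 mm
        assert gyroradius(0.432, 3.0) == pytest.approx(0.8812, abs=2e-4)

    def test_full_gyration_closes(self):
        r = gyroradius(0.432, 3.0)
        s = helical_step(electron_state((1, 0, 0)), FieldSpec((0, 0, 3.0)),
                         2 * math.pi * r, chord_tolerance=1e-6)
        assert np.linalg.norm(s.position) < 1e-9
        assert np.allclose(s.direction, [1, 0, 0], atol=1e-9)

    def test_perpendicular_orbit_diameter(self):
        # after half a gyration the electron sits 2 r_g away
        r = gyroradius(0.432, 3.0)
        s = helical_step(electron_state((1, 0, 0)), FieldSpec((0, 0, 3.0)),
                         math.pi * r, chord_tolerance=1e-7)
        assert np.linalg.norm(s.position) == pytest.approx(2 * r, rel=1e-6)
        assert s.position[2] == 0.0

    def test_substepped_path_matches_closed_form(self):
        # closed-form helix evaluated directly vs many chord sub-steps
        b = FieldSpec((0, 0, 3.0))
        st0 = electron_state((0.6, 0.64, 0.48))
        arc = 2.5
        fine = helical_step(st0, b, arc, chord_tolerance=1e-9)
        k = K.GYRO * 3.0 / math.sqrt(0.432 * (0.432 + 2 * K.ME))
        exact = K._helix_advance(0, 0, 0, *st0.direction, arc,
                                 0.0, 0.0, k, k)
        assert np.allclose(fine.position, exact[:3], atol=1e-12)
        assert np.allclose(fine.direction, exact[3:], atol=1e-12)

    def test_energy_unchanged_and_unit_direction(self):
        s = helical_step(electron_state((0, 1, 0)), FieldSpec((1, 2, 2)),
                         5.0)
        assert s.kinetic_energy == 0.432
        assert np.linalg.norm(s.direction) == pytest.approx(1.0, abs=1e-12)


class TestEnergyConservation:
    def test_per_history_conservation(self, mono_b0):
        tally = mono_b0.meta["conservation"]
        mean_e = tally["emitted"] / mono_b0.n_histories
        assert tally["max_residual"] < 1e-9 * mean_e
        assert tally["deposited"] + tally["escaped"] == pytest.approx(
            tally["emitted"], rel=1e-12)

    def test_conservation_violation_raises(self, lung_cube, fast_params):
        from magbrachy.transport import ConservationError, run_histories

        class BrokenSource(PointElectronSource):
            def _run_batch(self, n, *args, **kw):
                res = super()._run_batch(n, *args, **kw)
                return (res[0], res[1], res[2], 1.0)  # fake residual

        src = BrokenSource([0, 0, 0], energy=0.432)
        with pytest.raises(ConservationError):
            run_histories(src, lung_cube, FieldSpec((0, 0, 0)),
                          fast_params, 100, n_batches=2, seed=0)


class TestCSDAOracleBounds:
    def test_straight_line_range_without_scattering(self, lung_cube):
        # scattering off, B = 0: 95% of the energy inside the CSDA sphere
        params = TransportParams(max_step=0.5, scattering=False)
        src = PointElectronSource([0, 0, 0], energy=0.432)
        dose = run_histories(src, lung_cube, FieldSpec((0, 0, 0)), params,
                             3000, n_batches=2, seed=7)
        r_mm = csda_range(get_material("lung_icrp"), 0.432) / 0.26 * 10.0
        x = (np.arange(100) + 0.5) * 0.1 - 5.0
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        r = np.sqrt(xx**2 + yy**2 + zz**2)
        inside = dose.mean[r <= r_mm * 1.001].sum()
        assert inside / dose.mean.sum() > 0.95

    def test_field_confines_to_two_gyroradii(self, lung_cube):
        params = TransportParams(max_step=0.5, scattering=False)
        src = PointElectronSource([0, 0, 0], energy=0.432)
        dose = run_histories(src, lung_cube, FieldSpec((0, 0, 3.0)), params,
                             3000, n_batches=2, seed=7)
        bound = 2 * gyroradius(0.432, 3.0) + 0.1 * math.sqrt(3)
        x = (np.arange(100) + 0.5) * 0.1 - 5.0
        xx, yy = np.meshgrid(x, x, indexing="ij")
        rho = np.sqrt(xx**2 + yy**2)
        outside = dose.mean.sum(axis=2)[rho > bound].sum()
        assert outside == 0.0


class TestStatistics:
    def test_same_seed_bit_identical(self, lung_cube, fast_params):
        src = PointElectronSource([0, 0, 0], energy=0.432)
        d1 = run_histories(src, lung_cube, FieldSpec((0, 0, 0)),
                           fast_params, 5000, n_batches=4, seed=99)
        d2 = run_histories(src, lung_cube, FieldSpec((0, 0, 0)),
                           fast_params, 5000, n_batches=4, seed=99)
        assert np.array_equal(d1.mean, d2.mean)
        assert np.array_equal(d1.sem, d2.sem)

    def test_sem_scales_like_sqrt_n(self, lung_cube, fast_params):
        src = PointElectronSource([0, 0, 0], energy=0.432)
        small = run_histories(src, lung_cube, FieldSpec((0, 0, 0)),
                              fast_params, 30_000, n_batches=10, seed=5)
        big = run_histories(src, lung_cube, FieldSpec((0, 0, 0)),
                            fast_params, 120_000, n_batches=10, seed=6)
        c = small.voxel_of((0, 0, 0))
        sl = (slice(c[0] - 8, c[0] + 9), slice(c[1] - 8, c[1] + 9),
              slice(c[2] - 8, c[2] + 9))
        sel = small.mean[sl] > 0
        ratio = np.median(small.sem[sl][sel] /
                          np.where(big.sem[sl][sel] > 0,
                                   big.sem[sl][sel], np.inf))
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_b0_isotropy_on_axes(self, mono_b0):
        c = mono_b0.voxel_of((0, 0, 0))
        picks = {}
        for name, off in (("+x", (10, 0, 0)), ("+y", (0, 10, 0)),
                          ("+z", (0, 0, 10)), ("-x", (-10, 0, 0))):
            idx = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            picks[name] = (mono_b0.mean[idx], mono_b0.sem[idx])
        vals = np.array([v for v, _ in picks.values()])
        sems = np.array([s for _, s in picks.values()])
        for i in range(len(vals)):
            for j in range(i + 1, len(vals)):
                comb = math.sqrt(sems[i] ** 2 + sems[j] ** 2)
                assert abs(vals[i] - vals[j]) < 3.5 * comb

    def test_axisymmetry_with_field(self, mono_b3):
        from magbrachy.analysis import isodose_distance, normalize_at_point

        norm = normalize_at_point(mono_b3, (1.0, 0, 0))
        px = isodose_distance(norm, 10.0, directions=("+x", "-x"))
        py = isodose_distance(norm, 10.0, directions=("+y", "-y"))
        comb = math.sqrt(px.sem**2 + py.sem**2 + 2 * 0.05**2)
        assert abs(px.mean - py.mean) < 3 * comb + 0.1


def _water_slab(nx=100, spacing=1.0):
    dims = (nx, 40, 40)
    return VoxelPhantom(
        origin=np.array([0.0, -20.0, -20.0]),
        spacing=np.array([spacing, spacing, spacing]),
        material_index=np.zeros(dims, dtype=np.uint8),
        density=np.full(dims, 1.0),
        materials=("water",),
    )


class TestPhotonTransport:
    def test_attenuation_through_water(self):
        """Fraction of 0.612 MeV photons with no interaction over 10 cm
        of water equals exp(−μ·10) within 3σ binomial (Woodcock check)."""
        from magbrachy.tables import PhysicsTables

        ph = _water_slab()
        tables = PhysicsTables(ph.materials)
        params = TransportParams(max_step=0.5)
        mu = photon_cross_sections(get_material("water"),
                                   0.612462).sigma_total
        n = 20_000
        edep = np.zeros(ph.dims)
        st = K.rng_state(3, 0)
        scol, n_hard, dcut, don = tables.electron_loss_arrays(False, 0.05)
        mu_maj = tables.majorant(ph.density, ph.material_index)
        survived = 0
        for _ in range(n):
            d, e = K.photon_history(
                0.05, 0.0, 0.0, 1.0, 0.0, 0.0, 0.612462,
                ph.material_index, ph.density, *ph.origin, *ph.spacing,
                0.0, 0.0, 0.0, scol, tables.range_g, tables.inv_x0,
                tables.sig_total, tables.sig_pe, mu_maj,
                tables.loge0, tables.dloge,
                params.dr_over_range, params.final_range / 1000,
                params.electron_cutoff / 1000, params.max_step,
                params.chord_tolerance, 1, don, n_hard, dcut, 0,
                tables.zoa, params.photon_cutoff / 1000, edep, st)
            if d == 0.0:
                survived += 1
        p_want = math.exp(-mu * 9.995)  # start 0.05 mm inside the slab
        sigma = math.sqrt(p_want * (1 - p_want) / n)
        assert abs(survived / n - p_want) < 3 * sigma

    def test_heterogeneous_attenuation(self):
        """Woodcock tracking reproduces exp(−Σ μᵢρᵢℓᵢ) across a density
        step (5 cm of ρ=1 followed by 5 cm of ρ=0.3)."""
        from magbrachy.tables import PhysicsTables

        ph = _water_slab()
        ph.density[50:, :, :] = 0.3
        tables = PhysicsTables(ph.materials)
        params = TransportParams(max_step=0.5)
        mu = photon_cross_sections(get_material("water"),
                                   0.612462).sigma_total
        scol, n_hard, dcut, don = tables.electron_loss_arrays(False, 0.05)
        mu_maj = tables.majorant(ph.density, ph.material_index)
        n = 20_000
        edep = np.zeros(ph.dims)
        st = K.rng_state(4, 0)
        survived = 0
        for _ in range(n):
            d, e = K.photon_history(
                0.05, 0.0, 0.0, 1.0, 0.0, 0.0, 0.612462,
                ph.material_index, ph.density, *ph.origin, *ph.spacing,
                0.0, 0.0, 0.0, scol, tables.range_g, tables.inv_x0,
                tables.sig_total, tables.sig_pe, mu_maj,
                tables.loge0, tables.dloge,
                params.dr_over_range, params.final_range / 1000,
                params.electron_cutoff / 1000, params.max_step,
                params.chord_tolerance, 1, don, n_hard, dcut, 0,
                tables.zoa, params.photon_cutoff / 1000, edep, st)
            if d == 0.0:
                survived += 1
        tau = mu * (4.995 * 1.0 + 5.0 * 0.3)
        p_want = math.exp(-tau)
        sigma = math.sqrt(p_want * (1 - p_want) / n)
        assert abs(survived / n - p_want) < 3.5 * sigma

    def test_vacuum_crossing_deposits_nothing(self):
        from magbrachy.tables import PhysicsTables

        dims = (40, 40, 40)
        ph = VoxelPhantom(np.array([-20.0, -20, -20]), np.ones(3),
                          np.zeros(dims, dtype=np.uint8),
                          np.full(dims, 1e-25), ("vacuum",))
        tables = PhysicsTables(ph.materials)
        params = TransportParams()
        scol, n_hard, dcut, don = tables.electron_loss_arrays(False, 0.05)
        mu_maj = tables.majorant(ph.density, ph.material_index)
        edep = np.zeros(dims)
        st = K.rng_state(5, 0)
        d, e = K.photon_history(
            -19.0, 0.0, 0.0, 1.0, 0.0, 0.0, 0.3,
            ph.material_index, ph.density, *ph.origin, *ph.spacing,
            0.0, 0.0, 0.0, scol, tables.range_g, tables.inv_x0,
            tables.sig_total, tables.sig_pe, mu_maj,
            tables.loge0, tables.dloge,
            params.dr_over_range, params.final_range / 1000,
            params.electron_cutoff / 1000, params.max_step,
            params.chord_tolerance, 1, don, n_hard, dcut, 0,
            tables.zoa, params.photon_cutoff / 1000, edep, st)
        assert d == 0.0 and e == pytest.approx(0.3)
        assert edep.sum() == 0.0


class TestFreePathSampling:
    def test_exponential_free_paths_ks(self):
        """The kernel RNG's −ln(U)/μ free paths follow Exp(μ)
        (KS test at α = 0.01, n = 1e5)."""
        from scipy import stats

        st = K.rng_state(12, 0)
        mu = 0.7
        samples = np.array([-math.log(max(K._uniform(st), 1e-300)) / mu
                            for _ in range(100_000)])
        res = stats.kstest(samples, "expon", args=(0, 1 / mu))
        assert res.pvalue > 0.01


class TestRunValidation:
    def test_zero_histories_rejected(self, lung_cube, fast_params):
        src = PointElectronSource([0, 0, 0], energy=0.432)
        with pytest.raises(ValueError):
            run_histories(src, lung_cube, FieldSpec((0, 0, 0)),
                          fast_params, 0, seed=1)

    def test_particle_state_invariants(self):
        with pytest.raises(ValueError):
            ParticleState("electron", np.zeros(3), np.array([1.0, 1.0, 0]),
                          0.1)
        with pytest.raises(ValueError):
            ParticleState("electron", np.zeros(3), np.array([1.0, 0, 0]),
                          -0.1)
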