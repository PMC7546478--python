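"""Dose-grid analysis: normalization, iso-dose distances, reductions,
difference maps and DVH parameters — checked against closed forms and
brute-force oracles on synthetic fields."""

import math

import numpy as np
import pytest

from magbrachy.analysis import (
    AnalysisError,
    IsoDoseProfile,
    compute_dvh,
    difference_map,
    isodose_distance,
    normalize_at_point,
    normalize_to_prescription,
    percent_reduction,
)
from magbrachy.grids import DoseGrid


def radial_grid(n=101, spacing=0.1, power=2.0, sem_frac=0.001):
    """Synthetic radially monotone field D(r) = 100·(1 mm/r)^power."""
    half = n * spacing / 2.0
    x = -half + (np.arange(n) + 0.5) * spacing
    xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    r = np.maximum(r, spacing / 4)
    mean = 100.0 * r**-power
    return DoseGrid(np.full(3, -half), np.full(3, spacing), mean,
                    sem_frac * mean, 10, 1000)


class TestNormalizeAtPoint:
    def test_reference_voxel_reports_100(self):
        norm = normalize_at_point(radial_grid(), (1.0, 0, 0))
        i, j, k = norm.voxel_of((1.0, 0, 0))
        assert norm.mean[i, j, k] == pytest.approx(100.0, rel=0.05)

    def test_idempotent(self):
        once = normalize_at_point(radial_grid(), (1.0, 0, 0))
        twice = normalize_at_point(once, (1.0, 0, 0))
        assert np.allclose(once.mean, twice.mean, rtol=1e-12)

    def test_zero_reference_rejected(self):
        g = radial_grid()
        g.mean[:] = 0.0
        with pytest.raises(AnalysisError):
            normalize_at_point(g, (1.0, 0, 0))

    def test_undersampled_reference_names_sem(self):
        # neighborhood averaging gains √27, so the per-voxel noise must
        # be large before the reference is rejected
        g = radial_grid(sem_frac=0.5)
        with pytest.raises(AnalysisError, match="SEM"):
            normalize_at_point(g, (1.0, 0, 0))


class TestIsodoseDistance:
    def test_inverse_square_closed_form(self):
        # D(r) = 100/r²: the 10% level sits at r = √10 mm exactly
        norm = normalize_at_point(radial_grid(), (1.0, 0, 0))
        prof = isodose_distance(norm, 10.0)
        assert prof.mean == pytest.approx(math.sqrt(10.0), abs=0.06)

    def test_level_100_at_1mm(self):
        norm = normalize_at_point(radial_grid(), (1.0, 0, 0))
        prof = isodose_distance(norm, 100.0)
        assert prof.mean == pytest.approx(1.0, abs=0.06)

    def test_levels_monotone(self):
        norm = normalize_at_point(radial_grid(), (1.0, 0, 0))
        d10 = isodose_distance(norm, 10.0).mean
        d25 = isodose_distance(norm, 25.0).mean
        d50 = isodose_distance(norm, 50.0).mean
        assert d10 > d25 > d50

    def test_azimuthal_mode_agrees_with_axis_mode(self):
        norm = normalize_at_point(radial_grid(), (1.0, 0, 0))
        ax = isodose_distance(norm, 10.0, mode="axis")
        az = isodose_distance(norm, 10.0, mode="azimuthal")
        assert az.mean == pytest.approx(ax.mean, abs=0.15)

    def test_matches_brute_force_marching(self):
        # oracle: scan every voxel on the +x ray for the outermost
        # above-level voxel, no interpolation
        norm = normalize_at_point(radial_grid(), (1.0, 0, 0))
        level = 25.0
        i0, j0, k0 = norm.voxel_of((0, 0, 0))
        ray = norm.mean[i0:, j0, k0]
        above = np.nonzero(ray >= level)[0]
        brute = (above[-1] + 0.5) * 0.1
        prof = isodose_distance(norm, level, directions=("+x",))
        assert abs(prof.distances["+x"] - brute) <= 0.1  # one voxel

    def test_unreachable_level_raises(self):
        # a field varying only in x: the ±z rays never cross any level
        n, spacing = 51, 0.2
        half = n * spacing / 2
        x = -half + (np.arange(n) + 0.5) * spacing
        mean = np.broadcast_to(np.abs(x)[:, None, None] * 10.0,
                               (n, n, n)).copy()
        g = DoseGrid(np.full(3, -half), np.full(3, spacing), mean,
                     0.001 * mean, 10, 100)
        norm = normalize_at_point(g, (1.0, 0, 0))
        with pytest.raises(AnalysisError, match="never reached"):
            isodose_distance(norm, 50.0, directions=("+z",))

    def test_edge_flag_set_when_level_extends_past_grid(self):
        g = radial_grid(power=0.1)  # nearly flat: 10% beyond the edge
        norm = normalize_at_point(g, (1.0, 0, 0))
        prof = isodose_distance(norm, 50.0)
        assert prof.at_edge


class TestPercentReduction:
    def _profile(self, mean, sem=0.05, level=10.0):
        return IsoDoseProfile(level, {"+x": mean}, mean, sem)

    def test_reported_mono_values_consistent(self):
        val, _ = percent_reduction(self._profile(4.08), self._profile(1.43))
        assert val == pytest.approx(64.95, abs=0.05)

    def test_reported_spectrum_values_consistent(self):
        val, _ = percent_reduction(self._profile(2.01), self._profile(1.48))
        assert val == pytest.approx(26.4, abs=0.1)

    def test_identical_profiles_zero(self):
        val, _ = percent_reduction(self._profile(2.0), self._profile(2.0))
        assert val == 0.0

    def test_swap_antisymmetry_relation(self):
        p = self._profile(4.0)
        q = self._profile(3.0)
        fwd, _ = percent_reduction(p, q)
        rev, _ = percent_reduction(q, p)
        assert rev == pytest.approx(100 * (1 - 1 / (1 - fwd / 100)),
                                    rel=1e-12)

    def test_level_mismatch_rejected(self):
        with pytest.raises(AnalysisError):
            percent_reduction(self._profile(4.0, level=10.0),
                              self._profile(3.0, level=25.0))


class TestDifferenceMap:
    def test_identical_grids_fully_masked(self):
        g = radial_grid()
        diff = difference_map(g, g)
        assert np.all(np.isnan(diff))

    def test_uniform_5pct_unmasked(self):
        a = radial_grid(sem_frac=1e-6)
        b = a.scaled(1.05)
        diff = difference_map(a, b)
        assert np.nanmax(diff) == pytest.approx(5.0, abs=1e-9)
        assert np.isfinite(diff).mean() > 0.99

    def test_noisy_voxel_masked(self):
        a = radial_grid(sem_frac=1e-6)
        b = a.scaled(1.10)
        b.sem[:] = 0.12 * b.mean  # 12% combined SD > 10% difference
        diff = difference_map(a, b)
        assert np.all(np.isnan(diff))

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(AnalysisError):
            difference_map(radial_grid(101), radial_grid(51))


def box_grid(doses, vox_mm=1.0):
    n = len(doses)
    mean = np.asarray(doses, float).reshape(n, 1, 1)
    return DoseGrid(np.zeros(3), np.full(3, vox_mm), mean,
                    0.01 * mean, 10, 100)


class TestDVH:
    def test_uniform_dose_saturates(self):
        g = box_grid([20.0] * 50)
        dvh = compute_dvh(g, np.ones(g.dims, dtype=bool), 20.0)
        assert dvh.v100 == 100.0
        assert dvh.d90 == pytest.approx(100.0)
        assert dvh.d100 == pytest.approx(100.0)

    def test_linear_ramp_v100_half(self):
        n = 400
        ramp = np.linspace(0, 40.0, n)  # 0 → 200% of 20 Gy
        g = box_grid(ramp)
        dvh = compute_dvh(g, np.ones(g.dims, dtype=bool), 20.0)
        assert dvh.v100 == pytest.approx(50.0, abs=100.0 / n + 1e-9)

    def test_ramp_dx_against_sort_oracle(self):
        rng = np.random.default_rng(3)
        doses = rng.uniform(0, 50, 1000)
        g = box_grid(doses)
        dvh = compute_dvh(g, np.ones(g.dims, dtype=bool), 20.0)
        pct = np.sort(doses / 20.0 * 100.0)[::-1]
        # D90: minimum dose of the hottest 90% (interpolated percentile)
        assert dvh.d90 == pytest.approx(
            np.percentile(doses / 20.0 * 100.0, 10.0), rel=1e-12)
        assert dvh.v150 == pytest.approx((pct >= 150).mean() * 100.0)

    def test_d2cc_equals_sort_oracle(self):
        rng = np.random.default_rng(4)
        doses = rng.uniform(0, 50, 5000)  # 5000 voxels × 1 mm³
        g = box_grid(doses)
        dvh = compute_dvh(g, np.ones(g.dims, dtype=bool), 20.0,
                          want_d2cc=True)
        pct_sorted = np.sort(doses / 20.0 * 100.0)[::-1]
        n2 = math.ceil(2.0 / 0.001)  # 2 cm³ of 1 mm³ voxels
        assert dvh.d2cc == pytest.approx(pct_sorted[n2 - 1], rel=1e-12)

    def test_v_ordering_invariant(self):
        rng = np.random.default_rng(5)
        g = box_grid(rng.uniform(0, 60, 500))
        dvh = compute_dvh(g, np.ones(g.dims, dtype=bool), 20.0)
        assert dvh.v90 >= dvh.v100 >= dvh.v150 >= dvh.v200
        assert np.all(np.diff(dvh.cum_volume) <= 1e-12)
        assert dvh.cum_volume[0] == 100.0

    def test_small_structure_rejects_d2cc(self):
        g = box_grid([20.0] * 10)
        with pytest.raises(AnalysisError, match="2 cm"):
            compute_dvh(g, np.ones(g.dims, dtype=bool), 20.0,
                        want_d2cc=True)

    def test_empty_mask_rejected(self):
        g = box_grid([20.0] * 10)
        with pytest.raises(AnalysisError):
            compute_dvh(g, np.zeros(g.dims, dtype=bool), 20.0)


class TestPrescriptionNormalization:
    def test_d90_equals_prescription_exactly(self):
        rng = np.random.default_rng(6)
        g = box_grid(rng.uniform(1, 5, 1000))
        mask = np.ones(g.dims, dtype=bool)
        out = normalize_to_prescription(g, mask, 20.0)
        assert np.percentile(out.mean[mask], 10.0) == pytest.approx(
            20.0, rel=1e-12)

    def test_scaling_is_global(self):
        rng = np.random.default_rng(7)
        g = box_grid(rng.uniform(1, 5, 100))
        out = normalize_to_prescription(g, np.ones(g.dims, dtype=bool))
        ratio = out.mean / g.mean
        assert np.allclose(ratio, ratio.flat[0])

    def test_empty_ptv_rejected(self):
        g = box_grid([1.0] * 10)
        with pytest.raises(AnalysisError):
            normalize_to_prescription(g, np.zeros(g.dims, dtype=bool))
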