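"""Acute-angle statistics and the folded-sine isotropic null."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from gliogrowth.angular_alignment import (
    AngleAggregator,
    AngleMap,
    EigenvectorField,
    MaskedVectorField,
    acute_angle,
    aggregate_angles,
    alignment_test,
    angle_histogram,
    angle_map,
    isotropic_density,
    isotropic_p_below,
)
from gliogrowth.synthetic_cohort import FiberPattern, make_fiber_field
from gliogrowth.volume_io import TemplateGrid, Volume


class TestAcuteAngle:
    @pytest.mark.parametrize("v,e,expected", [
        ((2, 0, 0), (1, 0, 0), 0.0),
        ((0, 1, 0), (1, 0, 0), 90.0),
        ((1, 1, 0), (1, 0, 0), 45.0),
        ((1, 1, 0), (-1, 0, 0), 45.0),   # sign fold
        ((-3, -3, 0), (1, 0, 0), 45.0),  # scale + sign invariance
    ])
    def test_examples(self, v, e, expected):
        assert acute_angle(v, e) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            acute_angle((0, 0, 0), (1, 0, 0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(xs=st.lists(st.floats(-5, 5), min_size=6, max_size=6),
           sv=st.sampled_from([1.0, -1.0]), se=st.sampled_from([1.0, -1.0]))
    def test_sign_fold_and_range(self, xs, sv, se):
        v, e = np.array(xs[:3]), np.array(xs[3:])
        if np.linalg.norm(v) < 1e-6 or np.linalg.norm(e) < 1e-6:
            return
        t = acute_angle(v, e)
        assert 0.0 <= t <= 90.0
        assert acute_angle(sv * v, se * e) == pytest.approx(t, abs=1e-6)


class TestIsotropicNull:
    def test_p0_at_20_degrees(self):
        # 1 - cos(20 deg) = 0.0603 to four decimals
        assert isotropic_p_below(20.0) == pytest.approx(0.0603, abs=5e-5)

    @pytest.mark.parametrize("t,expected", [(0.0, 0.0), (60.0, 0.5),
                                            (90.0, 1.0)])
    def test_boundaries(self, t, expected):
        assert isotropic_p_below(t) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        for bad in (-1.0, 90.5):
            with pytest.raises(ValueError):
                isotropic_p_below(bad)
            with pytest.raises(ValueError):
                isotropic_density(bad)

    def test_density_normalization_and_shape(self):
        total, _ = integrate.quad(isotropic_density, 0.0, 90.0)
        assert total == pytest.approx(1.0, abs=1e-6)
        assert isotropic_density(90.0) > isotropic_density(10.0)

    def test_density_cdf_consistency(self):
        for t in (5.0, 20.0, 45.0, 77.0):
            cdf, _ = integrate.quad(isotropic_density, 0.0, t,
                                    epsabs=1e-12, epsrel=1e-12)
            assert cdf == pytest.approx(isotropic_p_below(t), abs=1e-9)


class TestAlignmentTest:
    def test_all_perpendicular_rejects_low(self):
        res = alignment_test(np.full(100, 90.0), 20.0)
        assert res.h == 0.0
        # exact binomial tail oracle: P(X = 0) = (1-p0)^100 bounds the
        # two-sided p-value from below (minlike method adds the other tail)
        p0 = isotropic_p_below(20.0)
        assert (1 - p0) ** 100 <= res.p_value < 0.01

    def test_null_consistent_sample_not_rejected(self):
        p0 = isotropic_p_below(20.0)
        n = 1000
        k = round(n * p0)
        angles = np.concatenate([np.full(k, 10.0), np.full(n - k, 50.0)])
        res = alignment_test(angles, 20.0)
        assert res.n_below == k
        assert res.p_value > 0.5

    def test_monte_carlo_isotropic_matches_p0(self):
        rng = np.random.default_rng(2024)
        v = rng.normal(size=(100_000, 3))
        cos = np.abs(v[:, 0]) / np.linalg.norm(v, axis=1)
        angles = np.degrees(np.arccos(cos))
        res = alignment_test(angles, 20.0)
        assert res.h == pytest.approx(0.0603, abs=0.003)
        assert res.p_value > 0.05

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            alignment_test(np.array([]))

    def test_type_one_error_calibrated(self):
        """Across isotropic replicates the exact test rejects ~ alpha."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps, n = 200, 2000
        for _ in range(reps):
            v = rng.normal(size=(n, 3))
            cos = np.abs(v[:, 0]) / np.linalg.norm(v, axis=1)
            angles = np.degrees(np.arccos(cos))
            if alignment_test(angles, 20.0).p_value < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.08


class TestAngleMap:
    GRID = TemplateGrid.from_origin((12, 12, 12), (1, 1, 1), (0, 0, 0))

    def _growth(self, vectors, valid=None):
        if valid is None:
            valid = np.ones(self.GRID.shape, dtype=bool)
        return MaskedVectorField(self.GRID, vectors, valid)

    def test_parallel_fields_give_zero(self):
        vec = np.zeros(self.GRID.shape + (3,), dtype=np.float32)
        vec[..., 0] = 2.5
        eig = make_fiber_field(self.GRID,
                               FiberPattern("uniform", direction=(1, 0, 0)),
                               seed=0)
        amap = angle_map(self._growth(vec), eig)
        np.testing.assert_allclose(amap.samples(), 0.0, atol=1e-3)

    def test_radial_growth_over_radial_field(self):
        center = (5.5, 5.5, 5.5)
        eig = make_fiber_field(self.GRID, FiberPattern("radial", center=center),
                               seed=1)
        ijk = np.indices(self.GRID.shape).transpose(1, 2, 3, 0).astype(float)
        vec = (ijk - np.array(center)).astype(np.float32)
        amap = angle_map(self._growth(vec), eig)
        assert amap.samples().max() < 5.0

    def test_empty_intersection_gives_empty_map(self):
        vec = np.ones(self.GRID.shape + (3,), dtype=np.float32)
        eig = make_fiber_field(self.GRID,
                               FiberPattern("uniform", direction=(1, 0, 0),
                                            validity_fraction=0.0), seed=0)
        amap = angle_map(self._growth(vec), eig)
        assert amap.samples().size == 0

    def test_sign_fold_invariance_of_h_and_p(self):
        """Negating any subset of eigenvector signs changes nothing."""
        rng = np.random.default_rng(3)
        vec = rng.normal(size=self.GRID.shape + (3,)).astype(np.float32)
        evec = rng.normal(size=self.GRID.shape + (3,)).astype(np.float32)
        valid = np.ones(self.GRID.shape, dtype=bool)
        eig1 = EigenvectorField(self.GRID, evec.copy(), valid.copy())
        flip = rng.random(self.GRID.shape) < 0.5
        evec2 = evec.copy()
        evec2[flip] *= -1.0
        eig2 = EigenvectorField(self.GRID, evec2, valid.copy())
        a1 = angle_map(self._growth(vec.copy()), eig1)
        a2 = angle_map(self._growth(vec.copy()), eig2)
        np.testing.assert_allclose(a1.theta, a2.theta, atol=1e-3)
        r1 = alignment_test(a1.samples())
        r2 = alignment_test(a2.samples())
        assert r1.h == r2.h and r1.p_value == r2.p_value


class TestAggregate:
    GRID = TemplateGrid.from_origin((6, 6, 6), (1, 1, 1), (0, 0, 0))

    def _map(self, value, where):
        theta = np.full(self.GRID.shape, np.nan, dtype=np.float32)
        theta[where] = value
        return AngleMap(self.GRID, theta)

    def _presence(self, where):
        vals = np.zeros(self.GRID.shape, dtype=np.uint8)
        vals[where] = 1
        return Volume(self.GRID, vals, "mask")

    def test_single_patient_identity(self):
        m = self._map(30.0, (slice(0, 3),))
        p = self._presence((slice(0, 3),))
        mean, pooled = aggregate_angles([m], [p], ["allocortex"])
        np.testing.assert_allclose(mean.theta[:3], 30.0)
        assert np.isnan(mean.theta[3:]).all()
        assert pooled["allocortex"].size == 3 * 36

    def test_shared_voxel_arithmetic_mean(self):
        m1 = self._map(10.0, (0, 0, 0))
        m2 = self._map(30.0, (0, 0, 0))
        p = self._presence((0, 0, 0))
        mean, _ = aggregate_angles([m1, m2], [p, p])
        assert mean.theta[0, 0, 0] == pytest.approx(20.0)

    def test_patient_without_presence_contributes_nothing(self):
        m1 = self._map(10.0, (0, 0, 0))
        m2 = self._map(80.0, (0, 0, 0))
        p1 = self._presence((0, 0, 0))
        p2 = self._presence((5, 5, 5))  # presence elsewhere
        mean, _ = aggregate_angles([m1, m2], [p1, p2])
        assert mean.theta[0, 0, 0] == pytest.approx(10.0)

    def test_streaming_matches_batch(self):
        maps = [self._map(v, (0, slice(None), 0)) for v in (10.0, 50.0)]
        pres = [self._presence((0, slice(None), 0))] * 2
        mean_b, pooled_b = aggregate_angles(maps, pres, ["a", "b"])
        agg = AngleAggregator(self.GRID)
        for m, p, r in zip(maps, pres, ["a", "b"]):
            agg.add(m, p, r)
        np.testing.assert_allclose(agg.mean_map().theta[0, :, 0],
                                   mean_b.theta[0, :, 0])
        assert set(agg.region_samples()) == set(pooled_b)


class TestHistogram:
    def test_bin_areas_sum_to_one(self):
        rng = np.random.default_rng(5)
        h = angle_histogram(rng.uniform(0, 90, 5000))
        widths = np.diff(h.edges)
        assert (h.density * widths).sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_value_occupies_one_bin(self):
        h = angle_histogram(np.full(50, 45.0), n_bins=18)
        assert (h.density > 0).sum() == 1
        assert h.mode_bin == (45.0, 50.0)

    def test_isotropic_sample_tracks_analytic_density(self):
        rng = np.random.default_rng(11)
        n = 200_000
        v = rng.normal(size=(n, 3))
        cos = np.abs(v[:, 0]) / np.linalg.norm(v, axis=1)
        h = angle_histogram(np.degrees(np.arccos(cos)), n_bins=18)
        widths = np.diff(h.edges)
        # multinomial SE oracle per bin, on the density scale
        p = h.analytic * widths
        se = np.sqrt(p * (1 - p) / n) / widths
        assert np.all(np.abs(h.density - h.analytic) < 3.5 * se + 1e-4)
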