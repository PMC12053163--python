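"""Fiber-field geometry and controlled tumor growth regimes."""

import numpy as np
import pytest

from gliogrowth.synthetic_cohort import (
    ConfigurationError,
    FiberPattern,
    GrowthRegime,
    grow_tumor,
    make_cohort,
    make_fiber_field,
    patient_seed,
)
from gliogrowth.volume_io import TemplateGrid


class TestFiberField:
    def test_uniform_field_holds_signed_direction(self, small_grid):
        f = make_fiber_field(small_grid,
                             FiberPattern("uniform", direction=(2, 0, 0)),
                             seed=0)
        assert f.valid.all()
        # every voxel holds +-(1,0,0): |x component| == 1
        np.testing.assert_allclose(np.abs(f.vectors[..., 0]), 1.0, atol=1e-6)
        np.testing.assert_allclose(f.vectors[..., 1:], 0.0, atol=1e-6)
        # sign ambiguity actually exercised
        assert (f.vectors[..., 0] > 0).any() and (f.vectors[..., 0] < 0).any()

    def test_radial_field_parallel_to_radius(self, small_grid):
        center = (0.0, 0.0, 0.0)
        f = make_fiber_field(small_grid, FiberPattern("radial", center=center),
                             seed=1)
        rng = np.random.default_rng(2)
        # independent geometric oracle at 100 random voxels
        for _ in range(100):
            ijk = rng.integers(0, 40, size=3)
            if not f.valid[tuple(ijk)]:
                continue
            world = small_grid.voxel_to_world(ijk)
            r = world - np.asarray(center)
            v = f.vectors[tuple(ijk)]
            cross = np.linalg.norm(np.cross(v, r / np.linalg.norm(r)))
            assert cross < 1e-5

    def test_unit_length_at_valid_voxels(self, small_grid):
        for kind, kw in [("concentric", {"center": (0, 0, 0)}),
                         ("crossing", {"direction": (1, 0, 0)})]:
            f = make_fiber_field(small_grid, FiberPattern(kind, **kw), seed=3)
            norms = np.linalg.norm(f.vectors[f.valid], axis=-1)
            np.testing.assert_allclose(norms, 1.0, atol=1e-3)

    def test_zero_validity_fraction_empty(self, small_grid):
        f = make_fiber_field(
            small_grid,
            FiberPattern("uniform", direction=(1, 0, 0), validity_fraction=0.0),
            seed=0)
        assert not f.valid.any()

    def test_zero_direction_rejected(self):
        with pytest.raises(ConfigurationError):
            FiberPattern("uniform", direction=(0, 0, 0))


class TestGrowTumor:
    @pytest.fixture
    def uniform_field(self, small_grid):
        return make_fiber_field(small_grid,
                                FiberPattern("uniform", direction=(1, 0, 0)),
                                seed=0)

    def test_output_superset_and_strict_growth(self, small_grid, uniform_field,
                                               ball_factory):
        seed_mask = ball_factory(small_grid, (20, 20, 20), 4)
        out = grow_tumor(seed_mask, uniform_field,
                         GrowthRegime("isotropic", magnitude=0.5, steps=10),
                         seed=1)
        assert np.all(out.values >= seed_mask.values)
        assert out.values.sum() > seed_mask.values.sum()

    def test_zero_steps_identity(self, small_grid, uniform_field, ball_factory):
        seed_mask = ball_factory(small_grid, (20, 20, 20), 4)
        out = grow_tumor(seed_mask, uniform_field,
                         GrowthRegime("isotropic", steps=0), seed=1)
        np.testing.assert_array_equal(out.values, seed_mask.values)

    def test_deterministic_given_seed(self, small_grid, uniform_field,
                                      ball_factory):
        seed_mask = ball_factory(small_grid, (20, 20, 20), 4)
        regime = GrowthRegime("along_fiber", magnitude=0.4, steps=8)
        a = grow_tumor(seed_mask, uniform_field, regime, seed=7)
        b = grow_tumor(seed_mask, uniform_field, regime, seed=7)
        np.testing.assert_array_equal(a.values, b.values)

    def test_isotropic_growth_stays_spherical(self, uniform_field, ball_factory,
                                              small_grid):
        # moment-of-inertia oracle: principal radii of the grown mask
        seed_mask = ball_factory(small_grid, (20, 20, 20), 3)
        out = grow_tumor(seed_mask, uniform_field,
                         GrowthRegime("isotropic", magnitude=0.4, steps=25,
                                      noise_deg=0.0), seed=3)
        idx = np.argwhere(out.values > 0).astype(float)
        idx -= idx.mean(axis=0)
        radii = np.sqrt(np.linalg.eigvalsh(idx.T @ idx / len(idx)))
        assert radii[2] / radii[0] < 1.2

    def test_along_fiber_elongates_along_fiber(self, uniform_field,
                                               ball_factory, small_grid):
        # principal-axis oracle: longest axis of the grown mask vs the fiber
        seed_mask = ball_factory(small_grid, (20, 20, 20), 3)
        out = grow_tumor(seed_mask, uniform_field,
                         GrowthRegime("along_fiber", magnitude=0.4, steps=25),
                         seed=4)
        idx = np.argwhere(out.values > 0).astype(float)
        idx -= idx.mean(axis=0)
        _, vecs = np.linalg.eigh(idx.T @ idx / len(idx))
        angle = np.degrees(np.arccos(abs(vecs[0, -1])))
        assert angle < 15.0

    def test_toward_target_moves_centroid_toward_target(self, uniform_field,
                                                        ball_factory,
                                                        small_grid):
        seed_mask = ball_factory(small_grid, (20, 20, 20), 3)
        target = (15.0, 0.0, 0.0)  # world mm, +x of the seed
        out = grow_tumor(seed_mask, uniform_field,
                         GrowthRegime("toward_target", magnitude=0.5, steps=15,
                                      target=target), seed=5)
        c0 = small_grid.voxel_to_world(
            np.argwhere(seed_mask.values).mean(axis=0))
        c1 = small_grid.voxel_to_world(np.argwhere(out.values).mean(axis=0))
        assert c1[0] > c0[0] + 1.0

    def test_empty_seed_rejected(self, small_grid, uniform_field):
        from gliogrowth.volume_io import Volume
        empty = Volume(small_grid, np.zeros(small_grid.shape, np.uint8), "mask")
        with pytest.raises(ValueError):
            grow_tumor(empty, uniform_field, GrowthRegime("isotropic"), seed=0)


class TestMakeCohort:
    # must contain every default region box plus room for ball seeds + growth
    GRID = TemplateGrid.from_origin((72, 88, 104), (1, 1, 1),
                                    (-52.0, -36.0, -40.0))
    REGIMES = {r: GrowthRegime("isotropic", magnitude=0.4)
               for r in ("allocortex", "mesocortex", "isocortex")}

    def test_counts_and_manifest(self, tmp_path):
        pats, manifest = make_cohort(2, self.REGIMES, self.GRID, seed=0,
                                     steps_range=(4, 8), out_dir=tmp_path)
        assert len(pats) == 6
        assert len(manifest) == 6
        assert len(list(tmp_path.glob("*_t*.nii.gz"))) == 12
        assert (tmp_path / "manifest.csv").exists()

    def test_determinism_same_seed(self):
        a, _ = make_cohort(1, self.REGIMES, self.GRID, seed=9,
                           steps_range=(4, 6))
        b, _ = make_cohort(1, self.REGIMES, self.GRID, seed=9,
                           steps_range=(4, 6))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.mask_t2.values, pb.mask_t2.values)
            assert pa.interval_days == pb.interval_days

    def test_growth_containment_and_interval_floor(self):
        pats, _ = make_cohort(2, self.REGIMES, self.GRID, seed=1,
                              steps_range=(4, 8))
        for p in pats:
            assert np.all(p.mask_t2.values >= p.mask_t1.values)
            assert p.mask_t2.values.sum() > p.mask_t1.values.sum()
            assert p.interval_days >= 14

    def test_seed_splitting_is_stable(self):
        assert patient_seed(0, 1) == patient_seed(0, 1)
        assert patient_seed(0, 1) != patient_seed(0, 2)
        assert 0 <= patient_seed(123, 45) < 2 ** 31

    def test_overlapping_region_boxes_rejected(self):
        boxes = {"a": ((0, 10), (0, 10), (0, 10)),
                 "b": ((5, 15), (0, 10), (0, 10))}
        regimes = {"a": GrowthRegime("isotropic"),
                   "b": GrowthRegime("isotropic")}
        with pytest.raises(ConfigurationError):
            make_cohort(1, regimes, self.GRID, seed=0, region_boxes=boxes)
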