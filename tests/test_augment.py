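"""Wrapped-phase augmentation: grid, transform cascade, sampling, splitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from holoplankton import (
    WQPI,
    apply_transform,
    build_grid,
    sample_plan,
    generate_dataset,
    split_train_val,
    wrap_phase,
)
from holoplankton.augment import AugmentationGrid, phase_to_uint8, uint8_to_phase


class TestWrapPhase:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, 0.0), (np.pi, -np.pi), (2.5 * np.pi, 0.5 * np.pi),
         (-np.pi, -np.pi), (-1.5 * np.pi, 0.5 * np.pi)],
    )
    def test_reference_values(self, value, expected):
        assert wrap_phase(value) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=200)
    @given(st.floats(min_value=-1e6, max_value=1e6))
    def test_output_in_principal_interval(self, v):
        w = wrap_phase(v)
        assert -np.pi <= w < np.pi

    @settings(deadline=None, max_examples=100)
    @given(st.floats(min_value=-100.0, max_value=100.0))
    def test_wrap_is_modular(self, v):
        assert wrap_phase(v + 2 * np.pi) == pytest.approx(wrap_phase(v), abs=1e-9)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            wrap_phase(np.array([0.0, np.nan]))


class TestBuildGrid:
    def test_default_dimensions_and_cardinality(self):
        grid = build_grid()
        assert grid.dims == (21, 21, 36, 11)
        assert grid.cardinality == 174_636
        assert grid.scales_x[0] == pytest.approx(-0.20)
        assert grid.scales_x[-1] == pytest.approx(0.20)
        assert grid.scales_x[1] - grid.scales_x[0] == pytest.approx(0.02)
        assert list(grid.angles_deg) == list(range(0, 360, 10))
        assert grid.biases_rad[0] == 0.0
        assert grid.biases_rad[-1] == pytest.approx(np.pi)

    def test_single_point_grid(self):
        grid = AugmentationGrid((0.0,), (0.0,), (0.0,), (0.0,))
        assert grid.cardinality == 1
        assert grid.tuple_at(0) == (0.0, 0.0, 0.0, 0.0)

    def test_empty_dimension_raises(self):
        with pytest.raises(ValueError, match="empty"):
            AugmentationGrid((), (0.0,), (0.0,), (0.0,))

    @settings(deadline=None, max_examples=30)
    @given(st.tuples(*[st.integers(min_value=1, max_value=7)] * 4))
    def test_cardinality_is_product_of_lengths(self, lens):
        a, b, c, d = lens
        grid = AugmentationGrid(
            tuple(np.linspace(-0.1, 0.1, a)),
            tuple(np.linspace(-0.1, 0.1, b)),
            tuple(np.linspace(0, 350, c)),
            tuple(np.linspace(0, np.pi, d)),
        )
        assert grid.cardinality == a * b * c * d

    def test_random_biases_mode_deterministic(self):
        g1 = build_grid(random_biases=True, seed=3)
        g2 = build_grid(random_biases=True, seed=3)
        assert g1.biases_rad == g2.biases_rad
        assert all(0.0 <= b <= np.pi for b in g1.biases_rad)


def disc_generator(radius=10, value=1.0, size=32, class_id=1):
    yy, xx = np.mgrid[:size, :size].astype(float)
    mask = (yy - size / 2) ** 2 + (xx - size / 2) ** 2 <= radius**2
    return WQPI(np.where(mask, value, 0.0), class_id=class_id)


class TestApplyTransform:
    def test_identity_parameters_preserve_input(self):
        gen = disc_generator()
        out = apply_transform(gen, 0.0, 0.0, 0.0, 0.0, out_shape=(48, 48))
        # locate the placed support and compare exactly against the original
        sup = np.abs(out.phase) > 0
        rows = np.nonzero(sup.any(axis=1))[0]
        cols = np.nonzero(sup.any(axis=0))[0]
        placed = out.phase[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
        gsup = np.abs(gen.phase) > 0
        grows = np.nonzero(gsup.any(axis=1))[0]
        gcols = np.nonzero(gsup.any(axis=0))[0]
        orig = gen.phase[grows[0] : grows[-1] + 1, gcols[0] : gcols[-1] + 1]
        np.testing.assert_array_equal(placed, orig)

    def test_bias_shifts_disc_value(self):
        c, b = 1.0, 2.8  # c + b > pi, so the result must wrap
        gen = disc_generator(value=c)
        out = apply_transform(gen, 0.0, 0.0, 0.0, b, out_shape=(48, 48))
        center = out.phase[24, 24]
        assert center == pytest.approx(wrap_phase(c + b), abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_output_always_in_principal_interval(self, seed):
        rng = np.random.default_rng(seed)
        gen = disc_generator(value=rng.uniform(-np.pi, np.pi))
        out = apply_transform(
            gen,
            rng.uniform(-0.2, 0.2),
            rng.uniform(-0.2, 0.2),
            rng.uniform(0, 360),
            rng.uniform(0, np.pi),
            out_shape=(64, 64),
        )
        assert out.phase.min() >= -np.pi
        assert out.phase.max() < np.pi

    def test_double_180_rotation_close_to_identity(self):
        rng = np.random.default_rng(1)
        size = 40
        yy, xx = np.mgrid[:size, :size].astype(float)
        mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= 14**2
        phase = np.where(mask, wrap_phase(rng.uniform(-3, 3, (size, size))), 0.0)
        # smooth it a little so interpolation error is the only discrepancy
        from scipy import ndimage

        phase = np.where(mask, ndimage.gaussian_filter(phase, 1.5), 0.0)
        gen = WQPI(phase)
        once = apply_transform(gen, 0.0, 0.0, 180.0, 0.0, out_shape=(64, 64))
        twice = apply_transform(once, 0.0, 0.0, 180.0, 0.0, out_shape=(64, 64))
        ref = apply_transform(gen, 0.0, 0.0, 0.0, 0.0, out_shape=(64, 64))
        sup = np.abs(ref.phase) > 0
        diff = np.abs(wrap_phase(twice.phase - ref.phase))[sup]
        assert diff.mean() < 0.02

    def test_object_larger_than_canvas_raises(self):
        gen = disc_generator(radius=14, size=32)
        with pytest.raises(ValueError, match="exceeds"):
            apply_transform(gen, 0.2, 0.2, 45.0, 0.0, out_shape=(24, 24))

    def test_insane_scale_raises(self):
        gen = disc_generator()
        with pytest.raises(ValueError, match="sane range"):
            apply_transform(gen, 1.5, 0.0, 0.0, 0.0, out_shape=(64, 64))

    def test_scaling_changes_support_area(self):
        gen = disc_generator(radius=10)
        small = apply_transform(gen, -0.2, -0.2, 0.0, 0.0, out_shape=(64, 64))
        large = apply_transform(gen, 0.2, 0.2, 0.0, 0.0, out_shape=(64, 64))
        a_small = (np.abs(small.phase) > 0.5).sum()
        a_large = (np.abs(large.phase) > 0.5).sum()
        assert a_small < (np.abs(gen.phase) > 0.5).sum() < a_large


class TestSamplePlan:
    def test_counts_and_determinism(self):
        grid = build_grid(n_scales=3, angle_step_deg=90.0, n_biases=2)
        plan1 = sample_plan([1, 2, 3], grid, per_class=10, seed=0)
        plan2 = sample_plan([1, 2, 3], grid, per_class=10, seed=0)
        pd.testing.assert_frame_equal(plan1, plan2)
        assert plan1.groupby("class_id").size().eq(10).all()

    def test_sampling_without_replacement(self):
        grid = build_grid(n_scales=2, angle_step_deg=90.0, n_biases=2)  # 2*2*4*2=32
        plan = sample_plan([7], grid, per_class=32, seed=1)
        assert plan["tuple_index"].is_unique

    def test_per_class_exceeding_cardinality_raises(self):
        grid = AugmentationGrid((0.0,), (0.0,), (0.0,), (0.0,))
        with pytest.raises(ValueError, match="cardinality"):
            sample_plan([1], grid, per_class=2, seed=0)

    def test_one_point_grid_gives_one_image_per_class(self):
        grid = AugmentationGrid((0.0,), (0.0,), (0.0,), (0.0,))
        gens = [disc_generator(class_id=k) for k in (1, 2)]
        manifest, images = generate_dataset(gens, grid, per_class=1, seed=0,
                                            out_shape=(48, 48))
        assert len(manifest) == 2
        assert images.shape == (2, 48, 48)

    def test_parameters_match_tuple_indices(self):
        grid = build_grid()
        plan = sample_plan([1], grid, per_class=50, seed=5)
        for row in plan.itertuples():
            assert grid.tuple_at(row.tuple_index) == (
                row.scale_x, row.scale_y, row.angle_deg, row.bias_rad
            )


class TestSplitTrainVal:
    def test_eighty_twenty_on_ten_per_class(self):
        manifest = pd.DataFrame(
            {"class_id": np.repeat([1, 2, 3], 10), "tuple_index": range(30)}
        )
        train, val = split_train_val(manifest, 0.8, seed=0)
        assert train.groupby("class_id").size().eq(8).all()
        assert val.groupby("class_id").size().eq(2).all()

    def test_partition_property(self):
        manifest = pd.DataFrame(
            {"class_id": np.repeat([1, 2], 25), "tuple_index": range(50)}
        )
        train, val = split_train_val(manifest, 0.7, seed=1)
        merged = pd.concat([train, val]).sort_index()
        pd.testing.assert_frame_equal(merged, manifest)
        assert set(train.index).isdisjoint(set(val.index))

    def test_paper_scale_arithmetic(self):
        """A 21,000-per-class plan at 80/20 gives 16,800/4,200 exactly."""
        manifest = pd.DataFrame(
            {"class_id": np.repeat([1, 2], 21_000), "tuple_index": range(42_000)}
        )
        train, val = split_train_val(manifest, 0.8, seed=2)
        assert train.groupby("class_id").size().eq(16_800).all()
        assert val.groupby("class_id").size().eq(4_200).all()

    def test_empty_side_raises(self):
        manifest = pd.DataFrame({"class_id": [1, 1], "tuple_index": [0, 1]})
        with pytest.raises(ValueError, match="empty"):
            split_train_val(manifest, 0.01, seed=0)

    def test_bad_fraction_raises(self):
        manifest = pd.DataFrame({"class_id": [1] * 10, "tuple_index": range(10)})
        with pytest.raises(ValueError):
            split_train_val(manifest, 1.0, seed=0)


class TestGenerateDataset:
    def test_manifest_counts_and_wrap_closure(self):
        grid = build_grid(n_scales=3, angle_step_deg=45.0, n_biases=3)
        gens = [disc_generator(class_id=k, value=0.5 * k) for k in (1, 2, 3)]
        manifest, images = generate_dataset(gens, grid, per_class=12, seed=3,
                                            out_shape=(48, 48))
        assert len(manifest) == 36
        assert manifest.groupby("class_id").size().eq(12).all()
        assert images.min() >= -np.pi and images.max() < np.pi

    def test_same_seed_identical_manifests(self):
        grid = build_grid(n_scales=3, angle_step_deg=90.0, n_biases=2)
        gens = [disc_generator(class_id=1)]
        m1, im1 = generate_dataset(gens, grid, per_class=8, seed=9, out_shape=(48, 48))
        m2, im2 = generate_dataset(gens, grid, per_class=8, seed=9, out_shape=(48, 48))
        pd.testing.assert_frame_equal(m1, m2)
        np.testing.assert_array_equal(im1, im2)

    def test_png_export_roundtrip(self, tmp_path):
        grid = AugmentationGrid((0.0,), (0.0,), (0.0,), (0.5,))
        gens = [disc_generator(class_id=1)]
        manifest, paths = generate_dataset(
            gens, grid, per_class=1, seed=0, out_dir=tmp_path, out_shape=(48, 48)
        )
        assert (tmp_path / "manifest.csv").exists()
        import imageio.v3 as iio

        gray = iio.imread(paths[0])
        restored = uint8_to_phase(gray)
        direct = apply_transform(gens[0], 0, 0, 0, 0.5, out_shape=(48, 48)).phase
        assert np.abs(restored - direct).max() <= np.pi / 255 + 1e-9

    def test_uint8_mapping_is_monotone_inverse(self):
        phase = np.linspace(-np.pi, np.pi - 1e-6, 100).reshape(10, 10)
        g = phase_to_uint8(phase)
        assert g.min() == 0 and g.max() == 255
        assert np.abs(uint8_to_phase(g) - phase).max() <= np.pi / 255 + 1e-9
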