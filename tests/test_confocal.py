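"""Apical-contour detection, mask construction and localization scoring."""

import numpy as np
import pytest
from scipy import ndimage

from epibarrier.confocal import (
    BACKGROUND,
    ConfocalStack,
    batch_localization,
    build_masks,
    detect_apical_contour,
    estimate_cell_height,
    measure_localization,
    smooth_lateral,
)
from epibarrier.synthetic import (
    StackSpec,
    flat_surface,
    generate_confocal_stack,
    step_surface,
)


class TestSmoothing:
    def test_slicewise_constant_is_invariant(self):
        stack = np.arange(5, dtype=float)[:, None, None] * np.ones((5, 20, 20))
        np.testing.assert_allclose(smooth_lateral(stack, 10), stack, rtol=1e-12)

    def test_matches_direct_convolution(self, rng):
        """gaussian smoothing equals direct convolution with its own kernel."""
        img = rng.uniform(0, 100, (1, 31, 31))
        width, sigma = 10, 2.5
        delta = np.zeros((31, 31))
        delta[15, 15] = 1.0
        kernel = ndimage.gaussian_filter(delta, sigma, truncate=width / (2 * sigma))
        assert kernel.sum() == pytest.approx(1.0, abs=1e-12)  # unit mass
        direct = ndimage.convolve(img[0], kernel, mode="reflect")
        np.testing.assert_allclose(smooth_lateral(img, width)[0], direct, atol=1e-9)

    def test_no_smoothing_along_z(self, rng):
        stack = rng.uniform(0, 10, (6, 24, 24))
        sm = smooth_lateral(stack, 10)
        for z in range(6):
            np.testing.assert_allclose(sm[z], smooth_lateral(stack[z : z + 1], 10)[0])

    def test_width_larger_than_slice_rejected(self):
        with pytest.raises(ValueError, match="width"):
            smooth_lateral(np.ones((3, 4, 4)), 10)


class TestContour:
    def test_first_crossing_oracle(self):
        """Column [0,0,10,10] at 30%: first value strictly above 3 is z=2."""
        col = np.array([0.0, 0.0, 10.0, 10.0])
        channel = np.stack([col, col], axis=1)[:, :, None]  # (4, 2, 1)
        contour = detect_apical_contour(channel, 0.3)
        # brute-force oracle
        expected = min(z for z in range(4) if col[z] > 0.3 * col.max())
        assert (contour == expected).all()

    def test_zero_column_is_background(self):
        channel = np.zeros((4, 1, 2))
        channel[2:, 0, 0] = 10.0
        contour = detect_apical_contour(channel, 0.3)
        assert contour[0, 0] == 2
        assert contour[0, 1] == BACKGROUND

    def test_all_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            detect_apical_contour(np.zeros((4, 2, 2)), 0.3)

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1])
    def test_threshold_range_validated(self, frac):
        with pytest.raises(ValueError, match="threshold"):
            detect_apical_contour(np.ones((2, 2, 2)), frac)

    def test_noiseless_step_profile_exact(self):
        spec = StackSpec(
            nx=48, ny=48, surface_um=step_surface(48, 48), noise_sd=0.0
        )
        stack, truth = generate_confocal_stack(spec)
        contour = detect_apical_contour(smooth_lateral(stack.membrane), 0.3)
        # exact away from the step edge where lateral smoothing mixes columns
        interior = np.ones((48, 48), dtype=bool)
        interior[:, 24 - 6 : 24 + 6] = False
        np.testing.assert_array_equal(contour[interior], truth.contour[interior])

    def test_noisy_contour_within_one_voxel(self):
        spec = StackSpec(nx=64, ny=64, noise_sd=20.0, seed=3)  # 10% of stain peak
        stack, truth = generate_confocal_stack(spec)
        contour = detect_apical_contour(smooth_lateral(stack.membrane), 0.3)
        assert (np.abs(contour - truth.contour) <= 1).mean() >= 0.99


class TestMasks:
    def test_index_arithmetic(self):
        contour = np.full((1, 1), 5)
        masks = build_masks(contour, (40, 1, 1), stripe_width=12)
        mem_z = np.nonzero(masks.membrane_mask[:, 0, 0])[0]
        cyt_z = np.nonzero(masks.cytoplasm_mask[:, 0, 0])[0]
        assert mem_z.tolist() == list(range(5, 17))
        assert cyt_z.tolist() == list(range(17, 40))

    def test_contour_at_bottom_flags_degenerate_column(self):
        contour = np.full((1, 1), 39)
        masks = build_masks(contour, (40, 1, 1), stripe_width=12)
        assert masks.membrane_mask.sum() == 1
        assert masks.cytoplasm_mask.sum() == 0
        assert masks.degenerate_columns[0, 0]

    def test_partition_invariant(self, noisy_stack_suite):
        """membrane + cytoplasm + above-contour + background tile the grid."""
        for stack, truth in noisy_stack_suite:
            nz = stack.shape[0]
            z = np.arange(nz)[:, None, None]
            above = (~truth.background_columns)[None] & (z < truth.contour[None])
            bg = np.broadcast_to(truth.background_columns[None], stack.shape)
            parts = [truth.membrane_mask, truth.cytoplasm_mask, above, bg]
            total = np.zeros(stack.shape, dtype=int)
            for p in parts:
                total += p
            assert (total == 1).all()  # exhaustive and pairwise disjoint

    def test_partition_with_background_columns(self):
        contour = np.array([[2, BACKGROUND], [0, 5]])
        masks = build_masks(contour, (8, 2, 2), stripe_width=3)
        assert not masks.membrane_mask[:, 0, 1].any()
        assert not masks.cytoplasm_mask[:, 0, 1].any()
        assert masks.background_columns[0, 1]
        assert masks.membrane_mask[:, 1, 0].sum() == 3


class TestLocalization:
    def test_uniform_target_gives_ratio_one(self):
        masks = build_masks(np.full((4, 4), 2), (20, 4, 4), 5)
        score = measure_localization(np.full((20, 4, 4), 7.0), masks)
        assert score.ratio == 1.0

    def test_enrichment_two_recovered_exactly_noise_free(self, flat_stack_rho2):
        stack, truth = flat_stack_rho2
        score = measure_localization(stack.target, truth)
        assert score.ratio == pytest.approx(2.0, abs=1e-12)

    def test_ratio_invariant_to_intensity_scaling(self, flat_stack_rho2):
        stack, truth = flat_stack_rho2
        s1 = measure_localization(stack.target, truth)
        s2 = measure_localization(stack.target * 37.5, truth)
        assert s2.ratio == pytest.approx(s1.ratio, rel=1e-12)
        assert s2.membrane_mean == pytest.approx(37.5 * s1.membrane_mean, rel=1e-12)

    @pytest.mark.parametrize("rho", [0.5, 1.0, 1.5, 2.0, 3.0])
    def test_ratio_recovery_under_default_noise(self, rho):
        spec = StackSpec(nx=48, ny=48, enrichment=rho, seed=11)
        stack, _ = generate_confocal_stack(spec)
        contour = detect_apical_contour(smooth_lateral(stack.membrane), 0.3)
        masks = build_masks(contour, stack.shape, 12)
        score = measure_localization(stack.target, masks)
        assert score.ratio == pytest.approx(rho, rel=0.05)

    def test_empty_cytoplasm_rejected_with_diagnostic(self):
        masks = build_masks(np.full((2, 2), 35), (40, 2, 2), 12)
        with pytest.raises(ValueError, match="cytoplasm mask is empty"):
            measure_localization(np.ones((40, 2, 2)), masks)


class TestCellHeight:
    def test_flat_contour_arithmetic(self):
        contour = np.full((3, 3), 5)
        assert estimate_cell_height(contour, 0.2, basal_z=45) == pytest.approx(8.0)

    def test_contour_at_basal_plane_is_zero(self):
        assert estimate_cell_height(np.full((2, 2), 10), 0.2, basal_z=10) == 0.0

    def test_basal_above_contour_rejected(self):
        with pytest.raises(ValueError, match="basal"):
            estimate_cell_height(np.full((2, 2), 10), 0.2, basal_z=5)

    def test_generator_round_trip_within_one_voxel(self):
        spec = StackSpec(nx=48, ny=48, noise_sd=10.0, seed=4)
        stack, truth = generate_confocal_stack(spec)
        contour = detect_apical_contour(smooth_lateral(stack.membrane), 0.3)
        est = estimate_cell_height(contour, spec.axial_um, basal_z=spec.nz - 1)
        true = estimate_cell_height(truth.contour, spec.axial_um, basal_z=spec.nz - 1)
        assert abs(est - true) <= spec.axial_um


class TestBatch:
    @staticmethod
    def _stack(rho, group, label):
        spec = StackSpec(
            nx=24, ny=24, surface_um=flat_surface(24, 24, 1.0),
            enrichment=rho, noise_sd=0.0,
        )
        stack, _ = generate_confocal_stack(spec)
        return ConfocalStack(
            membrane=stack.membrane, target=stack.target,
            lateral_um=stack.lateral_um, axial_um=stack.axial_um,
            label=label, group=group,
        )

    def test_single_stack_group_equals_stack_score(self):
        per_stack, agg = batch_localization([self._stack(2.0, "wt", "s1")])
        assert agg.loc["wt", ("ratio", "mean")] == pytest.approx(
            per_stack["ratio"].iloc[0]
        )

    def test_two_stack_mean(self):
        stacks = [self._stack(1.0, "g", "a"), self._stack(3.0, "g", "b")]
        _, agg = batch_localization(stacks)
        assert agg.loc["g", ("ratio", "mean")] == pytest.approx(2.0, rel=1e-6)

    def test_mixed_voxel_sizes_warn(self):
        s1 = self._stack(2.0, "g", "a")
        s2 = ConfocalStack(
            membrane=s1.membrane, target=s1.target, lateral_um=0.4,
            axial_um=0.2, group="g", label="b",
        )
        with pytest.warns(RuntimeWarning, match="voxel"):
            batch_localization([s1, s2])
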