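"""Image-conditioning contracts: background subtraction, segmentation,
trace extraction, Wiener denoising, deformable registration and QC, and
the Otsu union mask."""

import numpy as np
import pytest

from retscope import imgproc, synthgen
from retscope.imgproc import (
    FrameStack,
    RegistrationResult,
    otsu_union_mask,
    qc_registration,
    register_deformable,
    segment_mitochondria,
    subtract_background,
    wiener_denoise,
)
from retscope.synthgen import SceneConfig, build_scene, render_frames


def _stack(frames, channel="nadph", labels=None):
    frames = np.asarray(frames, dtype=float)
    labels = labels or tuple(f"c{i}" for i in range(frames.shape[0]))
    return FrameStack(frames=frames, channel=channel, condition_labels=labels)


class TestSubtractBackground:
    def test_flat_frame_goes_to_zero(self):
        out = subtract_background(_stack(np.full((1, 64, 64), 37.0)))
        assert np.all(out.frames == 0)

    def test_noiseless_scene_background_exact(self, noiseless_nadph_stack):
        out = subtract_background(noiseless_nadph_stack)
        # off-spot pixels must be exactly zero after subtracting the true level
        corner = out.frames[:, :4, :4]
        assert np.allclose(corner, 0.0, atol=1e-9)

    def test_noisy_background_recovered(self):
        """Estimates stay close to the true level and agree across frames.

        Selecting pixels below a percentile of the max projection
        conditions each frame's noise downward, a known property of the
        method: about -0.5 sigma at two frames and the median percentile.
        The estimate must stay within 0.6 sigma of truth, and the bias
        must be common to all frames (so intensity ratios are unaffected)."""
        per_frame = {0: [], 1: []}
        for seed in range(10):
            cfg = SceneConfig(
                image_shape=(96, 96), n_mito=10, read_noise_sigma=5.0,
                photon_gain=0.0, seed=seed,
            )
            stack = render_frames(build_scene(cfg), ("a", "b"), "nadph")
            out = subtract_background(stack)
            # original - subtracted equals the scalar estimate wherever the
            # pixel was not floored at zero; the max over a region is exact
            for t in (0, 1):
                per_frame[t].append(
                    (stack.frames[t][:16, :16] - out.frames[t][:16, :16]).max()
                )
        for t in (0, 1):
            assert abs(np.mean(per_frame[t]) - 100.0) < 0.6 * 5.0
        assert abs(np.mean(per_frame[0]) - np.mean(per_frame[1])) < 0.5

    def test_percentile_validated(self, noiseless_nadph_stack):
        with pytest.raises(ValueError):
            subtract_background(noiseless_nadph_stack, percentile=0.0)


class TestSegmentation:
    def test_noiseless_counts_and_centroids(self, noiseless_scene):
        stack = render_frames(noiseless_scene, ("a",), "nadph")
        sub = subtract_background(stack)
        rois = segment_mitochondria(sub.frames[0])
        assert len(rois) == len(noiseless_scene.mitochondria)
        truth = np.array([m.centroid for m in noiseless_scene.mitochondria])
        for c in rois.centroids:
            assert np.min(np.sqrt(((truth - c) ** 2).sum(1))) < 0.5

    def test_empty_field_yields_no_rois(self):
        assert len(segment_mitochondria(np.zeros((64, 64)))) == 0

    def test_recall_precision_at_high_snr(self):
        """Recall and precision >= 0.95 over 10 seeded scenes at SNR >= 10."""
        tp = fp = fn = 0
        for seed in range(10):
            cfg = SceneConfig(
                image_shape=(128, 128), n_mito=40, read_noise_sigma=10.0,
                photon_gain=0.5, nadph_baseline_mean=300.0, seed=100 + seed,
            )
            scene = build_scene(cfg)
            stack = render_frames(scene, ("a",), "nadph")
            sub = subtract_background(stack)
            rois = segment_mitochondria(sub.frames[0])
            truth = np.array([m.centroid for m in scene.mitochondria])
            found = np.zeros(len(truth), dtype=bool)
            for c in rois.centroids:
                d = np.sqrt(((truth - c) ** 2).sum(1))
                j = int(np.argmin(d))
                if d[j] < 3.0 and not found[j]:
                    found[j] = True
                    tp += 1
                else:
                    fp += 1
            fn += int((~found).sum())
        assert tp / (tp + fn) >= 0.95  # recall
        assert tp / (tp + fp) >= 0.95  # precision


class TestExtractTraces:
    def test_constant_frame_gives_constant_trace(self):
        frame = np.full((32, 32), 5.0)
        frame[10:13, 10:13] = 50.0  # a spot so segmentation finds one ROI
        rois = segment_mitochondria(frame)
        stack = _stack(np.stack([np.full((32, 32), 7.0)] * 2))
        traces = imgproc.extract_traces(stack, rois)
        assert np.allclose(traces[["c0", "c1"]].to_numpy(), 7.0)

    def test_single_pixel_roi_returns_pixel_value(self):
        from retscope.imgproc import ROISet

        rois = ROISet(
            label_image=np.zeros((8, 8), dtype=np.int32),
            pixel_indices=[(np.array([3]), np.array([4]))],
            areas=np.array([1]),
            centroids=np.array([[3.0, 4.0]]),
        )
        frames = np.arange(64, dtype=float).reshape(1, 8, 8)
        traces = imgproc.extract_traces(_stack(frames), rois)
        assert traces["c0"].iloc[0] == frames[0, 3, 4]

    def test_shape_mismatch_rejected(self, noiseless_nadph_stack):
        rois = segment_mitochondria(np.zeros((16, 16)))
        with pytest.raises(ValueError, match="shape"):
            imgproc.extract_traces(noiseless_nadph_stack, rois)


class TestWiener:
    def test_constant_frame_unchanged(self):
        f = np.full((32, 32), 11.0)
        np.testing.assert_allclose(wiener_denoise(f), f)

    def test_reduces_white_noise_variance(self):
        rng = np.random.default_rng(0)
        f = rng.normal(100.0, 10.0, (128, 128))
        out = wiener_denoise(f)
        assert out.std() < 10.0

    def test_preserves_mean_within_tolerance(self):
        rng = np.random.default_rng(1)
        f = rng.normal(100.0, 10.0, (128, 128))
        out = wiener_denoise(f)
        assert abs(out.mean() - f.mean()) / f.mean() < 1e-3

    def test_edge_bias_bounded_by_blur(self):
        """On a noiseless step edge the filter bias cannot exceed the
        bias of plain local-mean smoothing with the same kernel."""
        from scipy.ndimage import uniform_filter

        f = np.zeros((64, 64))
        f[:, 32:] = 100.0
        out = wiener_denoise(f, 3)
        blur_bound = np.abs(uniform_filter(f, 3) - f).max()
        assert np.abs(out - f).max() <= blur_bound + 1e-9

    def test_kernel_validation(self):
        with pytest.raises(ValueError):
            wiener_denoise(np.zeros((8, 8)), kernel_px=4)


class TestRegistration:
    def test_identical_frames_identity_field(self, noiseless_nadph_stack):
        f = noiseless_nadph_stack.frames[0]
        res = register_deformable(f, f)
        assert res.pearson_after == pytest.approx(1.0)
        assert np.abs(res.displacement_field).max() < 1e-6
        assert res.accepted

    def test_recovers_synthetic_warp(self):
        cfg = SceneConfig(image_shape=(128, 128), n_mito=40, seed=11)
        scene = build_scene(cfg)
        stack = render_frames(scene, ("a", "b"), "nadph")
        warped = synthgen.apply_motility(stack, 2.0, 50.0, seed=3)
        fixed = stack.frames[1]
        res = register_deformable(fixed, warped.frames[1])
        assert res.pearson_after > res.pearson_before
        true_field = warped.motility_fields[1]
        resid = res.displacement_field + true_field  # recovery is the inverse
        fg = fixed > np.percentile(fixed, 90)
        rms = np.sqrt((resid**2).sum(-1)[fg].mean())
        assert rms < 1.0

    def test_pure_noise_pair_rejected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(100, 10, (96, 96))
        b = rng.normal(100, 10, (96, 96))
        res = register_deformable(a, b)
        assert not res.accepted

    def test_never_degrades_pearson(self):
        rng = np.random.default_rng(2)
        a = rng.normal(100, 10, (64, 64))
        b = 0.5 * a + rng.normal(0, 5, (64, 64))
        res = register_deformable(a, b)
        assert res.pearson_after >= res.pearson_before - 1e-12

    def test_nonfinite_rejected(self):
        a = np.zeros((32, 32))
        a[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            register_deformable(a, np.zeros((32, 32)))


class TestQC:
    @pytest.mark.parametrize(
        "r,expected", [(0.59, False), (0.60, True), (1.0, True)]
    )
    def test_threshold_boundary(self, r, expected):
        res = RegistrationResult(
            displacement_field=np.zeros((4, 4, 2)),
            warped_frame=np.zeros((4, 4)),
            pearson_before=0.0,
            pearson_after=r,
            accepted=False,
        )
        assert qc_registration(res, threshold=0.6) is expected


class TestOtsuUnionMask:
    def test_identical_frames_idempotent(self, noiseless_nadph_stack):
        f = noiseless_nadph_stack.frames[0]
        single = f > __import__("skimage.filters", fromlist=["threshold_otsu"]).threshold_otsu(f)
        np.testing.assert_array_equal(otsu_union_mask(f, f), single)

    def test_vanished_mitochondrion_stays_in_mask(self, noiseless_scene):
        """A spot present only before challenge (simulated RET) must keep
        its pixels in the union mask so the excess count can see them."""
        stack = render_frames(noiseless_scene, ("a", "b"), "nadph")
        sub = subtract_background(stack)
        before, after = sub.frames[0].copy(), sub.frames[1].copy()
        m = noiseless_scene.mitochondria[0]
        yy, xx = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        core = ((yy - m.centroid[0]) ** 2 + (xx - m.centroid[1]) ** 2) <= (
            1.0 * m.spot_sigma
        ) ** 2
        after[core] = 0.0
        mask = otsu_union_mask(before, after)
        assert mask[core].all()

    def test_mask_covers_spot_cores(self, noiseless_scene):
        stack = render_frames(noiseless_scene, ("a", "b"), "nadph")
        sub = subtract_background(stack)
        mask = otsu_union_mask(sub.frames[0], sub.frames[1])
        yy, xx = np.meshgrid(np.arange(128), np.arange(128), indexing="ij")
        covered = total = 0
        for m in noiseless_scene.mitochondria:
            core = ((yy - m.centroid[0]) ** 2 + (xx - m.centroid[1]) ** 2) <= (
                1.0 * m.spot_sigma
            ) ** 2
            covered += int(mask[core].sum())
            total += int(core.sum())
        assert covered / total >= 0.99

    def test_degenerate_frame_empty_mask(self):
        mask = otsu_union_mask(np.zeros((16, 16)), np.zeros((16, 16)))
        assert mask.sum() == 0
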