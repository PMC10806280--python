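"""Architecture contracts of the attention-gated ROI U-Net."""

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad

from marrowseg.nn.baseline import BaselineConfig, BaselineUNet
from marrowseg.nn.ops import detach, softmax_all
from marrowseg.nn.roi_unet import (
    CoordinateGrid,
    NetworkConfig,
    RoiAttentionUNet,
    RoiCentre,
    implant_roi,
    locate_roi,
    pad_to_divisible,
    roi_corner,
)
from marrowseg.phantom import PhantomConfig, generate_phantom
from marrowseg.volumes import LabelMask, RegionLabel

CFG = NetworkConfig.test_scale()


@pytest.fixture(scope="module")
def net_and_params():
    net = RoiAttentionUNet(CFG)
    return net, net.init_params(0)


class TestConfig:
    def test_roi_sizes_must_halve(self):
        with pytest.raises(ValueError, match="halve"):
            NetworkConfig(roi_sizes=(32, 16, 8, 5))

    def test_attention_cube_at_least_roi(self):
        with pytest.raises(ValueError):
            NetworkConfig(attention_map_size=16, roi_sizes=(32, 16, 8, 4))

    def test_one_width_per_level(self):
        with pytest.raises(ValueError):
            NetworkConfig(channels=(8, 16))


class TestEncoder:
    def test_shapes_and_five_attention_maps(self, net_and_params, rng):
        net, p = net_and_params
        state = net.encode(p, rng.random((24, 24, 24)))
        sides = [f.shape[1] for f in state.features]
        assert sides == [24, 12, 6, 3]
        assert [f.shape[0] for f in state.features] == list(CFG.channels)
        assert len(state.attention_maps) == 5
        for m in state.attention_maps:
            assert detach(m).shape == (24, 24, 24)

    def test_downsampling_halves_each_level(self, net_and_params, rng):
        net, p = net_and_params
        state = net.encode(p, rng.random((24, 48, 48)))
        shapes = [f.shape[1:] for f in state.features]
        for a, b in zip(shapes, shapes[1:]):
            assert tuple(x // 2 for x in a) == tuple(b)

    def test_constant_zero_input_finite(self, net_and_params):
        net, p = net_and_params
        out = net.forward(p, np.zeros((24, 24, 24)))
        assert np.isfinite(detach(out.roi_logits)).all()
        assert np.isfinite(detach(out.prob_map)).all()

    def test_non_divisible_shape_rejected(self, net_and_params):
        net, p = net_and_params
        with pytest.raises(ValueError, match="divisible"):
            net.encode(p, np.zeros((44, 48, 48)))

    def test_forward_deterministic(self, net_and_params, rng):
        net, p = net_and_params
        x = rng.random((24, 24, 24))
        a = detach(net.forward(p, x).roi_logits)
        b = detach(net.forward(p, x).roi_logits)
        assert np.array_equal(a, b)


class TestFusion:
    def test_probability_map_normalized(self, net_and_params, rng):
        net, p = net_and_params
        for _ in range(3):
            out = net.forward(p, rng.random((24, 24, 24)))
            P = detach(out.prob_map)
            assert P.min() >= 0
            assert abs(P.sum() - 1.0) < 1e-5

    def test_wrong_map_count_rejected(self, net_and_params):
        net, p = net_and_params
        maps = [np.zeros((24, 24, 24))] * 4
        with pytest.raises(ValueError, match="attention maps"):
            net.fuse_attention(p, maps)

    def test_identical_constant_maps_give_uniform_map(self, net_and_params):
        net, p = net_and_params
        maps = [np.full((24, 24, 24), 0.37) for _ in range(5)]
        P = detach(net.fuse_attention(p, maps))
        assert np.allclose(P, 1.0 / P.size)

    def test_softmax_monotone_in_perturbed_logit(self, rng):
        logits = rng.normal(size=(6, 6, 6))
        base = softmax_all(logits)
        bumped = logits.copy()
        bumped[2, 3, 4] += 0.5
        assert softmax_all(bumped)[2, 3, 4] > base[2, 3, 4]


class TestLocateRoi:
    def test_delta_map(self):
        grid = CoordinateGrid.for_shape((9, 9, 9))
        P = np.zeros((9, 9, 9))
        # normalized coords (u, v, w) = (0.5, -0.25, 0.0) -> indices x=6, y=3, z=4
        P[4, 3, 6] = 1.0
        c = locate_roi(P, grid)
        assert (c.x, c.y, c.z) == pytest.approx((0.5, -0.25, 0.0), abs=1e-12)

    def test_uniform_map_centred(self):
        P = np.full((8, 8, 8), 1.0 / 512)
        c = locate_roi(P, CoordinateGrid.for_shape((8, 8, 8)))
        assert (c.x, c.y, c.z) == pytest.approx((0, 0, 0), abs=1e-12)

    def test_two_point_expectation(self):
        P = np.zeros((3, 3, 3))
        P[1, 1, 0] = 0.5  # u = -1
        P[1, 1, 2] = 0.5  # u = +1
        c = locate_roi(P, CoordinateGrid.for_shape((3, 3, 3)))
        assert c.x == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_expectation_oracle(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            P = r.random((5, 5, 5))
            P /= P.sum()
            grid = CoordinateGrid.for_shape((5, 5, 5))
            c = locate_roi(P, grid)
            # brute force: triple loop over voxels
            ex = ey = ez = 0.0
            coords = np.linspace(-1, 1, 5)
            for i in range(5):
                for j in range(5):
                    for k in range(5):
                        ex += P[i, j, k] * coords[k]
                        ey += P[i, j, k] * coords[j]
                        ez += P[i, j, k] * coords[i]
            assert (c.x, c.y, c.z) == pytest.approx((ex, ey, ez), abs=1e-6)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            locate_roi(np.full((4, 4, 4), 1.0), CoordinateGrid.for_shape((4, 4, 4)))


class TestCropImplant:
    def test_centre_zero_grid24_roi16_spans_4_to_19(self):
        corner = roi_corner((0.0, 0.0, 0.0), (24, 24, 24), 16)
        assert corner == (4, 4, 4)

    def test_high_corner_clamped_flush(self):
        corner = roi_corner((1.0, 1.0, 1.0), (24, 24, 24), 16)
        assert corner == (8, 8, 8)
        corner = roi_corner((-1.0, -1.0, -1.0), (24, 24, 24), 16)
        assert corner == (0, 0, 0)

    def test_roi_larger_than_grid_rejected(self):
        with pytest.raises(ValueError):
            roi_corner((0.0, 0.0, 0.0), (8, 8, 8), 16)

    def test_crop_then_implant_restores_mask_inside_roi(self):
        r = np.random.default_rng(0)
        for _ in range(50):
            mask = (r.random((24, 24, 24)) < 0.3).astype(np.uint8)
            centre = tuple(r.uniform(-1.1, 1.1, 3).clip(-1, 1))
            corner = roi_corner(centre, mask.shape, 16)
            z, y, x = corner
            crop = mask[z : z + 16, y : y + 16, x : x + 16]
            implanted = implant_roi(crop, corner, mask.shape)
            assert np.array_equal(
                implanted.data[z : z + 16, y : y + 16, x : x + 16], crop
            )
            outside = implanted.data.copy()
            outside[z : z + 16, y : y + 16, x : x + 16] = 0
            assert outside.sum() == 0

    def test_implant_all_foreground_and_all_background(self):
        scores = np.zeros((2, 4, 4, 4))
        scores[1] = 1.0  # all-foreground ROI
        m = implant_roi(scores, (2, 2, 2), (10, 10, 10))
        assert m.voxel_count == 64
        scores[1] = -1.0
        scores[0] = 1.0
        assert implant_roi(scores, (2, 2, 2), (10, 10, 10)).voxel_count == 0


class TestDecoder:
    def test_output_shape(self, net_and_params, rng):
        net, p = net_and_params
        out = net.forward(p, rng.random((24, 24, 24)))
        assert detach(out.roi_logits).shape == (2, 16, 16, 16)
        assert np.isfinite(detach(out.roi_logits)).all()

    def test_dice_gradient_wrt_decoder_input_nonzero(self, net_and_params, rng):
        net, p = net_and_params
        state = net.encode(p, rng.random((24, 24, 24)))
        P = net.fuse_attention(p, state.attention_maps)
        centre = locate_roi(P, CoordinateGrid.for_shape(detach(P).shape))
        crops = net.crop_roi(state, centre)
        target = (rng.random((16, 16, 16)) < 0.2).astype(float)
        base = [detach(f) for f in crops.features]

        def f(c0):
            from marrowseg.losses import dice_loss
            from marrowseg.nn.ops import softmax_channels
            from marrowseg.nn.roi_unet import RoiCrops

            feats = [c0] + base[1:]
            logits = net.decode(p, RoiCrops(features=feats, corners=crops.corners))
            return dice_loss(softmax_channels(logits)[1], target)

        g = grad(f)(base[0])
        assert np.abs(g).max() > 0

    def test_mismatched_crop_shapes_rejected(self, net_and_params, rng):
        from marrowseg.nn.roi_unet import RoiCrops

        net, p = net_and_params
        bad = RoiCrops(
            features=[np.zeros((CFG.channels[k], 4, 4, 4)) for k in range(4)],
            corners=[(0, 0, 0)] * 4,
        )
        with pytest.raises(ValueError, match="crop"):
            net.decode(p, bad)


class TestPaddingAndPredict:
    def test_slab_like_44_slices_padded_and_unpadded(self, net_and_params):
        net, p = net_and_params
        s = generate_phantom(
            PhantomConfig.test_scale(RegionLabel.DIAPHYSIS, shape=(20, 24, 24))
        )
        res = net.predict(p, s.fat)  # 20 is not divisible by 8 -> padded to 24
        assert res.mask.shape == (20, 24, 24)
        padded, lo = pad_to_divisible(np.zeros((44, 48, 48)), 8)
        assert padded.shape == (48, 48, 48) and lo == (2, 0, 0)

    def test_centre_within_unit_cube(self, net_and_params, rng):
        net, p = net_and_params
        s = generate_phantom(PhantomConfig.test_scale(RegionLabel.FEMORAL_HEAD, shape=(24, 24, 24)))
        res = net.predict(p, s.fat)
        for c in res.centre.as_xyz():
            assert -1.0 <= c <= 1.0


class TestLightweightClaim:
    def test_fewer_parameters_than_size_matched_unet(self):
        roi = RoiAttentionUNet(CFG)
        unet = BaselineUNet(BaselineConfig.test_scale())
        assert roi.parameter_count(roi.init_params(0)) < unet.parameter_count(unet.init_params(0))
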