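"""CARAFE: kernel prediction contracts and reassembly oracle equivalence."""
import numpy as np
import pytest

from dfma.carafe import Carafe, CarafeConfig
from dfma.nn import Tensor


def naive_reassemble(x, kernels, sigma, k_up):
    """Four-nested-loop reference implementation of the reassembly step."""
    B, C, H, W = x.shape
    out = np.zeros((B, C, sigma * H, sigma * W), dtype=x.dtype)
    half = k_up // 2
    for b in range(B):
        for oy in range(sigma * H):
            for ox in range(sigma * W):
                sy, sx = oy // sigma, ox // sigma  # source position floor(l'/sigma)
                k = kernels[b, :, oy, ox].reshape(k_up, k_up)
                for c in range(C):
                    acc = 0.0
                    for dy in range(-half, half + 1):
                        for dx in range(-half, half + 1):
                            yy, xx = sy + dy, sx + dx
                            if 0 <= yy < H and 0 <= xx < W:
                                acc += x[b, c, yy, xx] * k[dy + half, dx + half]
                    out[b, c, oy, ox] = acc
    return out


def _module(channels, sigma, k_up=3, seed=0):
    cfg = CarafeConfig(sigma=sigma, k_up=k_up, k_encoder=3, c_m=8)
    return Carafe(channels, cfg, rng=np.random.default_rng(seed))


class TestKernelPrediction:
    def test_kernel_grid_shape(self, rng):
        up = _module(6, sigma=2, k_up=5)
        x = Tensor(rng.normal(size=(2, 6, 4, 4)).astype(np.float32))
        assert up.predict_kernels(x).shape == (2, 25, 8, 8)

    def test_kernels_normalized_to_unit_sum(self, rng):
        up = _module(6, sigma=3)
        x = Tensor(rng.normal(size=(1, 6, 5, 5)).astype(np.float32))
        k = up.predict_kernels(x).data
        np.testing.assert_allclose(k.sum(axis=1), 1.0, atol=1e-6)
        assert (k >= 0).all()

    def test_constant_input_kernels_translation_invariant(self, rng):
        """On a constant field every source position sees the same content,
        so all interior positions of the same sigma-sub-phase share one
        kernel (phases come from distinct encoder channels and may differ)."""
        sigma = 2
        up = _module(4, sigma=sigma)
        x = Tensor(np.full((1, 4, 6, 6), 1.7, dtype=np.float32))
        k = up.predict_kernels(x).data
        interior = k[:, :, sigma:-sigma, sigma:-sigma]
        for py in range(sigma):
            for px in range(sigma):
                phase = interior[:, :, py::sigma, px::sigma]
                np.testing.assert_allclose(
                    phase, np.broadcast_to(phase[:, :, :1, :1], phase.shape),
                    atol=1e-6)


class TestReassembly:
    def test_delta_kernels_reproduce_nearest_neighbour(self, rng):
        sigma, k_up = 2, 3
        up = _module(3, sigma, k_up)
        x = rng.normal(size=(1, 3, 4, 4)).astype(np.float32)
        kernels = np.zeros((1, k_up * k_up, sigma * 4, sigma * 4), dtype=np.float32)
        kernels[:, (k_up * k_up) // 2] = 1.0  # weight 1 at the centre tap
        out = up.reassemble(Tensor(x), Tensor(kernels)).data
        expected = x.repeat(sigma, axis=2).repeat(sigma, axis=3)
        np.testing.assert_array_equal(out, expected)

    def test_constant_input_invariant_under_any_kernels(self, rng):
        sigma, k_up = 2, 3
        up = _module(2, sigma, k_up)
        x = Tensor(np.full((1, 2, 5, 5), 3.25, dtype=np.float32))
        out = up(x).data
        # interior positions: convex combination of a constant is the constant
        np.testing.assert_allclose(out[:, :, sigma:-sigma, sigma:-sigma], 3.25,
                                   rtol=1e-5)

    @pytest.mark.parametrize("shape,sigma,k_up", [
        ((1, 1, 2, 2), 2, 3),
        ((2, 3, 4, 5), 2, 3),
        ((1, 3, 8, 8), 4, 5),
    ])
    def test_vectorized_matches_naive_loop_oracle(self, rng, shape, sigma, k_up):
        up = _module(shape[1], sigma, k_up)
        x = rng.normal(size=shape).astype(np.float32)
        kern = up.predict_kernels(Tensor(x))
        got = up.reassemble(Tensor(x), kern).data
        ref = naive_reassemble(x, kern.data, sigma, k_up)
        np.testing.assert_allclose(got, ref, atol=1e-5)

    def test_convex_combination_bound(self, rng):
        sigma, k_up = 2, 3
        up = _module(1, sigma, k_up)
        x = rng.normal(size=(1, 1, 6, 6)).astype(np.float32)
        out = up(Tensor(x)).data
        for oy in range(sigma, sigma * 6 - sigma):
            for ox in range(sigma, sigma * 6 - sigma):
                sy, sx = oy // sigma, ox // sigma
                nb = x[0, 0, max(0, sy - 1):sy + 2, max(0, sx - 1):sx + 2]
                assert nb.min() - 1e-5 <= out[0, 0, oy, ox] <= nb.max() + 1e-5

    def test_channel_permutation_shares_kernels(self, rng):
        up = _module(4, sigma=2)
        x = rng.normal(size=(1, 4, 4, 4)).astype(np.float32)
        kern = Tensor(np.abs(rng.normal(size=(1, 9, 8, 8))).astype(np.float32))
        kern = kern / kern.sum(axis=1, keepdims=True)
        out = up.reassemble(Tensor(x), kern).data
        perm = [3, 0, 2, 1]
        out_p = up.reassemble(Tensor(x[:, perm]), kern).data
        np.testing.assert_allclose(out_p, out[:, perm], rtol=1e-6)

    def test_mismatched_kernel_grid_rejected(self, rng):
        up = _module(2, sigma=2)
        with pytest.raises(ValueError):
            up.reassemble(Tensor(rng.normal(size=(1, 2, 4, 4))),
                          Tensor(rng.normal(size=(1, 9, 6, 6))))


class TestUpsampleComposition:
    def test_spatial_factor_and_channel_preservation(self, rng):
        up = _module(5, sigma=4)
        x = Tensor(rng.normal(size=(1, 5, 4, 4)).astype(np.float32))
        assert up(x).shape == (1, 5, 16, 16)

    def test_two_sigma2_passes_match_sigma4_size(self, rng):
        up2 = _module(3, sigma=2)
        up4 = _module(3, sigma=4)
        x = Tensor(rng.normal(size=(1, 3, 4, 4)).astype(np.float32))
        twice = up2(up2(x))
        once = up4(x)
        assert twice.shape == once.shape == (1, 3, 16, 16)
        assert not np.allclose(twice.data, once.data)  # sizes equal, values differ

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CarafeConfig(sigma=1)
        with pytest.raises(ValueError):
            CarafeConfig(sigma=2, k_up=4)
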