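import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medcrypt.chaos import ChaosParams
from medcrypt.cipher import (
    BPCompressor,
    CipherConfig,
    CompressorTrainConfig,
    blockify,
    compress_blocks,
    deblockify,
    decrypt,
    diffuse,
    encrypt,
    fit_compressor,
    load_ciphertext,
    normalize_image,
    plaintext_digest,
    read_image,
    reconstruct_blocks,
    save_ciphertext,
    scramble,
    transfer,
    undiffuse,
    unscramble,
    write_image,
    zigzag_plan,
)
from medcrypt.security import information_entropy, npcr


class TestNormalize:
    def test_full_range_maps_to_unit_interval(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = normalize_image(img)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_midpoint(self):
        img = np.array([[0, 128, 255]], dtype=np.uint8)
        out = normalize_image(img)
        assert out[0, 1] == pytest.approx(128 / 255)

    def test_constant_image_maps_to_ymin(self):
        out = normalize_image(np.full((4, 4), 99, np.uint8), target=(0.2, 0.8))
        assert np.all(out == 0.2)


class TestBlocks:
    def test_block_count_divisible(self):
        bs = blockify(np.zeros((4, 4), np.uint8), 2)
        assert bs.n_blocks == 4

    def test_padding_and_round_trip(self, rng):
        img = rng.integers(0, 256, (5, 5), dtype=np.uint8)
        bs = blockify(img, 2)
        assert bs.padded_shape == (6, 6) and bs.n_blocks == 9
        np.testing.assert_array_equal(deblockify(bs), img)

    def test_single_pixel(self):
        img = np.array([[7]], dtype=np.uint8)
        bs = blockify(img, 1)
        assert bs.n_blocks == 1
        np.testing.assert_array_equal(bs.blocks[0], img)

    @pytest.mark.parametrize("shape,m", [((7, 3), 4), ((1, 9), 2), ((16, 16), 8)])
    def test_round_trip_odd_shapes(self, rng, shape, m):
        img = rng.integers(0, 256, shape, dtype=np.uint8)
        np.testing.assert_array_equal(deblockify(blockify(img, m)), img)


class TestTransfer:
    def test_logsig_symmetry_point(self):
        assert transfer(0.0, "logsig") == pytest.approx(0.5)

    def test_tansig_odd(self):
        assert transfer(0.0, "tansig") == pytest.approx(0.0)

    def test_logsig_ln3(self):
        assert transfer(np.log(3), "logsig") == pytest.approx(0.75)

    def test_ranges(self, rng):
        x = rng.normal(0, 5, 100)
        assert np.all((transfer(x, "logsig") > 0) & (transfer(x, "logsig") < 1))
        assert np.all((transfer(x, "tansig") > -1) & (transfer(x, "tansig") < 1))


class TestCompressor:
    def test_compression_rate(self):
        bs = blockify(np.zeros((16, 16), np.uint8), 8)
        bs.blocks = bs.blocks.astype(float) / 255.0
        comp = fit_compressor(bs, 16, CompressorTrainConfig(epochs=5))
        assert comp.compression_rate == 4.0

    def test_identity_rate(self):
        bs = blockify(np.zeros((4, 4), np.uint8), 2)
        comp = fit_compressor(bs, 4, CompressorTrainConfig(epochs=2))
        assert comp.compression_rate == 1.0

    def test_invalid_hidden_count(self):
        bs = blockify(np.zeros((4, 4), np.uint8), 2)
        with pytest.raises(ValueError):
            fit_compressor(bs, 0)

    def test_training_reduces_reconstruction_error(self, rng):
        from medcrypt.cipher import _reconstruction_mse

        blocks = np.repeat(rng.random((50, 1, 1)), 16, axis=1)
        bs = blockify(np.zeros((8, 8), np.uint8), 4)
        bs.blocks = blocks.reshape(50, 4, 4)
        untrained = fit_compressor(bs, 4, CompressorTrainConfig(epochs=0))
        trained = fit_compressor(bs, 4, CompressorTrainConfig(epochs=300))
        flat = bs.blocks.reshape(50, -1)
        assert _reconstruction_mse(trained, flat) < _reconstruction_mse(untrained, flat)

    def test_code_image_contract_and_psnr(self):
        """Smooth blocks at rate 4 reconstruct above 25 dB."""
        from medcrypt.synthdata import PhantomConfig, generate_phantom

        img, _, _ = generate_phantom(PhantomConfig(size=(64, 64), noise_sigma=2.0, seed=3))
        norm = normalize_image(img)
        bs = blockify(norm, 8)
        comp = fit_compressor(bs, 16, CompressorTrainConfig(epochs=500))
        code = compress_blocks(bs, comp)
        assert code.shape == (bs.n_blocks, 16)
        assert code.dtype == np.uint8
        rec = deblockify(reconstruct_blocks(code, comp, bs))
        mse = np.mean((rec - norm) ** 2)
        psnr = 10 * np.log10(1.0 / mse)
        assert psnr >= 25.0


class TestZigzag:
    def test_square_top_left_scan(self):
        vals = np.arange(1, 10).reshape(3, 3)
        plan = zigzag_plan(3, 3, 0)
        assert vals.reshape(-1)[plan.order].tolist() == [1, 2, 4, 7, 5, 3, 6, 8, 9]

    def test_nonsquare_top_left_scan(self):
        vals = np.arange(1, 7).reshape(2, 3)
        plan = zigzag_plan(2, 3, 0)
        assert vals.reshape(-1)[plan.order].tolist() == [1, 2, 4, 5, 3, 6]

    def test_single_cell_identity(self):
        assert zigzag_plan(1, 1, 0).order.tolist() == [0]

    def test_bijective_all_shapes_all_corners(self):
        """Every plan in [1,16]^2 x 4 corners visits every cell exactly once."""
        for rows in range(1, 17):
            for cols in range(1, 17):
                for corner in range(4):
                    order = zigzag_plan(rows, cols, corner).order
                    assert sorted(order.tolist()) == list(range(rows * cols))


class TestScramble:
    def test_known_rearrangement(self):
        vals = np.arange(1, 10).reshape(3, 3)
        out = scramble(vals, zigzag_plan(3, 3, 0))
        np.testing.assert_array_equal(out, [[1, 2, 4], [7, 5, 3], [6, 8, 9]])

    def test_inverse(self, rng):
        img = rng.integers(0, 256, (7, 11), dtype=np.uint8)
        for corner in range(4):
            plan = zigzag_plan(7, 11, corner)
            np.testing.assert_array_equal(unscramble(scramble(img, plan), plan), img)

    def test_pixel_multiset_preserved(self, rng):
        img = rng.integers(0, 256, (6, 9), dtype=np.uint8)
        out = scramble(img, zigzag_plan(6, 9, 1))
        np.testing.assert_array_equal(np.sort(img, axis=None), np.sort(out, axis=None))

    def test_corners_give_distinct_outputs(self):
        grad = np.arange(9, dtype=np.uint8).reshape(3, 3)
        tl = scramble(grad, zigzag_plan(3, 3, 0))
        br = scramble(grad, zigzag_plan(3, 3, 3))
        assert not np.array_equal(tl, br)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            scramble(np.zeros((2, 2), np.uint8), zigzag_plan(3, 3, 0))


class TestDiffusion:
    def test_xor_identity(self):
        np.testing.assert_array_equal(
            diffuse([0, 0, 0], [0, 0, 0], 0, "forward"), [0, 0, 0]
        )

    def test_forward_chain_by_hand(self):
        # 0^5^1=4; 4^5^2=3; 3^5^3=5
        np.testing.assert_array_equal(
            diffuse([1, 2, 3], [5, 5, 5], 0, "forward"), [4, 3, 5]
        )

    def test_forward_inverse_by_hand(self):
        np.testing.assert_array_equal(
            undiffuse([4, 3, 5], [5, 5, 5], 0, "forward"), [1, 2, 3]
        )

    def test_zero_cipher(self):
        np.testing.assert_array_equal(
            undiffuse(np.zeros(5, np.uint8), np.zeros(5, np.uint8), 0, "forward"),
            np.zeros(5),
        )

    @pytest.mark.parametrize("direction", ["forward", "reverse"])
    def test_round_trip_random_sequences(self, rng, direction):
        for _ in range(20):
            n = int(rng.integers(1, 200))
            q = rng.integers(0, 256, n, dtype=np.uint8)
            r = rng.integers(0, 256, n, dtype=np.uint8)
            iv = int(rng.integers(256))
            np.testing.assert_array_equal(
                undiffuse(diffuse(q, r, iv, direction), r, iv, direction), q
            )

    def test_keystream_too_short(self):
        with pytest.raises(ValueError):
            diffuse([1, 2, 3], [1], 0, "forward")


class TestEncryptDecrypt:
    def test_shape_contract(self, rng, key):
        img = rng.integers(0, 256, (24, 17), dtype=np.uint8)
        c, meta = encrypt(img, key)
        assert c.shape == img.shape
        assert meta["corner"] in (0, 1, 2, 3)

    def test_round_trip_exact_many_shapes(self, rng, key):
        for _ in range(25):
            shape = tuple(int(s) for s in rng.integers(1, 40, 2))
            img = rng.integers(0, 256, shape, dtype=np.uint8)
            c, meta = encrypt(img, key)
            np.testing.assert_array_equal(decrypt(c, meta, key), img)

    def test_single_pixel_round_trip(self, key):
        img = np.array([[123]], dtype=np.uint8)
        c, meta = encrypt(img, key)
        np.testing.assert_array_equal(decrypt(c, meta, key), img)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        rows=st.integers(1, 24),
        cols=st.integers(1, 24),
        seed=st.integers(0, 2**16),
    )
    def test_round_trip_property(self, rows, cols, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (rows, cols), dtype=np.uint8)
        key = ChaosParams(initial_state=tuple(rng.uniform(0.1, 0.9, 3)))
        c, meta = encrypt(img, key)
        np.testing.assert_array_equal(decrypt(c, meta, key), img)

    def test_constant_image_ciphertext_flat_histogram(self, key):
        from scipy.stats import chi2

        img = np.full((256, 256), 200, dtype=np.uint8)
        c, _ = encrypt(img, key)
        assert information_entropy(c) >= 7.99
        counts = np.bincount(c.ravel(), minlength=256)
        stat = np.sum((counts - 256.0) ** 2 / 256.0)
        assert stat < 1.2 * chi2.ppf(0.99, df=255)

    def test_key_sensitivity(self, rng):
        img = rng.integers(0, 256, (128, 128), dtype=np.uint8)
        k1 = ChaosParams(initial_state=(0.3, 0.6, 0.7))
        k2 = ChaosParams(initial_state=(0.3 + 1e-10, 0.6, 0.7))
        c1, _ = encrypt(img, k1)
        c2, _ = encrypt(img, k2)
        assert 99.0 <= npcr(c1, c2) <= 100.0

    def test_wrong_key_decrypts_to_noise(self, rng):
        img = rng.integers(0, 256, (128, 128), dtype=np.uint8)
        k1 = ChaosParams(initial_state=(0.3, 0.6, 0.7))
        k2 = ChaosParams(initial_state=(0.31, 0.6, 0.7))
        c, meta = encrypt(img, k1)
        garbage = decrypt(c, meta, k2)
        assert npcr(garbage, img) >= 99.0

    def test_avalanche_one_pixel_change(self, rng, key):
        """One plaintext pixel flips nearly every ciphertext byte."""
        img = rng.integers(0, 256, (64, 64), dtype=np.uint8)
        other = img.copy()
        other[10, 10] ^= 0x55
        c1, _ = encrypt(img, key)
        c2, _ = encrypt(other, key)
        assert npcr(c1, c2) >= 99.0

    def test_digest_changes_with_any_pixel(self, rng):
        img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        d0 = plaintext_digest(img)
        for _ in range(10):
            other = img.copy()
            i, j = rng.integers(16), rng.integers(16)
            other[i, j] ^= int(rng.integers(1, 256))
            assert plaintext_digest(other) != d0

    def test_compression_round_trip_is_faithful_enough(self):
        from medcrypt.synthdata import PhantomConfig, generate_phantom

        img, _, _ = generate_phantom(PhantomConfig(size=(64, 64), noise_sigma=2.0, seed=3))
        key = ChaosParams(initial_state=(0.3, 0.6, 0.7))
        cfg = CipherConfig(use_compression=True, block_size=8, hidden_nodes=16)
        c, meta = encrypt(img, key, cfg)
        assert c.shape == (meta["padded_shape"][0] // 8 * (meta["padded_shape"][1] // 8), 16)
        rec = decrypt(c, meta, key)
        assert rec.shape == img.shape
        mse = np.mean((rec.astype(float) - img.astype(float)) ** 2)
        psnr = 10 * np.log10(255.0**2 / mse)
        assert psnr >= 25.0
        assert meta["compression_rate"] == 4.0

    def test_ciphertext_file_round_trip(self, tmp_path, rng, key):
        img = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        c, meta = encrypt(img, key)
        out = tmp_path / "cipher.png"
        save_ciphertext(c, meta, out)
        c2, meta2 = load_ciphertext(out)
        np.testing.assert_array_equal(decrypt(c2, meta2, key), img)


class TestImageIO:
    @pytest.mark.parametrize("suffix", [".png", ".pgm"])
    def test_read_write(self, tmp_path, rng, suffix):
        img = rng.integers(0, 256, (9, 13), dtype=np.uint8)
        path = tmp_path / f"img{suffix}"
        write_image(img, path)
        np.testing.assert_array_equal(read_image(path), img)
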