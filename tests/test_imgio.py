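"""Stack I/O, quantisation, patch tiling and sequence decomposition."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

from lsfmrestore import errors
from lsfmrestore.imgio import (
    ImageStack,
    PresenceRule,
    make_sequences,
    patchify,
    read_stack,
    stitch,
    write_stack,
)

RNG = np.random.default_rng(7)


class TestReadWrite:
    def test_16bit_max_normalises_to_one(self, tmp_path):
        tifffile.imwrite(tmp_path / "a.tif", np.array([[0, 65535]], dtype=np.uint16))
        stack = read_stack(tmp_path / "a.tif")
        assert stack.bit_depth == 16
        assert stack.data.max() == 1.0 and stack.data.min() == 0.0

    def test_single_page_is_stack_of_depth_one(self, tmp_path):
        tifffile.imwrite(tmp_path / "a.tif", np.zeros((8, 8), dtype=np.uint8))
        assert read_stack(tmp_path / "a.tif").shape == (1, 8, 8)

    @pytest.mark.parametrize("depth", [8, 16])
    def test_round_trip_is_integer_exact(self, tmp_path, depth):
        raw = RNG.integers(0, 2**depth, size=(3, 8, 8)).astype(
            np.uint8 if depth == 8 else np.uint16
        )
        tifffile.imwrite(tmp_path / "v.tif", raw)
        stack = read_stack(tmp_path / "v.tif")
        write_stack(stack, tmp_path / "w.tif", depth)
        np.testing.assert_array_equal(tifffile.imread(tmp_path / "w.tif"), raw)

    def test_quantisation_rounds_half_away_from_zero(self, tmp_path):
        stack = ImageStack(np.array([[[0.0, 0.5, 1.0]]]), bit_depth=8)
        write_stack(stack, tmp_path / "q.tif", 8)
        np.testing.assert_array_equal(
            np.squeeze(tifffile.imread(tmp_path / "q.tif")), np.array([0, 128, 255], dtype=np.uint8)
        )

    def test_directory_of_slices_lexicographic(self, tmp_path):
        d = tmp_path / "stack"
        d.mkdir()
        for i in range(3):
            tifffile.imwrite(d / f"slice_{i:03d}.tif", np.full((4, 4), i * 100, dtype=np.uint16))
        stack = read_stack(d)
        assert stack.shape == (3, 4, 4)
        assert np.all(np.diff(stack.data[:, 0, 0]) > 0)

    def test_inconsistent_slice_shapes_rejected(self, tmp_path):
        d = tmp_path / "bad"
        d.mkdir()
        tifffile.imwrite(d / "a.tif", np.zeros((4, 4), np.uint8))
        tifffile.imwrite(d / "b.tif", np.zeros((5, 5), np.uint8))
        with pytest.raises(errors.ShapeError):
            read_stack(d)

    def test_non_image_file_is_format_error(self, tmp_path):
        (tmp_path / "junk.tif").write_text("not a tiff")
        with pytest.raises(errors.FormatError):
            read_stack(tmp_path / "junk.tif")

    def test_out_of_range_write_rejected(self, tmp_path):
        stack = ImageStack(np.zeros((1, 4, 4)))
        stack.data = stack.data + 1.5  # bypass constructor clip
        with pytest.raises(errors.RangeError):
            write_stack(stack, tmp_path / "x.tif")


class TestImageStackContract:
    def test_non_finite_rejected(self):
        with pytest.raises(errors.DataError):
            ImageStack(np.array([[[np.nan]]]))

    def test_out_of_range_rejected(self):
        with pytest.raises(errors.RangeError):
            ImageStack(np.array([[[1.5]]]))

    def test_2d_promoted_to_single_slice(self):
        assert ImageStack(np.zeros((4, 4))).shape == (1, 4, 4)


class TestPatchify:
    def test_2048_slice_gives_256_patches_of_128(self):
        patches, grid = patchify(np.zeros((2048, 2048), np.float32), 128)
        assert patches.shape == (256, 128, 128)
        assert grid.grid_shape == (16, 16)

    def test_small_slice_padded_to_one_tile(self):
        patches, grid = patchify(np.ones((100, 100)), 128)
        assert patches.shape == (1, 128, 128)
        assert grid.padded_shape == (128, 128)
        np.testing.assert_array_equal(patches[0], np.ones((128, 128)))  # edge padding

    @settings(deadline=None, max_examples=25)
    @given(
        h=st.integers(20, 200),
        w=st.integers(20, 200),
        ph=st.integers(8, 64),
        pw=st.integers(8, 64),
    )
    def test_stitch_inverts_patchify(self, h, w, ph, pw):
        x = np.random.default_rng(h * w).random((h, w))
        patches, grid = patchify(x, (ph, pw))
        np.testing.assert_array_equal(stitch(patches, grid), x)

    def test_patch_count_mismatch_is_grid_error(self):
        patches, grid = patchify(RNG.random((300, 200)), 128)
        with pytest.raises(errors.GridError):
            stitch(patches[:-1], grid)

    def test_tiny_patch_rejected(self):
        with pytest.raises(errors.SizeError):
            patchify(np.zeros((32, 32)), 4)


class TestSequences:
    def test_window_count_matches_closed_form(self):
        stack = ImageStack(RNG.random((62, 64, 64)))
        blocks = make_sequences(stack, seq_len=31, patch_size=32, stride_z=31)
        # 2 z-windows x (64/32)^2 lateral tiles
        assert len(blocks) == 2 * 4
        assert blocks[0].data.shape == (31, 32, 32)

    def test_default_geometry(self):
        stack = ImageStack(RNG.random((31, 32, 32)))
        blocks = make_sequences(stack)
        assert len(blocks) == 1 and blocks[0].data.shape == (31, 32, 32)

    def test_black_stack_filtered_empty(self):
        stack = ImageStack(np.zeros((31, 64, 64)))
        blocks = make_sequences(stack, presence_filter=PresenceRule(0.05, 0.01))
        assert blocks == []

    def test_seq_longer_than_stack_rejected(self):
        with pytest.raises(errors.SizeError):
            make_sequences(ImageStack(np.zeros((10, 32, 32))), seq_len=31)
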