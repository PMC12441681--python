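"""Binarization, intermodes thresholding, and Tanimoto/Manders statistics."""

import numpy as np
import pytest

from pepatlas.cell_mapping import MappingImage
from pepatlas.colocalization import (
    BinaryMask,
    ThresholdError,
    binarize,
    coloc_matrix,
    manders,
    plot_heatmap,
    read_mask_stack,
    tanimoto,
    threshold_intermodes,
    to_16bit,
    write_coloc_report,
    write_mask_stack,
)
from pepatlas.registration import GrayImage


def _mask(grid):
    return BinaryMask(grid=np.asarray(grid, dtype=bool))


def _mapping(grid):
    return MappingImage(
        grid=np.asarray(grid, dtype=np.uint8), peptide="p", section="0", pixel_size=1.0
    )


class TestTo16Bit:
    @pytest.mark.parametrize("v8,v16", [(0, 0), (255, 65535), (33, 8481)])
    def test_endpoint_and_threshold_values(self, v8, v16):
        out = to_16bit(_mapping(np.full((2, 2), v8)))
        assert out.bit_depth == 16
        assert np.all(out.grid == v16)

    def test_non_8bit_rejected(self):
        img = GrayImage(grid=np.zeros((2, 2), dtype=np.uint16), bit_depth=16)
        with pytest.raises(ValueError, match="8-bit"):
            to_16bit(img)


class TestIntermodes:
    def _spike_image(self, level_a, level_b):
        grid = np.concatenate(
            [np.full(100, level_a * 257, np.uint16), np.full(100, level_b * 257, np.uint16)]
        ).reshape(10, 20)
        return GrayImage(grid=grid, bit_depth=16)

    def test_two_equal_spikes_midpoint(self):
        assert threshold_intermodes(self._spike_image(50, 150)) == 100 * 257

    def test_close_spikes_midpoint(self):
        assert threshold_intermodes(self._spike_image(10, 20)) == 15 * 257

    def test_constant_image_fails(self):
        with pytest.raises(ThresholdError):
            threshold_intermodes(self._spike_image(80, 80))

    def test_matches_brute_force_smoothing_oracle(self, rng):
        """Iterative 3-bin smoothing oracle, written as explicit loops."""

        def oracle(values16):
            hist = [0.0] * 256
            for v in values16.ravel():
                hist[int(v) // 257] += 1.0
            for _ in range(10_000):
                peaks = [
                    i
                    for i in range(1, 255)
                    if hist[i] > hist[i - 1] and hist[i] >= hist[i + 1]
                ]
                if len(peaks) == 2:
                    return int(round((peaks[0] + peaks[1]) / 2 * 257))
                if len(peaks) < 2:
                    raise ThresholdError("unimodal")
                hist = [
                    ((hist[i - 1] if i > 0 else 0.0) + hist[i] + (hist[i + 1] if i < 255 else 0.0)) / 3.0
                    for i in range(256)
                ]
            raise ThresholdError("no convergence")

        for _ in range(25):
            mu1, mu2 = rng.uniform(20, 80), rng.uniform(150, 230)
            levels = np.concatenate(
                [rng.normal(mu1, 10, 300), rng.normal(mu2, 10, 300)]
            )
            grid = (np.clip(levels, 0, 255).astype(np.uint16) * 257).reshape(30, 20)
            img = GrayImage(grid=grid, bit_depth=16)
            assert threshold_intermodes(img) == oracle(grid)


class TestBinarize:
    def test_lower_bound_inclusive(self):
        grid = np.array([[8400, 8399], [65535, 0]], dtype=np.uint16)
        mask = binarize(GrayImage(grid=grid, bit_depth=16))
        np.testing.assert_array_equal(mask.grid, [[True, False], [True, False]])
        assert mask.area == 2

    def test_all_below_range_empty(self):
        mask = binarize(GrayImage(grid=np.full((3, 3), 100, np.uint16), bit_depth=16))
        assert mask.area == 0

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            binarize(np.zeros((2, 2), np.uint16), lo=100, hi=50)

    def test_idempotent_through_mask_rendering(self, rng):
        mask = rng.random((8, 8)) > 0.5
        rendered = (mask.astype(np.uint16)) * 65535
        again = binarize(rendered, 8400, 65535)
        np.testing.assert_array_equal(again.grid, mask)


class TestTanimoto:
    def test_identical_stacks_give_one(self, rng):
        stack = [_mask(rng.random((6, 6)) > 0.5) for _ in range(3)]
        assert tanimoto(stack, stack).tanimoto == 1.0

    def test_disjoint_stacks_give_zero(self):
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[:, :2] = True
        b[:, 2:] = True
        assert tanimoto([_mask(a)], [_mask(b)]).tanimoto == 0.0

    def test_printed_formula_arithmetic(self):
        a = np.zeros((20, 10), bool)
        b = np.zeros((20, 10), bool)
        a[:10] = True  # 100 px
        b[5:15] = True  # 100 px, 50 overlap
        res = tanimoto([_mask(a)], [_mask(b)])
        assert (res.area_a, res.area_b, res.area_overlap) == (100, 100, 50)
        assert res.tanimoto == pytest.approx(50 / 150)

    def test_both_empty_convention_zero(self):
        empty = [_mask(np.zeros((3, 3), bool))]
        assert tanimoto(empty, empty).tanimoto == 0.0

    def test_section_count_mismatch_rejected(self):
        m = _mask(np.ones((2, 2), bool))
        with pytest.raises(ValueError, match="mismatch"):
            tanimoto([m, m], [m])

    def test_symmetric_and_section_order_invariant(self, rng):
        a = [_mask(rng.random((5, 5)) > 0.4) for _ in range(4)]
        b = [_mask(rng.random((5, 5)) > 0.6) for _ in range(4)]
        t_ab = tanimoto(a, b).tanimoto
        t_ba = tanimoto(b, a).tanimoto
        t_rev = tanimoto(a[::-1], b[::-1]).tanimoto
        assert t_ab == t_ba == t_rev

    def test_pooling_equals_concatenated_3d_computation(self, rng):
        a = [rng.random((4, 4)) > 0.5 for _ in range(3)]
        b = [rng.random((4, 4)) > 0.5 for _ in range(3)]
        res = tanimoto([_mask(x) for x in a], [_mask(x) for x in b])
        va, vb = np.stack(a), np.stack(b)
        overlap = int((va & vb).sum())
        expected = overlap / (int(va.sum()) + int(vb.sum()) - overlap)
        assert res.tanimoto == pytest.approx(expected, abs=1e-15)


class TestManders:
    def test_containment_gives_m1_one(self):
        a = np.zeros((4, 4), bool)
        b = np.ones((4, 4), bool)
        a[0, 0] = True
        m1, m2 = manders([_mask(a)], [_mask(b)])
        assert m1 == 1.0
        assert m2 == pytest.approx(1 / 16)

    def test_printed_formula_arithmetic(self):
        a = np.zeros((20, 20), bool)
        b = np.zeros((20, 20), bool)
        b[:10, :20] = True  # 200 px
        a[:5, :10] = True  # 50 px inside b
        a[12:17, :10] = True  # 50 px outside b -> area_a = 100, overlap = 50
        m1, m2 = manders([_mask(a)], [_mask(b)])
        assert m1 == pytest.approx(50 / 100)
        assert m2 == pytest.approx(50 / 200)

    def test_disjoint_gives_zero(self):
        a = np.zeros((2, 2), bool)
        b = np.zeros((2, 2), bool)
        a[0, 0] = True
        b[1, 1] = True
        assert manders([_mask(a)], [_mask(b)]) == (0.0, 0.0)

    def test_zero_area_is_undefined(self):
        empty = _mask(np.zeros((2, 2), bool))
        full = _mask(np.ones((2, 2), bool))
        m1, m2 = manders([empty], [full])
        assert m1 is None and m2 == 0.0


def test_tanimoto_manders_reciprocal_identity(rng):
    """1/T = 1/M1 + 1/M2 - 1 whenever all three are positive."""
    for _ in range(200):
        a = rng.random((8, 8)) > 0.5
        b = rng.random((8, 8)) > 0.5
        a[0, 0] = b[0, 0] = True  # guarantee positive overlap
        res = tanimoto([_mask(a)], [_mask(b)])
        assert 1 / res.tanimoto == pytest.approx(1 / res.m1 + 1 / res.m2 - 1, abs=1e-12)


class TestColocMatrix:
    def _stacks(self, rng, names, n_sections=2):
        return {n: [_mask(rng.random((6, 6)) > 0.5) for _ in range(n_sections)] for n in names}

    def test_symmetric_with_unit_diagonal(self, rng):
        stacks = self._stacks(rng, ["a", "b", "c"])
        mat, results = coloc_matrix(stacks)
        np.testing.assert_allclose(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 1.0)

    def test_offdiagonals_match_pairwise_tanimoto(self, rng):
        stacks = self._stacks(rng, ["a", "b", "c"])
        mat, _ = coloc_matrix(stacks)
        for x in stacks:
            for y in stacks:
                if x != y:
                    assert mat.loc[x, y] == tanimoto(stacks[x], stacks[y]).tanimoto

    def test_two_peptides_two_by_two(self, rng):
        mat, _ = coloc_matrix(self._stacks(rng, ["a", "b"]))
        assert mat.shape == (2, 2)
        assert mat.loc["a", "a"] == 1.0 and mat.loc["b", "b"] == 1.0

    def test_empty_peptide_diagonal_missing_row_kept(self, rng):
        stacks = self._stacks(rng, ["a", "b"])
        stacks["c"] = [_mask(np.zeros((6, 6), bool)) for _ in range(2)]
        mat, _ = coloc_matrix(stacks)
        assert np.isnan(mat.loc["c", "c"])
        assert "c" in mat.index

    def test_report_and_heatmap_files(self, tmp_path, rng):
        stacks = self._stacks(rng, ["a", "b", "c"])
        mat, results = coloc_matrix(stacks)
        csv = write_coloc_report(results, tmp_path / "coloc.csv")
        png = plot_heatmap(mat, tmp_path / "heatmap.png")
        assert csv.exists() and png.stat().st_size > 0
        import pandas as pd

        table = pd.read_csv(csv)
        assert set(table.columns) >= {"peptide_a", "peptide_b", "tanimoto", "m1", "m2"}
        assert len(table) == 3


def test_mask_stack_round_trip(tmp_path, rng):
    masks = [
        BinaryMask(grid=rng.random((5, 5)) > 0.5, peptide=f"p{i}") for i in range(4)
    ]
    path = write_mask_stack(masks, tmp_path / "masks.tiff")
    back = read_mask_stack(path)
    assert len(back) == 4
    for m, b in zip(masks, back):
        np.testing.assert_array_equal(b.grid, m.grid)
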