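"""Cell segmentation, ion-image integration, composites, and layer stacks."""

import numpy as np
import pytest
from scipy import stats

from pepatlas import synthetic_data as sd
from pepatlas.cell_mapping import (
    CellLabelMap,
    export_layer_stack,
    integrate,
    integrate_raw,
    MappingImage,
    read_layer_stack,
    render_composite,
    segment_fluorescent_cells,
)
from pepatlas.msi_io import IonImage
from pepatlas.registration import GrayImage, TransformSpec


def _disc(grid, row, col, radius, value=200):
    rr, cc = np.mgrid[0 : grid.shape[0], 0 : grid.shape[1]]
    grid[(rr - row) ** 2 + (cc - col) ** 2 <= radius**2] = value
    return grid


def _full_frame_cells(shape, pixel_size=1.0):
    return CellLabelMap(
        grid=np.ones(shape, dtype=np.int32),
        n_cells=1,
        centroids_um=np.array([[shape[1] / 2.0, shape[0] / 2.0]]),
        diameters_um=np.array([10.0]),
        pixel_size=pixel_size,
    )


def _ion(grid, target=1000.0, tol=0.25):
    grid = np.asarray(grid, dtype=float)
    return IonImage(grid=grid, target_mz=target, tolerance=tol, max_intensity=grid.max())


class TestSegmentation:
    def test_two_blobs_found(self):
        grid = np.zeros((60, 60))
        _disc(grid, 15, 15, 4)
        _disc(grid, 45, 45, 5)
        cells = segment_fluorescent_cells(GrayImage(grid=grid, pixel_size=1.0))
        assert cells.n_cells == 2
        assert np.all((cells.diameters_um >= 4) & (cells.diameters_um <= 16.8))

    def test_blank_image_has_no_cells(self):
        cells = segment_fluorescent_cells(GrayImage(grid=np.zeros((30, 30)), pixel_size=1.0))
        assert cells.n_cells == 0

    def test_single_pixel_blob_filtered_out(self):
        grid = np.zeros((30, 30))
        grid[10, 10] = 255
        _disc(grid, 22, 22, 4)  # one valid cell so Otsu has two classes
        cells = segment_fluorescent_cells(GrayImage(grid=grid, pixel_size=1.0))
        assert cells.n_cells == 1
        assert cells.grid[10, 10] == 0

    def test_oversized_blob_filtered_out(self):
        grid = np.zeros((80, 80))
        _disc(grid, 40, 40, 20)  # 40 um "cell" exceeds the neuron size range
        cells = segment_fluorescent_cells(GrayImage(grid=grid, pixel_size=1.0))
        assert cells.n_cells == 0

    def test_missing_pixel_size_rejected(self):
        img = GrayImage(grid=np.zeros((10, 10)), pixel_size=1.0)
        img.pixel_size = 0.0
        with pytest.raises(ValueError, match="pixel_size"):
            segment_fluorescent_cells(img)


class TestIntegrate:
    def test_constant_ion_full_frame_cell(self):
        cells = _full_frame_cells((16, 16))
        out = integrate(_ion(np.ones((16, 16))), TransformSpec(), cells, msi_pixel_size=1.0)
        assert np.all(out.grid == 255)

    def test_zero_ion_image_maps_to_zero(self):
        cells = _full_frame_cells((16, 16))
        out = integrate(_ion(np.zeros((16, 16))), TransformSpec(), cells, msi_pixel_size=1.0)
        assert np.all(out.grid == 0)

    def test_support_never_exceeds_cell_mask(self, rng):
        grid = np.zeros((60, 60))
        _disc(grid, 20, 20, 4)
        _disc(grid, 40, 35, 5)
        cells = segment_fluorescent_cells(GrayImage(grid=grid, pixel_size=1.0))
        ion = _ion(rng.uniform(0, 10, size=(3, 3)))
        out = integrate(ion, TransformSpec(dx=2, dy=-1, theta=4), cells, msi_pixel_size=20.0)
        assert np.all((out.grid > 0) <= cells.mask())

    def test_masked_interior_matches_unmasked_resample(self, rng):
        from pepatlas.registration import apply_rigid_transform

        half = np.zeros((20, 20), dtype=np.int32)
        half[:, :10] = 1
        cells = CellLabelMap(
            grid=half,
            n_cells=1,
            centroids_um=np.array([[5.0, 10.0]]),
            diameters_um=np.array([10.0]),
            pixel_size=1.0,
        )
        ion = _ion(rng.uniform(0, 5, size=(4, 4)))
        spec = TransformSpec(dx=1.0, dy=0.5, theta=2.0)
        raw = integrate_raw(ion, spec, cells, msi_pixel_size=5.0)
        ref = apply_rigid_transform(
            GrayImage(grid=ion.grid, pixel_size=5.0), spec, (20, 20), 1.0
        )
        np.testing.assert_allclose(raw[:, :10], ref.grid[:, :10])
        assert np.all(raw[:, 10:] == 0)

    def test_monotone_in_ion_intensity(self, rng):
        cells = _full_frame_cells((12, 12))
        ion = rng.uniform(0, 3, size=(3, 3))
        a = integrate_raw(_ion(ion), TransformSpec(), cells, msi_pixel_size=4.0)
        b = integrate_raw(_ion(ion * 2.5), TransformSpec(), cells, msi_pixel_size=4.0)
        np.testing.assert_allclose(b, 2.5 * a, rtol=1e-12)

    def test_zero_cells_flagged_empty(self):
        cells = CellLabelMap(
            grid=np.zeros((10, 10), dtype=np.int32),
            n_cells=0,
            centroids_um=np.empty((0, 2)),
            diameters_um=np.empty(0),
            pixel_size=1.0,
        )
        out = integrate(_ion(np.ones((2, 2))), TransformSpec(), cells, msi_pixel_size=5.0)
        assert out.empty and np.all(out.grid == 0)

    def test_per_cell_intensity_tracks_truth_expression(self):
        """Mapped per-cell means recover which cells express the peptide and
        rank cells broadly like their true expression.

        The binary recovery (expressing vs non-expressing) is near-perfect;
        the continuous ranking is attenuated by pixel-split geometry — a
        5-14 um cell straddling 20 um pixel borders divides its signal —
        so only a coarser monotone association is required of it.
        """
        cfg = sd.PhantomConfig(seed=3)
        truth = sd.generate_phantom(cfg)
        # label map straight from the truth table: discs at the true positions
        rows, cols = cfg.image_shape()
        labels = np.zeros((rows, cols), dtype=np.int32)
        yy, xx = np.mgrid[0:rows, 0:cols]
        for i, row in truth.cells.iterrows():
            r2 = (xx + 0.5 - row.x_um) ** 2 + (yy + 0.5 - row.y_um) ** 2
            labels[r2 <= (row.diameter_um / 2) ** 2] = i + 1
        cells = CellLabelMap(
            grid=labels,
            n_cells=len(truth.cells),
            centroids_um=truth.cells[["x_um", "y_um"]].to_numpy(),
            diameters_um=truth.cells["diameter_um"].to_numpy(),
            pixel_size=cfg.microscopy_pixel_size,
        )
        from pepatlas import msi_io

        dataset = msi_io.tic_normalize(sd.render_msi(truth))
        ion = msi_io.extract_ion_image(dataset, cfg.peptide_mz["NP-4"], 0.5)
        raw = integrate_raw(ion, cfg.transform, cells, cfg.msi_pixel_size)
        per_cell = np.array(
            [raw[labels == lbl].mean() for lbl in range(1, cells.n_cells + 1)]
        )
        expr = truth.expression("NP-4")
        expressing = expr > 0
        u = stats.mannwhitneyu(per_cell[expressing], per_cell[~expressing]).statistic
        auc = u / (expressing.sum() * (~expressing).sum())
        assert auc >= 0.95
        rho = stats.spearmanr(per_cell, expr).statistic
        assert rho >= 0.8


class TestComposite:
    def _mapping(self, grid, name):
        return MappingImage(
            grid=np.asarray(grid, dtype=np.uint8), peptide=name, section="0", pixel_size=1.0
        )

    def test_single_red_layer(self):
        m = self._mapping(np.full((4, 4), 200), "a")
        rgb, legend = render_composite([m], {"a": (255, 0, 0)})
        np.testing.assert_array_equal(rgb[..., 0], m.grid)
        assert np.all(rgb[..., 1:] == 0)
        assert legend[0]["peptide"] == "a"

    def test_disjoint_layers_make_no_yellow(self):
        a = np.zeros((4, 4), dtype=np.uint8)
        b = np.zeros((4, 4), dtype=np.uint8)
        a[:2] = 255
        b[2:] = 255
        rgb, _ = render_composite(
            [self._mapping(a, "a"), self._mapping(b, "b")],
            {"a": (255, 0, 0), "b": (0, 255, 0)},
        )
        yellow = (rgb[..., 0] > 0) & (rgb[..., 1] > 0)
        assert not yellow.any()

    def test_overlapping_saturated_layers_make_yellow(self):
        full = np.full((4, 4), 255, dtype=np.uint8)
        rgb, _ = render_composite(
            [self._mapping(full, "a"), self._mapping(full, "b")],
            {"a": (255, 0, 0), "b": (0, 255, 0)},
        )
        np.testing.assert_array_equal(rgb[..., 0], 255)
        np.testing.assert_array_equal(rgb[..., 1], 255)
        np.testing.assert_array_equal(rgb[..., 2], 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            render_composite(
                [
                    self._mapping(np.zeros((4, 4), dtype=np.uint8), "a"),
                    self._mapping(np.zeros((5, 5), dtype=np.uint8), "b"),
                ],
                {"a": (255, 0, 0), "b": (0, 255, 0)},
            )


class TestLayerStack:
    def _mappings(self, rng, names):
        return [
            MappingImage(
                grid=rng.integers(0, 256, size=(8, 8), dtype=np.uint8).astype(np.uint8),
                peptide=name,
                section="0",
                pixel_size=1.0,
            )
            for name in names
        ]

    def test_page_order_and_round_trip(self, tmp_path, rng):
        names = [f"pep{i}" for i in range(23)]
        mappings = self._mappings(rng, names)
        path = export_layer_stack(mappings, tmp_path / "stack.tiff")
        back = read_layer_stack(path)
        assert [name for name, _ in back] == names
        for (_, page), m in zip(back, mappings):
            np.testing.assert_array_equal(page, m.grid)

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="no mapping"):
            export_layer_stack([], tmp_path / "empty.tiff")

    def test_duplicate_names_rejected(self, tmp_path, rng):
        mappings = self._mappings(rng, ["a", "a"])
        with pytest.raises(ValueError, match="duplicate"):
            export_layer_stack(mappings, tmp_path / "dup.tiff")
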