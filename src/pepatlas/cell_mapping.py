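"""Cell-level peptide mapping on the microscopy grid.

Fluorescence images of peptidergic cells are segmented into a label map;
each peptide's MSI ion image is resampled bilinearly onto the microscopy
grid and masked to the cell pixels, producing the per-peptide "mapping
image" that all colocalization and atlas steps consume.  Neurons in the
tissue measure roughly 5-14 um across, so segmentation filters connected
components by equivalent diameter in physical units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from skimage import filters, measure

from .msi_io import IonImage
from .registration import GrayImage, TransformSpec, apply_rigid_transform

DEFAULT_DIAMETER_RANGE_UM = (5.0, 14.0)


@dataclass
class CellLabelMap:
    """Connected-component cell segmentation with physical measurements."""

    grid: np.ndarray  # int labels, 0 = background, 1..n_cells
    n_cells: int
    centroids_um: np.ndarray  # (n_cells, 2) as (x, y) um
    diameters_um: np.ndarray  # equivalent diameters, um
    pixel_size: float

    def __post_init__(self):
        labels = np.unique(self.grid)
        labels = labels[labels > 0]
        if self.n_cells != len(labels) or (
            self.n_cells and (labels.min() != 1 or labels.max() != self.n_cells)
        ):
            raise ValueError("labels must be contiguous 1..n_cells")

    def mask(self) -> np.ndarray:
        return self.grid > 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": np.arange(1, self.n_cells + 1),
                "centroid_x_um": self.centroids_um[:, 0],
                "centroid_y_um": self.centroids_um[:, 1],
                "diameter_um": self.diameters_um,
            }
        )


@dataclass
class MappingImage:
    """Per-peptide cell-level map: ion intensity inside cell pixels, 8-bit."""

    grid: np.ndarray  # uint8 on the microscopy grid
    peptide: str
    section: str
    pixel_size: float
    scale_max: float = 0.0  # pre-quantization maximum used for 8-bit scaling
    empty: bool = False  # True when the section had no cells

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.dtype != np.uint8:
            raise ValueError("mapping images are 8-bit")


def segment_fluorescent_cells(
    fluor: GrayImage,
    threshold: float | None = None,
    diameter_range_um: tuple[float, float] = DEFAULT_DIAMETER_RANGE_UM,
    size_margin: float = 0.2,
) -> CellLabelMap:
    """Threshold + connected components + physical size filter.

    Otsu's threshold is used unless an explicit value is given.  Components
    whose equivalent diameter falls outside ``diameter_range_um`` are
    dropped (default 5-14 um, the neuron size range in this tissue); labels
    are then re-packed to 1..n.  ``size_margin`` relaxes the bounds by a
    relative fraction because a thresholded blob's apparent size depends on
    where the threshold cuts its edge profile.  Requires a physical pixel
    size.  Touching cells are not split; they appear as one component (and
    are removed by the size filter if the merge exceeds the upper bound).
    """
    if fluor.pixel_size is None or fluor.pixel_size <= 0:
        raise ValueError("segmentation needs a positive pixel_size in um")
    grid = np.asarray(fluor.grid, dtype=float)
    if threshold is None:
        if np.ptp(grid) == 0:
            return CellLabelMap(
                grid=np.zeros(grid.shape, dtype=np.int32),
                n_cells=0,
                centroids_um=np.empty((0, 2)),
                diameters_um=np.empty(0),
                pixel_size=fluor.pixel_size,
            )
        threshold = filters.threshold_otsu(grid)
    binary = grid > threshold
    labels = measure.label(binary, connectivity=2)
    props = measure.regionprops(labels)
    d_min, d_max = diameter_range_um
    d_min = d_min * (1.0 - size_margin)
    d_max = d_max * (1.0 + size_margin)
    keep = [
        p
        for p in props
        if d_min <= p.equivalent_diameter_area * fluor.pixel_size <= d_max
    ]
    out = np.zeros(grid.shape, dtype=np.int32)
    centroids = []
    diameters = []
    for new_label, p in enumerate(keep, start=1):
        out[labels == p.label] = new_label
        r, c = p.centroid
        centroids.append(((c + 0.5) * fluor.pixel_size, (r + 0.5) * fluor.pixel_size))
        diameters.append(p.equivalent_diameter_area * fluor.pixel_size)
    return CellLabelMap(
        grid=out,
        n_cells=len(keep),
        centroids_um=np.asarray(centroids).reshape(-1, 2),
        diameters_um=np.asarray(diameters),
        pixel_size=fluor.pixel_size,
    )


def integrate(
    ion_image: IonImage,
    transform: TransformSpec,
    cells: CellLabelMap,
    msi_pixel_size: float = 20.0,
    peptide: str = "",
    section: str = "",
    scale_max: float | None = None,
) -> MappingImage:
    """Resample an ion image onto the microscopy grid and mask to cells.

    The MSI grid is upsampled bilinearly through ``transform`` (which maps
    the MSI physical frame into the microscopy frame), zeroed outside cell
    pixels, and quantized to 8 bits against the section-wise maximum of the
    masked values (or ``scale_max``, e.g. a global maximum for
    cross-section comparability).  A section with no cells yields a valid
    all-zero mapping flagged ``empty``.
    """
    src = GrayImage(grid=ion_image.grid, bit_depth="float", pixel_size=msi_pixel_size)
    warped = apply_rigid_transform(src, transform, cells.grid.shape, cells.pixel_size)
    masked = np.where(cells.mask(), warped.grid, 0.0)
    peak = float(masked.max()) if scale_max is None else float(scale_max)
    if peak > 0:
        quantized = np.rint(np.clip(masked / peak, 0, 1) * 255.0).astype(np.uint8)
    else:
        quantized = np.zeros(masked.shape, dtype=np.uint8)
    return MappingImage(
        grid=quantized,
        peptide=peptide,
        section=section,
        pixel_size=cells.pixel_size,
        scale_max=peak,
        empty=cells.n_cells == 0,
    )


def integrate_raw(
    ion_image: IonImage,
    transform: TransformSpec,
    cells: CellLabelMap,
    msi_pixel_size: float = 20.0,
) -> np.ndarray:
    """The pre-quantization masked resample (float), for calibration/QC."""
    src = GrayImage(grid=ion_image.grid, bit_depth="float", pixel_size=msi_pixel_size)
    warped = apply_rigid_transform(src, transform, cells.grid.shape, cells.pixel_size)
    return np.where(cells.mask(), warped.grid, 0.0)


def render_composite(
    mappings: Sequence[MappingImage],
    colors: dict[str, tuple[int, int, int]],
) -> tuple[np.ndarray, list[dict]]:
    """Additively blend pseudocolored mapping layers into one RGB image.

    Each mapping is tinted with its peptide's RGB color (0-255), layers are
    summed, and channels clipped at 255.  Returns the uint8 RGB array and a
    legend (peptide name -> color) for the figure caption.
    """
    if not mappings:
        raise ValueError("no mapping images to composite")
    shape = mappings[0].grid.shape
    acc = np.zeros((*shape, 3), dtype=float)
    legend = []
    for m in mappings:
        if m.grid.shape != shape:
            raise ValueError(
                f"mapping {m.peptide!r} shape {m.grid.shape} != {shape}"
            )
        if m.peptide not in colors:
            raise KeyError(f"no color assigned for peptide {m.peptide!r}")
        rgb = np.asarray(colors[m.peptide], dtype=float)
        acc += m.grid[..., None] / 255.0 * rgb
        legend.append({"peptide": m.peptide, "color": tuple(int(v) for v in rgb)})
    return np.clip(acc, 0, 255).astype(np.uint8), legend


def export_mapping_png(mapping: MappingImage, path: str | Path) -> Path:
    """One grayscale PNG per peptide per section."""
    path = Path(path)
    Image.fromarray(mapping.grid, mode="L").save(path)
    return path


def export_layer_stack(mappings: Sequence[MappingImage], path: str | Path) -> Path:
    """All of a section's peptide mappings as one multi-page grayscale TIFF.

    Page order follows the input (peptide-table) order; page descriptions
    carry the peptide names.  Duplicate peptide names are rejected.
    """
    if not mappings:
        raise ValueError("no mapping images to stack")
    names = [m.peptide for m in mappings]
    if len(set(names)) != len(names):
        raise ValueError("duplicate peptide names in layer stack")
    shape = mappings[0].grid.shape
    for m in mappings:
        if m.grid.shape != shape:
            raise ValueError("all layers must share the same shape")
    path = Path(path)
    with tifffile.TiffWriter(path) as writer:
        for m in mappings:
            writer.write(m.grid, description=m.peptide, contiguous=False)
    return path


def read_layer_stack(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Read back a layer stack as (peptide name, page) pairs."""
    out = []
    with tifffile.TiffFile(path) as tif:
        for page in tif.pages:
            out.append((page.description, page.asarray()))
    return out
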