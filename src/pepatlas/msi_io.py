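"""imzML I/O, TIC normalization, and ion-image extraction.

An :class:`MSIDataset` holds one section's gridded pixel spectra exactly as
they live in an imzML + ibd pair: integer pixel coordinates on a rectangular
grid (20 um pitch by default), one m/z / intensity pair of arrays per pixel,
and a normalization flag.  Ion images are window sums around a target m/z on
that grid.  Reading and writing go through pyimzml; coordinates are 1-based
in imzML and 0-based (row-major, origin top-left, y down) in memory.
"""

from __future__ import annotations

import hashlib
import json
import re
import uuid as uuid_module
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from PIL import Image
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

DEFAULT_PIXEL_SIZE_UM = 20.0
DEFAULT_MZ_RANGE = (500.0, 4500.0)


_EMPTY_IMZML_TEMPLATE = """<?xml version="1.0" encoding="ISO-8859-1"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1">
  <cvList count="2">
    <cv uri="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" id="MS" version="3.65.0"/>
    <cv uri="https://raw.githubusercontent.com/imzML/imzML/master/imagingMS.obo" fullName="Imaging MS Ontology" id="IMS" version="0.9.1"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000031" name="{mode}" value=""/>
      <cvParam cvRef="IMS" accession="IMS:1000080" name="universally unique identifier" value="{{{uuid}}}"/>
      <cvParam cvRef="IMS" accession="IMS:1000091" name="ibd SHA-1" value="{sha1}"/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="pepatlas" version="0.1">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="pepatlas exporter"/>
    </software>
  </softwareList>
  <scanSettingsList count="1">
    <scanSettings id="scanSettings1">
      <cvParam cvRef="IMS" accession="IMS:1000042" name="max count of pixels x" value="0"/>
      <cvParam cvRef="IMS" accession="IMS:1000043" name="max count of pixels y" value="0"/>
    </scanSettings>
  </scanSettingsList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="export">
      <processingMethod order="1" softwareRef="pepatlas">
        <cvParam cvRef="MS" accession="MS:1000530" name="file format conversion" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run defaultInstrumentConfigurationRef="IC1" id="empty">
    <spectrumList count="0" defaultDataProcessingRef="export"/>
  </run>
</mzML>
"""


class CorruptPairError(IOError):
    """The imzML and ibd files do not form a consistent pair."""


class UnsupportedFormatError(IOError):
    """The imzML file uses a binary encoding this reader does not support."""


@dataclass
class MSIDataset:
    """Gridded pixel spectra for one MSI acquisition.

    ``coordinates`` are 0-based (x, y) grid indices; ``spectra`` is the
    parallel list of (mz, intensity) float arrays.  ``normalization`` is
    ``"raw"`` or ``"TIC"``.
    """

    coordinates: list[tuple[int, int]]
    spectra: list[tuple[np.ndarray, np.ndarray]]
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    mz_range: tuple[float, float] = DEFAULT_MZ_RANGE
    normalization: str = "raw"
    zero_tic_pixels: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.coordinates) != len(self.spectra):
            raise ValueError("coordinates and spectra must be parallel")
        if len(set(self.coordinates)) != len(self.coordinates):
            raise ValueError("pixel coordinates must be unique")
        for (x, y), (mz, inten) in zip(self.coordinates, self.spectra):
            if len(mz) != len(inten):
                raise ValueError(f"pixel ({x},{y}): m/z and intensity lengths differ")
            if len(mz) > 1 and not np.all(np.diff(mz) > 0):
                raise ValueError(f"pixel ({x},{y}): m/z axis not strictly increasing")
            if np.any(np.asarray(inten) < 0):
                raise ValueError(f"pixel ({x},{y}): negative intensities")

    @property
    def n_pixels(self) -> int:
        return len(self.coordinates)

    def grid_shape(self) -> tuple[int, int]:
        """(rows, cols) extent covering all pixels, as (max_y+1, max_x+1)."""
        if not self.coordinates:
            return (0, 0)
        xs = [c[0] for c in self.coordinates]
        ys = [c[1] for c in self.coordinates]
        return (max(ys) + 1, max(xs) + 1)

    def acquisition_mask(self) -> np.ndarray:
        """Boolean grid: True where a spectrum was acquired.

        Distinguishes measured zeros from off-tissue pixels that were never
        acquired (those render as 0 in ion images but are not data).
        """
        mask = np.zeros(self.grid_shape(), dtype=bool)
        for x, y in self.coordinates:
            mask[y, x] = True
        return mask

    def tic(self) -> np.ndarray:
        """Total ion count per pixel, in coordinate order."""
        return np.array([float(np.sum(inten)) for _, inten in self.spectra])


@dataclass
class IonImage:
    """2D window-sum intensity map for one target m/z."""

    grid: np.ndarray  # rows = y, cols = x
    target_mz: float
    tolerance: float
    max_intensity: float
    normalization: str = "raw"
    acquisition_mask: np.ndarray | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if np.any(self.grid < 0):
            raise ValueError("ion image intensities must be non-negative")


# ---------------------------------------------------------------------------
# imzML read/write


def write_imzml(dataset: MSIDataset, path: str | Path, mode: str = "processed") -> Path:
    """Write a dataset as a standards-conformant imzML + ibd pair.

    ``mode="processed"`` stores one m/z axis per pixel (the default and the
    form the vendor export uses for normalized data); ``"continuous"``
    requires every spectrum to share an identical m/z axis.
    """
    path = Path(path)
    if mode not in ("processed", "continuous"):
        raise ValueError(f"mode must be 'processed' or 'continuous', got {mode!r}")
    if mode == "continuous" and dataset.spectra:
        first = dataset.spectra[0][0]
        for mz, _ in dataset.spectra[1:]:
            if len(mz) != len(first) or not np.allclose(mz, first):
                raise ValueError("continuous mode requires a shared m/z axis")
    if dataset.n_pixels == 0:
        # pyimzml cannot emit a zero-spectrum file; write a minimal valid pair
        pair_uuid = uuid_module.uuid4()
        ibd_bytes = pair_uuid.bytes
        path.with_suffix(".ibd").write_bytes(ibd_bytes)
        path.write_text(
            _EMPTY_IMZML_TEMPLATE.format(
                mode=mode,
                uuid=str(pair_uuid).upper(),
                sha1=hashlib.sha1(ibd_bytes).hexdigest().upper(),
            )
        )
        return path
    with ImzMLWriter(str(path), mode=mode) as writer:
        for (x, y), (mz, inten) in zip(dataset.coordinates, dataset.spectra):
            writer.addSpectrum(np.asarray(mz, float), np.asarray(inten, float), (x + 1, y + 1))
    return path


def _parsed_uuid(parser: ImzMLParser) -> uuid_module.UUID | None:
    for param in parser.metadata.file_description.cv_params:
        if param[1] == "IMS:1000080":  # universally unique identifier
            return uuid_module.UUID(str(param[2]).strip("{}"))
    return None


def read_imzml(
    path: str | Path,
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM,
    mz_range: tuple[float, float] | None = None,
    normalization: str = "raw",
) -> MSIDataset:
    """Read an imzML + ibd pair into an :class:`MSIDataset`.

    Supports both "continuous" and "processed" binary modes.  The ibd UUID
    must match the imzML metadata and the ibd must be long enough for every
    declared array; otherwise a :class:`CorruptPairError` is raised and no
    partial dataset is returned.
    """
    path = Path(path)
    ibd_path = path.with_suffix(".ibd")
    if not path.exists() or not ibd_path.exists():
        raise FileNotFoundError(f"imzML/ibd pair incomplete for {path}")
    text_head = path.read_text(errors="replace")
    if "<spectrum " not in text_head:
        # zero-spectrum file: pyimzml cannot parse it, validate the pair here
        match = re.search(
            r'IMS:1000080"[^/>]*value="\{?([0-9a-fA-F-]{36})\}?"', text_head
        )
        with open(ibd_path, "rb") as fh:
            ibd_uuid = uuid_module.UUID(bytes=fh.read(16))
        if match and uuid_module.UUID(match.group(1)) != ibd_uuid:
            raise CorruptPairError(
                f"ibd UUID {ibd_uuid} does not match imzML UUID {match.group(1)}"
            )
        return MSIDataset(
            coordinates=[],
            spectra=[],
            pixel_size=pixel_size,
            mz_range=mz_range or DEFAULT_MZ_RANGE,
            normalization=normalization,
        )
    parser = ImzMLParser(str(path))
    try:
        declared = _parsed_uuid(parser)
        with open(ibd_path, "rb") as fh:
            ibd_uuid = uuid_module.UUID(bytes=fh.read(16))
        if declared is not None and ibd_uuid != declared:
            raise CorruptPairError(
                f"ibd UUID {ibd_uuid} does not match imzML UUID {declared}"
            )
        size_of = parser.sizeDict
        if parser.mzPrecision not in size_of or parser.intensityPrecision not in size_of:
            raise UnsupportedFormatError("unsupported binary encoding in imzML")
        ibd_size = ibd_path.stat().st_size
        needed = 0
        for off, ln, prec in zip(parser.mzOffsets, parser.mzLengths, [parser.mzPrecision] * len(parser.mzOffsets)):
            needed = max(needed, off + ln * size_of[prec])
        for off, ln in zip(parser.intensityOffsets, parser.intensityLengths):
            needed = max(needed, off + ln * size_of[parser.intensityPrecision])
        if ibd_size < needed:
            raise CorruptPairError(
                f"ibd file truncated: {ibd_size} bytes, {needed} required"
            )
        coordinates: list[tuple[int, int]] = []
        spectra: list[tuple[np.ndarray, np.ndarray]] = []
        all_mz: list[np.ndarray] = []
        for i, (x, y, *_z) in enumerate(parser.coordinates):
            mz, inten = parser.getspectrum(i)
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            coordinates.append((x - 1, y - 1))
            spectra.append((mz, inten))
            if len(mz):
                all_mz.append(mz)
    finally:
        parser.m.close()
    if mz_range is None:
        if all_mz:
            lo = min(float(a[0]) for a in all_mz)
            hi = max(float(a[-1]) for a in all_mz)
            mz_range = (min(lo, DEFAULT_MZ_RANGE[0]), max(hi, DEFAULT_MZ_RANGE[1]))
        else:
            mz_range = DEFAULT_MZ_RANGE
    return MSIDataset(
        coordinates=coordinates,
        spectra=spectra,
        pixel_size=pixel_size,
        mz_range=mz_range,
        normalization=normalization,
    )


# ---------------------------------------------------------------------------
# Normalization and image extraction


def tic_normalize(dataset: MSIDataset) -> MSIDataset:
    """Divide each pixel spectrum by its total ion count.

    Pixels whose spectrum sums to zero are left as zeros and listed in the
    returned dataset's ``zero_tic_pixels``.  Re-normalizing an already
    TIC-normalized dataset is rejected.
    """
    if dataset.normalization != "raw":
        raise ValueError("dataset is already normalized")
    spectra = []
    zero_pixels = []
    for (x, y), (mz, inten) in zip(dataset.coordinates, dataset.spectra):
        total = float(np.sum(inten))
        if total > 0:
            spectra.append((mz.copy(), np.asarray(inten, float) / total))
        else:
            spectra.append((mz.copy(), np.asarray(inten, float).copy()))
            zero_pixels.append((x, y))
    return MSIDataset(
        coordinates=list(dataset.coordinates),
        spectra=spectra,
        pixel_size=dataset.pixel_size,
        mz_range=dataset.mz_range,
        normalization="TIC",
        zero_tic_pixels=zero_pixels,
    )


def extract_ion_image(dataset: MSIDataset, target_mz: float, tolerance: float = 0.25) -> IonImage:
    """Window-sum ion image: pixel value = sum of intensities with
    |m/z - target| <= tolerance (inclusive); never-acquired pixels are 0.

    The display quantity "max intensity" (used to annotate per-peptide ion
    images) is carried on the result.  Tolerance is in Da (default +/-0.25, a reflectron-TOF peak
    width at peptide masses); use :func:`ppm_to_da` for a ppm window.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    lo_range, hi_range = dataset.mz_range
    if not (lo_range <= target_mz <= hi_range):
        raise ValueError(
            f"target m/z {target_mz} outside acquisition range {dataset.mz_range}"
        )
    grid = np.zeros(dataset.grid_shape(), dtype=float)
    for (x, y), (mz, inten) in zip(dataset.coordinates, dataset.spectra):
        lo = np.searchsorted(mz, target_mz - tolerance, side="left")
        hi = np.searchsorted(mz, target_mz + tolerance, side="right")
        grid[y, x] = float(np.sum(inten[lo:hi]))
    return IonImage(
        grid=grid,
        target_mz=target_mz,
        tolerance=tolerance,
        max_intensity=float(grid.max()) if grid.size else 0.0,
        normalization=dataset.normalization,
        acquisition_mask=dataset.acquisition_mask(),
    )


def ppm_to_da(target_mz: float, ppm: float) -> float:
    """Convert a ppm half-window to Da at a given m/z."""
    return target_mz * ppm * 1e-6


def average_spectrum(
    dataset: MSIDataset, bin_width: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Mean spectrum over all pixels on a common m/z binning.

    Returns (bin centers, mean intensity per bin), where each pixel
    contributes the sum of its intensities falling in a bin and the mean is
    taken over all pixels.
    """
    if dataset.n_pixels == 0:
        raise ValueError("cannot average an empty dataset")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = dataset.mz_range
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + np.arange(n_bins + 1) * bin_width
    acc = np.zeros(n_bins, dtype=float)
    for mz, inten in dataset.spectra:
        idx = np.clip(np.searchsorted(edges, mz, side="right") - 1, 0, n_bins - 1)
        np.add.at(acc, idx, inten)
    centers = edges[:-1] + bin_width / 2
    return centers, acc / dataset.n_pixels


# ---------------------------------------------------------------------------
# Ion-image export


def export_ion_image(image: IonImage, path: str | Path) -> Path:
    """Export an ion image as 32-bit float TIFF or 8-bit PNG preview.

    A JSON sidecar with the target m/z, tolerance, and max intensity is
    written next to the image so exports remain self-describing.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.grid.astype(np.float32))
    elif path.suffix.lower() == ".png":
        peak = image.max_intensity if image.max_intensity > 0 else 1.0
        preview = np.clip(image.grid / peak * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(preview, mode="L").save(path)
    else:
        raise ValueError(f"unsupported export format {path.suffix!r}")
    sidecar = {
        "target_mz": image.target_mz,
        "tolerance": image.tolerance,
        "max_intensity": image.max_intensity,
        "normalization": image.normalization,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def tic_image(dataset: MSIDataset) -> np.ndarray:
    """Per-pixel TIC rendered on the grid (off-tissue pixels 0)."""
    grid = np.zeros(dataset.grid_shape(), dtype=float)
    for (x, y), (_, inten) in zip(dataset.coordinates, dataset.spectra):
        grid[y, x] = float(np.sum(inten))
    return grid
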