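"""Synthetic ganglion phantoms with full ground truth.

A phantom emulates the measurement geometry of single-cell MSI on a small
oval neural tissue: fluorescently labelled cells of 5-14 um placed in an
ellipse divided into three expression domains (dorso-rostral, dorso-caudal,
ventral), rendered both as a high-resolution fluorescence/DIC microscopy
pair (1 um/px) and as a 20 um-pitch MSI dataset related to the microscopy
frame by a known rigid transform.  Every stage of the pipeline can be
checked against the truth tables: cell positions, per-cell peptide
expression, the generating transform, and pipeline-free colocalization
values computed directly from the cell table.

A phantom "animal" is a series of serial sections (36 by default, 10 um
apart) sharing the ellipse geometry smoothly scaled along z; cells are
drawn independently per section from the same regional programs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .msi_io import MSIDataset
from .registration import GrayImage, TransformSpec, _rotation_matrix

DEFAULT_N_SECTIONS = 36
DEFAULT_SECTION_THICKNESS_UM = 10.0

#: Default 6-channel peptide panel (synthetic names and m/z values inside
#: the m/z 500-4500 acquisition window; not real peptide masses).
DEFAULT_PEPTIDE_MZ: dict[str, float] = {
    "NP-1": 988.50,
    "NP-2": 1074.58,
    "NP-3": 1247.68,
    "NP-4": 1538.82,
    "NP-5": 2042.05,
    "NP-6": 3302.91,
}

#: Regional expression programs: peptide -> (expression probability, mean level).
DEFAULT_REGION_PROGRAMS: dict[str, dict[str, tuple[float, float]]] = {
    "dorso_rostral": {"NP-1": (0.7, 1.0), "NP-2": (0.7, 1.0), "NP-3": (0.7, 1.0)},
    "dorso_caudal": {"NP-1": (0.7, 1.0), "NP-2": (0.7, 1.0), "NP-3": (0.7, 1.0)},
    "ventral": {"NP-4": (0.8, 1.0), "NP-5": (0.8, 1.0), "NP-6": (0.8, 1.0)},
}

#: Coupled pairs: (peptide_a, peptide_b, joint probability of forced co-expression).
DEFAULT_CO_EXPRESSION: list[tuple[str, str, float]] = [("NP-1", "NP-2", 0.9)]


@dataclass
class PhantomConfig:
    """Everything needed to generate one phantom animal reproducibly."""

    seed: int = 0
    tissue_axes_um: tuple[float, float] = (300.0, 150.0)  # ellipse semi-axes (x, y)
    margin_um: float = 25.0
    n_cells: int = 50
    cell_diameter_range_um: tuple[float, float] = (5.0, 14.0)
    #: minimum center separation as a multiple of the larger diameter of a
    #: pair; 1.5 keeps soft-edged somata optically resolvable (two discs at
    #: exactly one diameter apart would fuse under thresholding)
    min_separation_factor: float = 1.5
    microscopy_pixel_size: float = 1.0
    msi_pixel_size: float = 20.0
    transform: TransformSpec = field(default_factory=lambda: TransformSpec(dx=8.0, dy=-6.0, theta=3.0))
    peptide_mz: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PEPTIDE_MZ))
    region_programs: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {r: dict(p) for r, p in DEFAULT_REGION_PROGRAMS.items()}
    )
    co_expression: list[tuple[str, str, float]] = field(
        default_factory=lambda: list(DEFAULT_CO_EXPRESSION)
    )
    noise_sd: float = 2.0  # additive Gaussian noise on microscopy renders
    cell_lognormal_sd: float = 0.25  # per-cell multiplicative intensity spread
    fluor_amplitude: float = 200.0
    peak_sd_da: float = 0.08
    mz_range: tuple[float, float] = (500.0, 4500.0)
    baseline_n_peaks: int = 30
    baseline_mean_intensity: float = 2.0
    n_sections: int = DEFAULT_N_SECTIONS
    section_thickness_um: float = DEFAULT_SECTION_THICKNESS_UM

    def __post_init__(self):
        for region, program in self.region_programs.items():
            for pep, (prob, level) in program.items():
                if not (0.0 <= prob <= 1.0):
                    raise ValueError(f"{region}/{pep}: probability {prob} outside [0, 1]")
                if pep not in self.peptide_mz:
                    raise ValueError(f"{region}: unknown peptide {pep!r}")
        for a, b, q in self.co_expression:
            if not (0.0 <= q <= 1.0):
                raise ValueError(f"co-expression probability {q} outside [0, 1]")
        d_lo, d_hi = self.cell_diameter_range_um
        ax, ay = self.tissue_axes_um
        if d_hi >= 2 * min(ax, ay):
            raise ValueError("cell diameter range exceeds tissue extent")
        if self.msi_pixel_size < self.microscopy_pixel_size:
            raise ValueError("MSI pixel size must be >= microscopy pixel size")

    @property
    def peptides(self) -> list[str]:
        return list(self.peptide_mz.keys())

    def image_shape(self) -> tuple[int, int]:
        """Microscopy grid (rows, cols) covering the tissue plus margin."""
        ax, ay = self.tissue_axes_um
        width = 2 * (ax + self.margin_um)
        height = 2 * (ay + self.margin_um)
        return (
            int(np.ceil(height / self.microscopy_pixel_size)),
            int(np.ceil(width / self.microscopy_pixel_size)),
        )

    def msi_shape(self) -> tuple[int, int]:
        rows, cols = self.image_shape()
        ps = self.microscopy_pixel_size / self.msi_pixel_size
        return (int(np.ceil(rows * ps)), int(np.ceil(cols * ps)))


@dataclass
class PhantomTruth:
    """Ground truth for one section: cells, regions, and the config used."""

    cells: pd.DataFrame  # id, x_um, y_um, diameter_um, region, expr_<pep>, fluor_factor
    region_map: np.ndarray  # 0 background, 1..3 region codes on the microscopy grid
    region_names: list[str]
    config: PhantomConfig
    section_index: int = 0
    axes_um: tuple[float, float] | None = None  # section-specific ellipse semi-axes

    def __post_init__(self):
        if self.axes_um is None:
            self.axes_um = self.config.tissue_axes_um

    def expression(self, peptide: str) -> np.ndarray:
        col = f"expr_{peptide}"
        if col not in self.cells.columns:
            raise KeyError(f"unknown peptide {peptide!r}")
        return self.cells[col].to_numpy()


def _section_rng(config: PhantomConfig, section_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, section_index, stream])


def _z_profile(section_index: int, n_sections: int) -> float:
    """Smooth elliptical scaling of the in-plane axes along the stack.

    End sections shrink to 60% of the central axes, approximating an
    ellipsoidal organ without making cell packing infeasible.
    """
    if n_sections <= 1:
        return 1.0
    u = 2.0 * section_index / (n_sections - 1) - 1.0
    return float(np.sqrt(1.0 - (0.8 * u) ** 2))


def region_label_map(config: PhantomConfig, axes_um: tuple[float, float]) -> tuple[np.ndarray, list[str]]:
    """Rasterize the three-domain partition of the tissue ellipse.

    The dorsal half (above the minor axis) splits into rostral (left) and
    caudal (right); the ventral half is one domain.  0 marks background.
    """
    rows, cols = config.image_shape()
    ps = config.microscopy_pixel_size
    cx = cols * ps / 2.0
    cy = rows * ps / 2.0
    y, x = np.mgrid[0:rows, 0:cols]
    xu = (x + 0.5) * ps
    yu = (y + 0.5) * ps
    ax, ay = axes_um
    inside = ((xu - cx) / ax) ** 2 + ((yu - cy) / ay) ** 2 <= 1.0
    names = ["dorso_rostral", "dorso_caudal", "ventral"]
    out = np.zeros((rows, cols), dtype=np.int8)
    dorsal = yu < cy
    out[inside & dorsal & (xu < cx)] = 1
    out[inside & dorsal & (xu >= cx)] = 2
    out[inside & ~dorsal] = 3
    return out, names


def generate_phantom(config: PhantomConfig, section_index: int = 0) -> PhantomTruth:
    """Place cells and draw their peptide programs for one section.

    Cell centers are rejection-sampled uniformly inside the (z-scaled)
    tissue ellipse with every cell fully inside the tissue and any two
    centers at least ``min_separation_factor`` times the larger diameter
    of the pair apart, so rendered somata never overlap or fuse.  Each
    cell's peptide set comes from its region's program; coupled pairs are
    forced on together with their joint probability first, then remaining
    peptides draw independently.  Fully reproducible from the config seed
    and section index.
    """
    rng = _section_rng(config, section_index, 0)
    factor = _z_profile(section_index, config.n_sections)
    axes = (config.tissue_axes_um[0] * factor, config.tissue_axes_um[1] * factor)
    rows, cols = config.image_shape()
    ps = config.microscopy_pixel_size
    cx = cols * ps / 2.0
    cy = rows * ps / 2.0
    d_lo, d_hi = config.cell_diameter_range_um

    centers: list[tuple[float, float]] = []
    diameters: list[float] = []
    max_attempts = 2000 * config.n_cells
    attempts = 0
    while len(centers) < config.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not pack {config.n_cells} cells in ellipse {axes} um "
                f"after {max_attempts} attempts ({len(centers)} placed); "
                "reduce n_cells or enlarge the tissue"
            )
        d = rng.uniform(d_lo, d_hi)
        x = cx + rng.uniform(-axes[0], axes[0])
        y = cy + rng.uniform(-axes[1], axes[1])
        # cell fully inside the ellipse: shrink the axes by the radius
        if ((x - cx) / (axes[0] - d / 2)) ** 2 + ((y - cy) / (axes[1] - d / 2)) ** 2 > 1.0:
            continue
        ok = True
        for (px, py), pd_ in zip(centers, diameters):
            min_sep = config.min_separation_factor * max(d, pd_)
            if (x - px) ** 2 + (y - py) ** 2 < min_sep**2:
                ok = False
                break
        if ok:
            centers.append((x, y))
            diameters.append(d)

    region_map, region_names = region_label_map(config, axes)
    records = []
    for i, ((x, y), d) in enumerate(zip(centers, diameters)):
        col = min(cols - 1, int(x / ps))
        row = min(rows - 1, int(y / ps))
        code = int(region_map[row, col])
        region = region_names[code - 1] if code > 0 else "ventral"
        program = config.region_programs.get(region, {})
        expressed: dict[str, bool] = {}
        for a, b, q in config.co_expression:
            if a in program and b in program and rng.random() < q:
                expressed[a] = True
                expressed[b] = True
        levels = {}
        for pep in config.peptides:
            if expressed.get(pep):
                on = True
            else:
                prob = program.get(pep, (0.0, 0.0))[0]
                on = rng.random() < prob
            if on:
                mean_level = program.get(pep, (0.0, 1.0))[1]
                levels[pep] = mean_level * rng.lognormal(0.0, config.cell_lognormal_sd)
            else:
                levels[pep] = 0.0
        records.append(
            {
                "id": i + 1,
                "x_um": x,
                "y_um": y,
                "diameter_um": d,
                "region": region,
                # the cell label (fluorescence) is uniform across cells; the
                # lognormal spread belongs to peptide expression intensity
                "fluor_factor": 1.0,
                **{f"expr_{pep}": levels[pep] for pep in config.peptides},
            }
        )
    columns = [
        "id",
        "x_um",
        "y_um",
        "diameter_um",
        "region",
        "fluor_factor",
        *[f"expr_{pep}" for pep in config.peptides],
    ]
    cells = pd.DataFrame(records, columns=columns)
    return PhantomTruth(
        cells=cells,
        region_map=region_map,
        region_names=region_names,
        config=config,
        section_index=section_index,
        axes_um=axes,
    )


def generate_animal(config: PhantomConfig) -> list[PhantomTruth]:
    """All serial sections of one phantom animal (config.n_sections)."""
    return [generate_phantom(config, z) for z in range(config.n_sections)]


# ---------------------------------------------------------------------------
# Rendering


def _paint_cells(
    shape: tuple[int, int],
    cells: pd.DataFrame,
    amplitudes: np.ndarray,
    pixel_size: float,
) -> np.ndarray:
    """Sum of per-cell soft-edged discs at grid resolution.

    Each cell is a Gaussian-edged disc of its nominal diameter — a
    supergaussian ``amp * exp(-(r / (d/2))**6)`` — so the rendered object
    measures its stated size under thresholding while keeping a unique,
    strictly interior intensity maximum at the centroid (a fluorophore
    fills the soma; the soft edge stands in for the optical PSF).
    """
    out = np.zeros(shape, dtype=float)
    rows, cols = shape
    for (x, y, d), amp in zip(
        cells[["x_um", "y_um", "diameter_um"]].itertuples(index=False), amplitudes
    ):
        if amp <= 0:
            continue
        radius = d / 2.0
        half = max(2, int(np.ceil(1.6 * radius / pixel_size)))
        c0 = int(x / pixel_size)
        r0 = int(y / pixel_size)
        r_lo, r_hi = max(0, r0 - half), min(rows, r0 + half + 1)
        c_lo, c_hi = max(0, c0 - half), min(cols, c0 + half + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        xu = (cc + 0.5) * pixel_size
        yu = (rr + 0.5) * pixel_size
        r2 = ((xu - x) ** 2 + (yu - y) ** 2) / radius**2
        out[r_lo:r_hi, c_lo:c_hi] += amp * np.exp(-(r2**3))
    return out


def render_microscopy(truth: PhantomTruth) -> tuple[GrayImage, GrayImage]:
    """Fluorescence and DIC-like channels at microscopy resolution.

    Every cell appears in the fluorescence channel (the labelling marks all
    peptidergic cells, not specific peptides) as a Gaussian disc scaled by
    its lognormal brightness factor; additive Gaussian noise (sd from the
    config) is applied and clipped at zero.  The DIC-like channel is the
    tissue outline: a flat interior with an edge gradient.
    """
    config = truth.config
    shape = config.image_shape()
    rng = _section_rng(config, truth.section_index, 1)
    amplitudes = config.fluor_amplitude * truth.cells["fluor_factor"].to_numpy()
    fluor = _paint_cells(shape, truth.cells, amplitudes, config.microscopy_pixel_size)
    if config.noise_sd > 0:
        fluor = fluor + rng.normal(0.0, config.noise_sd, size=shape)
    fluor = np.clip(fluor, 0, None)

    inside = truth.region_map > 0
    edge = ndimage.binary_dilation(inside, iterations=2) & ~ndimage.binary_erosion(
        inside, iterations=2
    )
    dic = inside.astype(float) * 120.0 + edge.astype(float) * 80.0
    if config.noise_sd > 0:
        dic = np.clip(dic + rng.normal(0.0, config.noise_sd, size=shape), 0, None)
    ps = config.microscopy_pixel_size
    return (
        GrayImage(grid=fluor, bit_depth="float", pixel_size=ps),
        GrayImage(grid=dic, bit_depth="float", pixel_size=ps),
    )


def peptide_field(truth: PhantomTruth, peptide: str) -> np.ndarray:
    """Continuous expression field for one peptide on the microscopy grid."""
    config = truth.config
    return _paint_cells(
        config.image_shape(),
        truth.cells,
        truth.expression(peptide),
        config.microscopy_pixel_size,
    )


def render_msi(truth: PhantomTruth, config: PhantomConfig | None = None) -> MSIDataset:
    """Forward-model the MSI acquisition of a phantom section.

    Each 20 um MSI pixel is placed in the microscopy frame through the truth
    transform (rotation about the MSI image center, then translation); its
    per-peptide intensity is the integral of the corresponding expression
    field over a 3x3 supersample of the pixel footprint (signal scales with
    the analyte amount under the pixel, so a whole cell contributes its
    full disc integral to whichever pixels cover it).  The pixel spectrum is a
    sum of Gaussian peaks (sd ``peak_sd_da``) at the expressed peptides'
    m/z values whose areas equal those intensities, plus sparse baseline
    noise peaks.  The result writes cleanly through ``write_imzml``.
    """
    config = config or truth.config
    for pep, mz in config.peptide_mz.items():
        if not (config.mz_range[0] <= mz <= config.mz_range[1]):
            raise ValueError(f"{pep}: m/z {mz} outside acquisition range {config.mz_range}")
    rng = _section_rng(config, truth.section_index, 2)
    msi_rows, msi_cols = config.msi_shape()
    ps_msi = config.msi_pixel_size
    ps_micro = config.microscopy_pixel_size
    micro_shape = config.image_shape()

    # MSI pixel centers (physical, MSI frame) with a 3x3 supersample each
    offsets = (np.arange(3) - 1) / 3.0 * ps_msi
    oy, ox = np.meshgrid(offsets, offsets, indexing="ij")
    jj, ii = np.meshgrid(np.arange(msi_cols), np.arange(msi_rows), indexing="xy")
    x_msi = (jj + 0.5) * ps_msi
    y_msi = (ii + 0.5) * ps_msi
    xs = x_msi[..., None] + ox.ravel()  # (rows, cols, 9)
    ys = y_msi[..., None] + oy.ravel()

    t = config.transform
    c_msi = np.array([msi_cols * ps_msi / 2.0, msi_rows * ps_msi / 2.0])
    r = _rotation_matrix(t.theta)
    x_mic = t.scale * (r[0, 0] * (xs - c_msi[0]) + r[0, 1] * (ys - c_msi[1])) + c_msi[0] + t.dx
    y_mic = t.scale * (r[1, 0] * (xs - c_msi[0]) + r[1, 1] * (ys - c_msi[1])) + c_msi[1] + t.dy
    col_idx = x_mic / ps_micro - 0.5
    row_idx = y_mic / ps_micro - 0.5

    # mean over the supersample x pixel area = integral of the field (um^2)
    area_factor = (ps_msi / ps_micro) ** 2
    intensities = {}
    for pep in config.peptides:
        fld = peptide_field(truth, pep)
        sampled = ndimage.map_coordinates(
            fld, [row_idx.ravel(), col_idx.ravel()], order=1, mode="constant", cval=0.0
        ).reshape(row_idx.shape)
        intensities[pep] = sampled.mean(axis=-1) * area_factor

    sd = config.peak_sd_da
    peak_offsets = np.arange(-4 * sd, 4 * sd + 1e-9, sd / 4.0)
    peak_weights = np.exp(-(peak_offsets**2) / (2 * sd**2))
    peak_weights = peak_weights / peak_weights.sum()

    coordinates: list[tuple[int, int]] = []
    spectra: list[tuple[np.ndarray, np.ndarray]] = []
    lo, hi = config.mz_range
    for row in range(msi_rows):
        for col in range(msi_cols):
            mz_parts = []
            int_parts = []
            for pep in config.peptides:
                level = intensities[pep][row, col]
                if level > 1e-9:
                    mz_parts.append(config.peptide_mz[pep] + peak_offsets)
                    int_parts.append(level * peak_weights)
            n_base = rng.poisson(config.baseline_n_peaks)
            if n_base > 0:
                mz_parts.append(rng.uniform(lo + 1.0, hi - 1.0, size=n_base))
                int_parts.append(rng.exponential(config.baseline_mean_intensity, size=n_base))
            if mz_parts:
                mz = np.concatenate(mz_parts)
                inten = np.concatenate(int_parts)
            else:
                mz = np.empty(0)
                inten = np.empty(0)
            keep = (mz >= lo) & (mz <= hi)
            mz, inten = mz[keep], inten[keep]
            uniq, inverse = np.unique(mz, return_inverse=True)
            summed = np.zeros(len(uniq))
            np.add.at(summed, inverse, inten)
            coordinates.append((col, row))
            spectra.append((uniq, summed))
    return MSIDataset(
        coordinates=coordinates,
        spectra=spectra,
        pixel_size=ps_msi,
        mz_range=config.mz_range,
        normalization="raw",
    )


# ---------------------------------------------------------------------------
# Ground-truth oracles


def truth_mask(truth: PhantomTruth, peptide: str) -> np.ndarray:
    """Boolean cell-disc mask of the cells expressing a peptide.

    Discs of radius diameter/2 at microscopy resolution — the pipeline-free
    reference geometry for colocalization.
    """
    config = truth.config
    rows, cols = config.image_shape()
    ps = config.microscopy_pixel_size
    out = np.zeros((rows, cols), dtype=bool)
    levels = truth.expression(peptide)
    y, x = np.mgrid[0:rows, 0:cols]
    for (cx, cy, d), level in zip(
        truth.cells[["x_um", "y_um", "diameter_um"]].itertuples(index=False), levels
    ):
        if level <= 0:
            continue
        r = d / 2.0
        c0 = int(cx / ps)
        r0 = int(cy / ps)
        half = int(np.ceil(r / ps)) + 1
        r_lo, r_hi = max(0, r0 - half), min(rows, r0 + half + 1)
        c_lo, c_hi = max(0, c0 - half), min(cols, c0 + half + 1)
        xu = (x[r_lo:r_hi, c_lo:c_hi] + 0.5) * ps
        yu = (y[r_lo:r_hi, c_lo:c_hi] + 0.5) * ps
        out[r_lo:r_hi, c_lo:c_hi] |= (xu - cx) ** 2 + (yu - cy) ** 2 <= r**2
    return out


def truth_coloc(
    truths: PhantomTruth | Sequence[PhantomTruth], peptide_a: str, peptide_b: str
) -> float:
    """Ground-truth pooled-area Tanimoto straight from the cell tables."""
    if isinstance(truths, PhantomTruth):
        truths = [truths]
    area_a = area_b = overlap = 0
    for truth in truths:
        ma = truth_mask(truth, peptide_a)
        mb = truth_mask(truth, peptide_b)
        area_a += int(ma.sum())
        area_b += int(mb.sum())
        overlap += int((ma & mb).sum())
    union = area_a + area_b - overlap
    return overlap / union if union > 0 else 0.0
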