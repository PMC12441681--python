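"""Pooled-area Tanimoto and Manders colocalization over section stacks.

Mapping images are lifted to 16-bit, binarized — by the fixed inclusive
range 8400-65535 by default, or by the intermodes auto-threshold — and the
foreground pixel areas of two peptides' stacks are pooled over all sections
before forming the coefficients:

    T  = overlap / (area_A + area_B - overlap)
    M1 = overlap / area_A
    M2 = overlap / area_B

T = 1 means complete colocalization, T = 0 none.  Whenever all three are
positive the identity 1/T = 1/M1 + 1/M2 - 1 holds exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .cell_mapping import MappingImage
from .registration import GrayImage

DEFAULT_BINARIZE_RANGE = (8400, 65535)
#: Descriptive operating point: pairs with T above this are called colocalized.
COLOC_CALL_THRESHOLD = 0.6


@dataclass
class BinaryMask:
    """Binarized mapping image; ``area`` is the foreground pixel count."""

    grid: np.ndarray  # bool
    section: str = ""
    peptide: str = ""

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.grid.sum())


@dataclass
class ColocResult:
    """Pairwise colocalization with the pixel areas that define it."""

    peptide_a: str
    peptide_b: str
    area_a: int
    area_b: int
    area_overlap: int
    tanimoto: float
    m1: float | None  # None when area_a == 0 (undefined)
    m2: float | None


def to_16bit(mapping: MappingImage | GrayImage) -> GrayImage:
    """Lift an 8-bit image to 16 bits by the exact factor 257 (255 -> 65535)."""
    if isinstance(mapping, MappingImage):
        grid = mapping.grid
        pixel_size = mapping.pixel_size
    else:
        if mapping.bit_depth != 8:
            raise ValueError("to_16bit expects an 8-bit image")
        grid = mapping.grid
        pixel_size = mapping.pixel_size
    if grid.dtype != np.uint8:
        raise ValueError("to_16bit expects uint8 data")
    return GrayImage(grid=grid.astype(np.uint16) * 257, bit_depth=16, pixel_size=pixel_size)


class ThresholdError(RuntimeError):
    """The histogram never became bimodal under iterative smoothing."""


def threshold_intermodes(image16: GrayImage | np.ndarray, max_iter: int = 10_000) -> int:
    """Intermodes auto-threshold on a 16-bit image.

    The 16-bit values are down-binned to 256 levels (exact inverse of the
    x257 lift), the histogram is repeatedly smoothed with a 3-bin running
    mean until exactly two local maxima survive, and the threshold is the
    midpoint of the two modes rescaled back to the 16-bit range.  Raises
    :class:`ThresholdError` if the histogram never becomes bimodal (e.g. a
    constant image); callers then fall back to the fixed range.
    """
    grid = image16.grid if isinstance(image16, GrayImage) else np.asarray(image16)
    levels = (grid.astype(np.int64) // 257).ravel()
    hist = np.bincount(levels, minlength=256).astype(float)

    def n_modes(h: np.ndarray) -> list[int]:
        modes = []
        for i in range(1, len(h) - 1):
            if h[i] > h[i - 1] and h[i] >= h[i + 1]:
                modes.append(i)
        return modes

    h = hist.copy()
    for _ in range(max_iter):
        modes = n_modes(h)
        if len(modes) == 2:
            midpoint = (modes[0] + modes[1]) / 2.0
            return int(round(midpoint * 257))
        if len(modes) < 2:
            raise ThresholdError("histogram is not bimodal; use the fixed range")
        # 3-bin running mean, zero beyond the histogram ends
        h = (np.concatenate(([0.0], h[:-1])) + h + np.concatenate((h[1:], [0.0]))) / 3.0
    raise ThresholdError(f"histogram did not become bimodal in {max_iter} iterations")


def binarize(
    image16: GrayImage | np.ndarray,
    lo: int = DEFAULT_BINARIZE_RANGE[0],
    hi: int = DEFAULT_BINARIZE_RANGE[1],
    section: str = "",
    peptide: str = "",
) -> BinaryMask:
    """Range binarization: foreground iff lo <= value <= hi (inclusive)."""
    if not (0 <= lo <= hi <= 65535):
        raise ValueError(f"invalid binarization range ({lo}, {hi})")
    grid = image16.grid if isinstance(image16, GrayImage) else np.asarray(image16)
    fg = (grid >= lo) & (grid <= hi)
    return BinaryMask(grid=fg, section=section, peptide=peptide)


# ---------------------------------------------------------------------------
# Stack statistics


def _pool_areas(
    stack_a: Sequence[BinaryMask | np.ndarray],
    stack_b: Sequence[BinaryMask | np.ndarray],
) -> tuple[int, int, int]:
    if len(stack_a) != len(stack_b):
        raise ValueError(
            f"section count mismatch: {len(stack_a)} vs {len(stack_b)}"
        )
    area_a = area_b = overlap = 0
    for ma, mb in zip(stack_a, stack_b):
        ga = ma.grid if isinstance(ma, BinaryMask) else np.asarray(ma, dtype=bool)
        gb = mb.grid if isinstance(mb, BinaryMask) else np.asarray(mb, dtype=bool)
        if ga.shape != gb.shape:
            raise ValueError("mask shapes differ within a section pair")
        area_a += int(ga.sum())
        area_b += int(gb.sum())
        overlap += int((ga & gb).sum())
    return area_a, area_b, overlap


def tanimoto(
    stack_a: Sequence[BinaryMask | np.ndarray],
    stack_b: Sequence[BinaryMask | np.ndarray],
    peptide_a: str = "A",
    peptide_b: str = "B",
) -> ColocResult:
    """Pooled-area Tanimoto (with M1/M2) for two section-aligned stacks.

    Areas are summed over all sections before the ratio is taken — one
    coefficient per pair for the whole stack, not a per-section mean.  Two
    empty stacks give T = 0 ("not colocalized" is the conservative report).
    """
    area_a, area_b, overlap = _pool_areas(stack_a, stack_b)
    union = area_a + area_b - overlap
    t = overlap / union if union > 0 else 0.0
    return ColocResult(
        peptide_a=peptide_a,
        peptide_b=peptide_b,
        area_a=area_a,
        area_b=area_b,
        area_overlap=overlap,
        tanimoto=t,
        m1=overlap / area_a if area_a > 0 else None,
        m2=overlap / area_b if area_b > 0 else None,
    )


def manders(
    stack_a: Sequence[BinaryMask | np.ndarray],
    stack_b: Sequence[BinaryMask | np.ndarray],
) -> tuple[float | None, float | None]:
    """Manders' M1 = overlap/area_A and M2 = overlap/area_B.

    A coefficient whose own area is zero is undefined and reported as None.
    """
    area_a, area_b, overlap = _pool_areas(stack_a, stack_b)
    m1 = overlap / area_a if area_a > 0 else None
    m2 = overlap / area_b if area_b > 0 else None
    return m1, m2


def coloc_matrix(
    stacks: dict[str, Sequence[BinaryMask | np.ndarray]],
    order: Sequence[str] | None = None,
    precursors: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, list[ColocResult]]:
    """Pairwise Tanimoto matrix over all peptides.

    Row/column order follows ``order`` (default: insertion order of
    ``stacks``), grouped by precursor when a peptide->precursor mapping is
    given.  The diagonal is 1 for nonempty peptides and NaN for peptides
    whose stack has no foreground anywhere (row retained).
    """
    names = list(order) if order is not None else list(stacks.keys())
    if len(names) < 2:
        raise ValueError("colocalization matrix needs at least 2 peptides")
    n_sections = {name: len(stacks[name]) for name in names}
    if len(set(n_sections.values())) != 1:
        raise ValueError(f"section counts differ across peptides: {n_sections}")
    if precursors:
        names = sorted(names, key=lambda n: (precursors.get(n, n), names.index(n)))
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    results = []
    areas = {name: sum(int(np.asarray(m.grid if isinstance(m, BinaryMask) else m).sum()) for m in stacks[name]) for name in names}
    for name in names:
        if areas[name] == 0:
            mat.loc[name, name] = math.nan
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = tanimoto(stacks[a], stacks[b], a, b)
            results.append(res)
            mat.loc[a, b] = res.tanimoto
            mat.loc[b, a] = res.tanimoto
    return mat, results


def write_coloc_report(results: Sequence[ColocResult], path: str | Path) -> Path:
    rows = [
        {
            "peptide_a": r.peptide_a,
            "peptide_b": r.peptide_b,
            "area_a": r.area_a,
            "area_b": r.area_b,
            "area_overlap": r.area_overlap,
            "tanimoto": r.tanimoto,
            "m1": r.m1,
            "m2": r.m2,
        }
        for r in results
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def plot_heatmap(matrix: pd.DataFrame, path: str | Path, cmap: str = "viridis") -> Path:
    """Render the Tanimoto matrix as a labelled heatmap PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(matrix)),) * 2)
    im = ax.imshow(matrix.values, vmin=0, vmax=1, cmap=cmap)
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Tanimoto coefficient")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def write_mask_stack(masks: Sequence[BinaryMask], path: str | Path) -> Path:
    """Mask stack as multi-page 1-bit-per-sample TIFF (stored as uint8 0/255)."""
    if not masks:
        raise ValueError("empty mask stack")
    path = Path(path)
    with tifffile.TiffWriter(path) as writer:
        for m in masks:
            writer.write(
                (m.grid.astype(np.uint8) * 255), description=m.peptide, contiguous=False
            )
    return path


def read_mask_stack(path: str | Path) -> list[BinaryMask]:
    out = []
    with tifffile.TiffFile(path) as tif:
        for page in tif.pages:
            out.append(BinaryMask(grid=page.asarray() > 0, peptide=page.description))
    return out
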