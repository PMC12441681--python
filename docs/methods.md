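# Methods

This note documents the models, conventions, parameters, and numerical
choices behind `pepatlas`, and what the synthetic phantoms do and do not
establish about behavior on real data.

## Measurement model and coordinate conventions

All images live on physical grids. Pixel (row, col) has its center at
`((col + 0.5)·p, (row + 0.5)·p)` µm with pixel size `p`, origin at the
top-left corner and y increasing downward; imzML's 1-based pixel indices are
converted to 0-based indices at the I/O boundary. A rigid transform
(`TransformSpec`) maps source-frame physical coordinates to target-frame
coordinates as

    p_tgt = s · R(θ) · (p_src − c_src) + c_src + (dx, dy)

with rotation θ counter-clockwise (display sense) about the **source image
center** `c_src`, scale `s` (default 1 — pixel sizes already carry grid
resolution), and translation in µm. The pivot choice makes the inverse
transform well-defined from the source geometry alone and matches how
interactive alignment tools behave. Resampling maps each output pixel
center through the inverse transform and interpolates bilinearly
(`scipy.ndimage.map_coordinates`, order 1); samples outside the source are
0 and are excluded from downstream statistics via a validity mask. The MSI
grid is always resampled onto the microscopy grid (never the reverse), so
cell-scale geometry is preserved.

## MSI data handling

Spectra are stored per pixel as parallel m/z / intensity arrays
(imzML "processed" mode; "continuous" mode is supported when all pixels
share one axis). TIC normalization divides each spectrum by its intensity
sum — the plain per-spectrum reading of "normalized by total ion count";
zero-TIC pixels are left untouched and reported. Ion images are inclusive
window sums, `|m/z − target| ≤ tol`, with `tol` defaulting to ±0.25 Da
(a reflectron-TOF peak width at peptide masses; configurable in Da or ppm).
Sum (not max) aggregation keeps the extraction linear in intensities, so
ion images over a partition of the m/z axis add up exactly to the TIC
image. Never-acquired pixels are distinguished from measured zeros by an
acquisition mask.

## Microscopy preprocessing and segmentation

Auto-contrast rescales the [0.35, 99.65] percentile window onto 0–255
(the exact percentiles of the emulated interactive "auto" mode are not
published, so they are parameters). Background subtraction estimates the
background by grayscale opening with a rolling ball (or paraboloid-like
ellipsoid) element, radius 25 px by default, and clamps the difference at
zero. Cell segmentation is deliberately simple and fully parameterized:
Otsu threshold (or an explicit value), 8-connected components, and a
physical size filter keeping components whose equivalent diameter lies in
5–14 µm — the neuron size range in the target tissue — relaxed by a
±20 % measurement margin because a thresholded blob's apparent diameter
depends on where the threshold cuts its edge profile. Touching cells are
not split; merged components exceeding the upper size bound are discarded.

## Integration and colocalization

Each peptide's ion image is resampled onto the microscopy grid through the
section transform, masked to cell pixels, and quantized to 8 bits against
the section-wise per-peptide maximum (a global-max mode exists for
cross-section comparability). Mapping images are lifted to 16 bits by the
exact factor 257 (0→0, 255→65535) and binarized by the fixed inclusive
range **8400–65535** by default; the intermodes auto-threshold (iterative
3-bin mean smoothing of the 256-level histogram until exactly two modes
survive, threshold at their midpoint, zero padding beyond the histogram
ends) is provided as an alternative and fails explicitly on unimodal
histograms so callers can fall back to the fixed range. The fixed range is
the default because it is deterministic and reproduces the published
operating point.

Colocalization pools foreground pixel areas over **all sections of the
stack** before forming the coefficients — one coefficient per pair per
animal, not a per-section average:

    T  = overlap / (A + B − overlap),   M1 = overlap / A,   M2 = overlap / B.

Conventions: two empty stacks give T = 0 ("not colocalized" is the
conservative report); a Manders coefficient whose own area is zero is
undefined and reported as missing; an all-empty peptide keeps its matrix
row with a missing diagonal. The descriptive operating point for calling a
pair colocalized is T > 0.6; it is a configuration constant, not a test.

## 3D atlas

Per-peptide mask stacks are assembled into anisotropic voxel volumes
(z spacing 10 µm — the section thickness — against the in-plane microscopy
pixel size); an optional integer block-max downsampling factor is recorded
on the volume and in the scene manifest. Meshes come from marching cubes
at level 0.5 after zero-padding by one voxel (so foreground touching the
stack boundary still closes), with vertices shifted back into the volume's
physical frame; voxels stay anisotropic and vertices are scaled into µm
rather than resampling the data. Note the isosurface joins voxels sharing
a face or an edge but not corner-only neighbors, so mesh body counts
mirror **18-connected** volume components. STL output is binary by default
(80-byte header, 4-byte count, 50 bytes per triangle → file size
84 + 50·n) with an ASCII option; no inter-section re-registration is
applied along z.

## Peptide arithmetic

Monoisotopic [M+zH]z+ masses use a standard residue table with water
18.010565 Da and proton 1.007276 Da (the MALDI [M+H]+ convention).
Fragment series are singly charged b (prefix + proton) and y (suffix +
water + proton) ions for cleavage sites 1..n−1; C-terminal modifications
(e.g. the −0.98402 Da amidation carried by most mature neuropeptides) ride
on y ions only, N-terminal ones on b ions. Matching is greedy on smallest
absolute ppm error (ties: lower fragment index), each ion and peak used at
most once, with a 500 ppm default tolerance — wide enough to accommodate
the few-hundred-ppm fragment errors typical of on-tissue MS/MS. The
reported figure of merit is the mean absolute ppm error of matched pairs.

## Synthetic phantoms

A phantom emulates the geometry and contrast of the real experiment, not
its detailed physics. Defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| tissue ellipse semi-axes | 300 × 150 µm | a small oval central ganglion, sub-millimeter scale |
| regions | dorso-rostral / dorso-caudal / ventral | dorsal half split at the midline, ventral half whole |
| cells per section | 50 | dense enough for pairwise statistics, sparse enough to resolve |
| cell diameters | uniform 5–14 µm | the tissue's neuron size range |
| min center separation | 1.5 × larger diameter | keeps soft-edged somata resolvable; at exactly one diameter two discs fuse under any near-half-max threshold |
| microscopy / MSI pixel | 1 µm / 20 µm | confocal-scale reference vs MSI lateral resolution |
| sections per animal | 36, 10 µm apart | whole-organ serial stack; in-plane axes scale smoothly to 60 % at the ends (ellipsoid-like profile) |
| true transform | dx 8 µm, dy −6 µm, θ 3° | modest misalignment typical of manual mounting |
| expression spread | lognormal, sd 0.25 | per-cell peptide intensity variation |
| microscopy noise | additive Gaussian, sd 2 (amplitude 200) | low-noise confocal baseline |
| MSI peaks | Gaussian, sd 0.08 Da | reflectron-TOF peak width |
| baseline | ~Poisson(30) peaks/spectrum, Exp(2) intensities | chemical noise floor |

Cells are rejection-sampled uniformly in the (z-scaled) ellipse; each
cell's peptide set is drawn from its region's program, with coupled pairs
forced on together with their joint probability first (default: NP-1/NP-2
at 0.9 in the dorsal domains). The fluorescence channel renders every cell
at a uniform amplitude — the label marks peptidergic cells, not specific
peptides — as a soft-edged disc `exp(−(r/(d/2))⁶)`, which measures its
nominal diameter under thresholding while keeping a unique interior
maximum. MSI pixel intensities are the *integral* of the expression field
under the (transformed) pixel footprint, sampled 3×3, so signal scales
with analyte amount; spectra are Gaussian peaks with those areas plus
baseline noise. Everything is reproducible from `(seed, section index)`.

Ground-truth colocalization (`truth_coloc`) rasterizes hard discs of the
expressing cells and pools areas exactly like the pipeline, but straight
from the cell table — the pipeline-free reference.

**What the phantoms do not show.** No matrix crystal artifacts, isotope
envelopes, detector saturation, ionization suppression, or z-continuity of
cells across sections (each section draws cells independently); noise
levels are conventions, not fits to any instrument. Passing recovery tests
therefore demonstrates the correctness and stability of the *computation*,
not instrument-level performance on real acquisitions.

**Known attenuation.** A 5–14 µm cell straddling 20 µm pixel borders
splits its signal up to four ways, so per-cell *quantification* is
position-dependent: mapped per-cell means separate expressing from
non-expressing cells nearly perfectly (AUC ≥ 0.95 in tests) but rank
expressing cells by level only coarsely (Spearman ≈ 0.82–0.90 across
seeds). Binary-mask colocalization is insensitive to this; intensity-based
downstream analyses would not be.

## Numerical choices and degenerate inputs

- Constant images auto-contrast to all zeros (no contrast to stretch).
- Empty (zero-pixel) MSI datasets write and read as a valid zero-spectrum
  imzML + ibd pair; duplicate pixel coordinates, truncated ibd files, and
  UUID mismatches are hard errors with no partial results.
- Zero-TIC spectra stay zero and are listed, never divided.
- Greedy fragment matching breaks exact ppm ties by lower fragment index;
  results are invariant to observed-peak order.
- Intermodes thresholding raises after 10,000 smoothing iterations or on
  unimodal histograms rather than guessing.
- Both-empty Tanimoto is 0; zero-area Manders coefficients are missing,
  not 0 or NaN-propagated.
- An empty section (no segmented cells) yields a valid all-zero mapping
  flagged `empty`, not an error, so stacks keep their section alignment.
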