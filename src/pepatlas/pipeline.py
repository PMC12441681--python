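"""End-to-end convenience driver: phantom section -> per-peptide masks.

Chains the full measurement-and-analysis path on a phantom section exactly
as it runs on real data: render microscopy and MSI, auto-contrast to 8 bits,
segment the fluorescent cells, TIC-normalize the spectra, extract each
peptide's ion image, integrate it onto the microscopy grid through the
section transform, lift to 16 bits, and binarize with the fixed inclusive
range.  The synthetic truth enters only through the rendered data and the
known transform — never through the analysis itself.
"""

from __future__ import annotations

import numpy as np

from . import cell_mapping, colocalization, msi_io, registration, synthetic_data
from .colocalization import BinaryMask
from .synthetic_data import PhantomConfig, PhantomTruth


def section_masks(
    truth: PhantomTruth,
    ion_tolerance_da: float = 0.5,
    binarize_range: tuple[int, int] = colocalization.DEFAULT_BINARIZE_RANGE,
    subtract_bg: bool = False,
) -> dict[str, BinaryMask]:
    """Run the full pipeline on one phantom section.

    Returns one binarized mapping mask per peptide channel.  Background
    subtraction is optional (the phantom has a flat background; on real
    images it precedes auto-contrast).
    """
    config = truth.config
    fluor, _dic = synthetic_data.render_microscopy(truth)
    if subtract_bg:
        fluor = registration.subtract_background(fluor)
    fluor8 = registration.to_8bit_autocontrast(fluor)
    cells = cell_mapping.segment_fluorescent_cells(fluor8)

    dataset = synthetic_data.render_msi(truth)
    dataset = msi_io.tic_normalize(dataset)

    masks: dict[str, BinaryMask] = {}
    section_id = str(truth.section_index)
    for pep, mz in config.peptide_mz.items():
        ion = msi_io.extract_ion_image(dataset, mz, tolerance=ion_tolerance_da)
        mapping = cell_mapping.integrate(
            ion,
            config.transform,
            cells,
            msi_pixel_size=config.msi_pixel_size,
            peptide=pep,
            section=section_id,
        )
        image16 = colocalization.to_16bit(mapping)
        masks[pep] = colocalization.binarize(
            image16, *binarize_range, section=section_id, peptide=pep
        )
    return masks


def animal_mask_stacks(
    config: PhantomConfig,
    n_sections: int | None = None,
    **kwargs,
) -> tuple[dict[str, list[BinaryMask]], list[PhantomTruth]]:
    """Pipeline mask stacks for all sections of a phantom animal.

    Returns (peptide -> per-section masks, per-section truths); the truths
    let callers compare against :func:`synthetic_data.truth_coloc`.
    """
    if n_sections is not None:
        config = synthetic_data.replace(config, n_sections=n_sections)
    truths = synthetic_data.generate_animal(config)
    stacks: dict[str, list[BinaryMask]] = {pep: [] for pep in config.peptides}
    for truth in truths:
        masks = section_masks(truth, **kwargs)
        for pep, mask in masks.items():
            stacks[pep].append(mask)
    return stacks, truths
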