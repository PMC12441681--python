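"""Peptide target bookkeeping and MS/MS verification arithmetic.

Monoisotopic [M+zH]z+ masses, singly charged b/y fragment series, and
ppm-tolerance matching of observed MS/MS peaks against the theoretical
series.  Masses follow the MALDI [M+H]+ convention: residue monoisotopic
masses plus one water for the intact chain, plus one proton per charge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

PROTON = 1.007276
WATER = 18.010565

#: Monoisotopic residue masses (Da) for the 20 canonical one-letter codes.
RESIDUE_MASSES = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Common post-translational mass deltas (Da). C-terminal amidation is the
#: modification carried by most mature neuropeptides in this pipeline.
KNOWN_MODIFICATIONS = {
    "amidation": -0.98402,
    "pyroglutamate_from_Q": -17.026549,
    "oxidation": 15.994915,
}

Modification = tuple[str, float]


class UnknownResidueError(ValueError):
    """Sequence contains a non-canonical residue code."""

    def __init__(self, sequence: str, position: int):
        self.position = position
        super().__init__(
            f"unknown residue {sequence[position]!r} at position {position} "
            f"in sequence {sequence!r}"
        )


def _validate_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("peptide sequence must be non-empty")
    for i, residue in enumerate(sequence):
        if residue not in RESIDUE_MASSES:
            raise UnknownResidueError(sequence, i)


def _mod_mass(modifications: Iterable[Modification] | None) -> float:
    return sum(delta for _, delta in modifications) if modifications else 0.0


def monoisotopic_mz(
    sequence: str,
    modifications: Iterable[Modification] | None = None,
    charge: int = 1,
) -> float:
    """Monoisotopic m/z of [M + zH]z+ for a peptide.

    Parameters
    ----------
    sequence : str
        Residue string using the 20 canonical one-letter codes.
    modifications : iterable of (label, delta) pairs
        Mass deltas in Da added to the neutral mass, e.g.
        ``[("amidation", -0.98402)]``.
    charge : int
        Positive charge state z.

    Returns
    -------
    float
        (sum of residue masses + water + sum of deltas + z protons) / z.
    """
    _validate_sequence(sequence)
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    neutral = sum(RESIDUE_MASSES[r] for r in sequence) + WATER + _mod_mass(modifications)
    return (neutral + charge * PROTON) / charge


def neutral_mass(sequence: str, modifications: Iterable[Modification] | None = None) -> float:
    """Neutral monoisotopic peptide mass M in Da."""
    _validate_sequence(sequence)
    return sum(RESIDUE_MASSES[r] for r in sequence) + WATER + _mod_mass(modifications)


@dataclass(frozen=True)
class FragmentIon:
    """One theoretical backbone fragment (singly charged b or y ion)."""

    series: str  # "b" or "y"
    index: int  # 1 .. len(sequence) - 1
    mz: float
    charge: int = 1

    def __post_init__(self):
        if self.series not in ("b", "y"):
            raise ValueError(f"series must be 'b' or 'y', got {self.series!r}")
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")


@dataclass
class PeptideRecord:
    """One row of the peptide target table.

    ``target_mz`` is checked against the computed monoisotopic value on
    construction so the table cannot silently drift from the arithmetic.
    """

    name: str
    sequence: str
    modifications: list[Modification] = field(default_factory=list)
    charge: int = 1
    target_mz: float | None = None
    precursor: str | None = None  # shared-precursor grouping for heatmaps

    def __post_init__(self):
        computed = monoisotopic_mz(self.sequence, self.modifications, self.charge)
        if self.target_mz is None:
            self.target_mz = computed
        elif abs(self.target_mz - computed) > 1e-4:
            raise ValueError(
                f"{self.name}: target_mz {self.target_mz} differs from computed "
                f"{computed:.5f} by more than 1e-4 Da"
            )


def fragment_ions(
    sequence: str,
    modifications: Iterable[Modification] | None = None,
    series: Sequence[str] = ("b", "y"),
) -> list[FragmentIon]:
    """Singly charged b and/or y ions for cleavage sites 1..len-1.

    b_i = prefix residues + proton; y_i = suffix residues + water + proton.
    Modification placement follows mature-peptide convention: labels
    containing "amid" or starting with "cterm" ride on y ions, labels
    starting with "nterm" or "pyro" on b ions.  A single-residue peptide
    has no cleavage site and yields an empty list.
    """
    _validate_sequence(sequence)
    mods = list(modifications) if modifications else []
    n_term_delta = 0.0
    c_term_delta = 0.0
    for label, delta in mods:
        key = label.lower()
        if "amid" in key or key.startswith("cterm"):
            c_term_delta += delta
        else:
            n_term_delta += delta

    ions: list[FragmentIon] = []
    n = len(sequence)
    prefix = 0.0
    suffix_masses = [RESIDUE_MASSES[r] for r in sequence]
    total = sum(suffix_masses)
    for i in range(1, n):
        prefix += suffix_masses[i - 1]
        if "b" in series:
            ions.append(FragmentIon("b", i, prefix + n_term_delta + PROTON))
        if "y" in series:
            suffix = total - prefix
            ions.append(FragmentIon("y", n - i, suffix + c_term_delta + WATER + PROTON))
    return ions


@dataclass
class MatchResult:
    """Outcome of matching observed MS/MS peaks to a theoretical series."""

    pairs: list[tuple[float, FragmentIon, float]]  # (observed mz, ion, ppm error)
    mean_abs_error_ppm: float
    n_matched: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "observed_mz": obs,
                    "series": ion.series,
                    "index": ion.index,
                    "theoretical_mz": ion.mz,
                    "error_ppm": err,
                }
                for obs, ion, err in self.pairs
            ]
        )


def match_fragments(
    observed_peaks: Sequence[float],
    peptide: PeptideRecord,
    tolerance_ppm: float = 500.0,
) -> MatchResult:
    """Greedily match each theoretical b/y ion to at most one observed peak.

    Candidate (ion, peak) pairs within ``tolerance_ppm`` are taken in order
    of increasing |ppm error| (ties: lower fragment index); each ion and
    each peak is used at most once.  The reported figure of merit is the
    mean absolute ppm error over matched pairs — on-tissue MS/MS typically
    yields fragment errors of a few hundred ppm.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance must be positive")
    theoretical = fragment_ions(peptide.sequence, peptide.modifications)
    if not theoretical:
        raise ValueError(
            f"{peptide.name}: single-residue peptide has no fragment ions to match"
        )
    candidates = []
    for ion_idx, ion in enumerate(theoretical):
        for peak_idx, obs in enumerate(observed_peaks):
            err = (obs - ion.mz) / ion.mz * 1e6
            if abs(err) <= tolerance_ppm:
                candidates.append((abs(err), ion.index, ion_idx, peak_idx, obs, err))
    candidates.sort(key=lambda c: (c[0], c[1]))
    used_ions: set[int] = set()
    used_peaks: set[int] = set()
    pairs = []
    for _, _, ion_idx, peak_idx, obs, err in candidates:
        if ion_idx in used_ions or peak_idx in used_peaks:
            continue
        used_ions.add(ion_idx)
        used_peaks.add(peak_idx)
        pairs.append((obs, theoretical[ion_idx], err))
    pairs.sort(key=lambda p: (p[1].series, p[1].index))
    mean_abs = sum(abs(p[2]) for p in pairs) / len(pairs) if pairs else 0.0
    return MatchResult(pairs=pairs, mean_abs_error_ppm=mean_abs, n_matched=len(pairs))


# ---------------------------------------------------------------------------
# Peptide table I/O


def _parse_modifications(text: str) -> list[Modification]:
    """Parse 'label:delta;label:delta' (empty string -> no modifications)."""
    if not text or (isinstance(text, float) and pd.isna(text)):
        return []
    mods = []
    for item in str(text).split(";"):
        item = item.strip()
        if not item:
            continue
        label, _, delta = item.partition(":")
        mods.append((label.strip(), float(delta)))
    return mods


def _format_modifications(mods: Iterable[Modification]) -> str:
    return ";".join(f"{label}:{delta}" for label, delta in mods)


def read_peptide_table(path: str | Path) -> list[PeptideRecord]:
    """Load a peptide target CSV (name,sequence,modifications,charge,target_mz)."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        records.append(
            PeptideRecord(
                name=str(row["name"]),
                sequence=str(row["sequence"]),
                modifications=_parse_modifications(row.get("modifications", "")),
                charge=int(row.get("charge", 1)),
                target_mz=float(row["target_mz"]) if "target_mz" in row and pd.notna(row["target_mz"]) else None,
                precursor=str(row["precursor"]) if "precursor" in row and pd.notna(row.get("precursor")) else None,
            )
        )
    return records


def write_peptide_table(records: Sequence[PeptideRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row = {
            "name": rec.name,
            "sequence": rec.sequence,
            "modifications": _format_modifications(rec.modifications),
            "charge": rec.charge,
            "target_mz": rec.target_mz,
        }
        if rec.precursor is not None:
            row["precursor"] = rec.precursor
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_match_report(result: MatchResult, path: str | Path) -> None:
    """Match report as CSV or JSON, keyed on the file extension."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "n_matched": result.n_matched,
            "mean_abs_error_ppm": result.mean_abs_error_ppm,
            "pairs": [
                {
                    "observed_mz": obs,
                    "series": ion.series,
                    "index": ion.index,
                    "theoretical_mz": ion.mz,
                    "error_ppm": err,
                }
                for obs, ion, err in result.pairs
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        result.to_frame().to_csv(path, index=False)
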