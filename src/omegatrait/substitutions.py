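"""Group-specific amino-acid substitution scanning.

Translates codon alignments and scans columns for replacements carried by a
phenotype group (e.g. ascrotal, IDT or UDT species) while the background is
conserved at the reference residue, reporting records in reference-species
coordinates using the familiar M256V-style notation (reference residue,
1-based ungapped reference position, derived residue set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trees_io import CodonAlignment, GAP, MISSING
from .codon_model import CODON_AA


@dataclass
class AminoAcidAlignment:
    """Residue matrix aligned column-for-column with its codon alignment.

    '-' marks gaps, 'X' missing/ambiguous residues; both are ignored by the
    specificity scan.
    """

    taxa: list[str]
    residues: np.ndarray  # (n_taxa, n_columns) of single characters

    @property
    def n_columns(self) -> int:
        return self.residues.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        return self.residues[self.taxa.index(taxon)]


@dataclass
class SubstitutionRecord:
    """One group-specific replacement at an alignment column."""

    gene: str
    column: int  # 1-based alignment column
    ref_position: int  # 1-based position in the ungapped reference sequence
    ref_residue: str
    derived_residues: tuple[str, ...]
    fg_fraction: float  # fraction of non-missing foreground carrying a derived state
    fg_carriers: dict[str, list[str]] = field(default_factory=dict)
    bg_derived_count: int = 0

    @property
    def notation(self) -> str:
        """e.g. ``M256V`` or ``N332S/I``."""
        return f"{self.ref_residue}{self.ref_position}{'/'.join(self.derived_residues)}"


def translate_alignment(aln: CodonAlignment) -> AminoAcidAlignment:
    """Codon -> residue translation; gaps and missing codons propagate."""
    aa = np.empty(aln.codons.shape, dtype="<U1")
    aa[aln.codons == GAP] = "-"
    aa[aln.codons == MISSING] = "X"
    sense = aln.codons >= 0
    aa_table = np.array(CODON_AA)
    aa[sense] = aa_table[aln.codons[sense]]
    return AminoAcidAlignment(taxa=list(aln.taxa), residues=aa)


def map_to_reference_position(
    aa_aln: AminoAcidAlignment, column: int, reference_species: str
) -> int:
    """1-based ungapped reference coordinate of a 1-based alignment column.

    Counts non-gap reference residues in columns 1..column; raises if the
    reference itself is gapped at the column (no coordinate exists there).
    """
    row = aa_aln.row(reference_species)
    if not 1 <= column <= len(row):
        raise IndexError(f"column {column} outside alignment (1..{len(row)})")
    if row[column - 1] == "-":
        raise ValueError(
            f"reference {reference_species!r} is gapped at column {column}"
        )
    return int(np.count_nonzero(row[:column] != "-"))


def scan_specific_substitutions(
    aa_aln: AminoAcidAlignment,
    foreground: set[str] | frozenset[str] | list[str],
    reference_species: str,
    gene: str = "",
    min_fg_fraction: float = 0.75,
    max_bg_derived: int = 0,
    min_bg_coverage: float = 0.8,
) -> list[SubstitutionRecord]:
    """Columns where the foreground group carries derived residues.

    A column is reported when (a) at most ``max_bg_derived`` (default 0)
    non-missing background residues differ from the reference residue,
    (b) at least ``min_fg_fraction`` of non-missing foreground residues
    differ from it (multiple derived states allowed, as in N332S/I), and
    (c) at least ``min_bg_coverage`` of background species have data at the
    column.  Columns where the reference is gapped or missing are skipped.
    The result does not depend on taxon row order.
    """
    fg = set(foreground)
    if reference_species not in aa_aln.taxa:
        raise KeyError(f"reference species {reference_species!r} not in alignment")
    unknown = fg - set(aa_aln.taxa)
    if unknown:
        raise KeyError(f"foreground species not in alignment: {sorted(unknown)}")
    if not fg or fg >= set(aa_aln.taxa):
        raise ValueError("foreground must be a nonempty proper subset of taxa")
    bg = [t for t in aa_aln.taxa if t not in fg]
    fg_sorted = sorted(fg)
    fg_rows = np.array([aa_aln.taxa.index(t) for t in fg_sorted])
    bg_rows = np.array([aa_aln.taxa.index(t) for t in bg])
    ref_row = aa_aln.row(reference_species)
    R = aa_aln.residues
    records: list[SubstitutionRecord] = []
    for col in range(aa_aln.n_columns):
        ref = ref_row[col]
        if ref in ("-", "X"):
            continue
        bg_res = R[bg_rows, col]
        bg_ok = ~np.isin(bg_res, ("-", "X"))
        if len(bg_rows) == 0 or bg_ok.sum() / len(bg_rows) < min_bg_coverage:
            continue
        bg_derived = int(np.count_nonzero(bg_res[bg_ok] != ref))
        if bg_derived > max_bg_derived:
            continue
        fg_res = R[fg_rows, col]
        fg_ok = ~np.isin(fg_res, ("-", "X"))
        n_fg = int(fg_ok.sum())
        if n_fg == 0:
            continue
        derived_mask = fg_ok & (fg_res != ref)
        n_derived = int(derived_mask.sum())
        if n_derived == 0 or n_derived / n_fg < min_fg_fraction:
            continue
        derived = tuple(sorted(set(fg_res[derived_mask])))
        carriers: dict[str, list[str]] = {d: [] for d in derived}
        for t, r, ok in zip(fg_sorted, fg_res, fg_ok):
            if ok and r != ref:
                carriers[r].append(t)
        records.append(
            SubstitutionRecord(
                gene=gene,
                column=col + 1,
                ref_position=map_to_reference_position(aa_aln, col + 1, reference_species),
                ref_residue=str(ref),
                derived_residues=derived,
                fg_fraction=n_derived / n_fg,
                fg_carriers=carriers,
                bg_derived_count=bg_derived,
            )
        )
    return records


def records_to_frame(records: list[SubstitutionRecord]) -> pd.DataFrame:
    """Tidy table of substitution records (one row per record)."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "column": r.column,
                "ref_pos": r.ref_position,
                "ref_aa": r.ref_residue,
                "derived_aa": "/".join(r.derived_residues),
                "fg_fraction": r.fg_fraction,
                "fg_carriers": ";".join(
                    f"{aa}:{','.join(sp)}" for aa, sp in sorted(r.fg_carriers.items())
                ),
                "notation": r.notation,
            }
            for r in records
        ],
        columns=[
            "gene", "column", "ref_pos", "ref_aa", "derived_aa",
            "fg_fraction", "fg_carriers", "notation",
        ],
    )
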