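"""Assembly and trimming of per-family protein alignments.

Each pfam family pools four provenances: curated reference ("uniprot")
proteins, the public pfam membership (subsampled when huge), and the
psychrophile and mesophile candidates.  After external alignment, the
alignment is trimmed to the span covered by every reference protein (the
last reference start column to the earliest reference end column) and rows
too gappy within that window are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from Bio import SeqIO


@dataclass
class AlignedRow:
    protein_id: str
    source_group: str
    sequence: str


@dataclass
class FamilyAlignment:
    """An aligned protein family with per-row provenance."""

    family: str
    rows: list[AlignedRow]

    def __post_init__(self) -> None:
        widths = {len(r.sequence) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"family {self.family}: ragged alignment widths {widths}")

    @property
    def width(self) -> int:
        return len(self.rows[0].sequence) if self.rows else 0

    def by_group(self, group: str) -> list[AlignedRow]:
        return [r for r in self.rows if r.source_group == group]


@dataclass(frozen=True)
class TrimWindow:
    """0-based half-open column window."""

    start_col: int
    end_col: int

    def __post_init__(self) -> None:
        if not 0 <= self.start_col < self.end_col:
            raise ValueError(f"degenerate trim window [{self.start_col}, {self.end_col})")


class DegenerateWindowError(ValueError):
    pass


def subsample_family(sequences: list, cap: int = 5000, seed: int = 0) -> list:
    """Uniform random subsample of at most ``cap`` sequences (order preserved).

    Families at or under the cap are returned unchanged; larger families are
    reduced to ``cap`` members chosen uniformly without replacement,
    reproducibly for a fixed seed.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if len(sequences) <= cap:
        return list(sequences)
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(sequences), size=cap, replace=False))
    return [sequences[i] for i in keep]


def _first_last_residue_cols(seq: str) -> tuple[int, int] | None:
    """Columns of the first and one-past-last non-gap character, or None."""
    stripped = seq.rstrip("-")
    lead = len(seq) - len(seq.lstrip("-"))
    if not stripped.lstrip("-"):
        return None
    return lead, len(stripped)


def compute_trim_window(alignment: FamilyAlignment, reference_group: str = "uniprot") -> TrimWindow:
    """Window from the latest reference start to the earliest reference end."""
    refs = alignment.by_group(reference_group)
    if not refs:
        raise ValueError(f"family {alignment.family}: no {reference_group!r} rows to trim by")
    start = 0
    end = alignment.width
    for row in refs:
        span = _first_last_residue_cols(row.sequence)
        if span is None:
            raise ValueError(f"reference row {row.protein_id} is all gaps")
        start = max(start, span[0])
        end = min(end, span[1])
    if start >= end:
        raise DegenerateWindowError(
            f"family {alignment.family}: reference spans do not overlap "
            f"(start {start} >= end {end})"
        )
    return TrimWindow(start, end)


def trim_and_filter(
    alignment: FamilyAlignment,
    window: TrimWindow,
    min_fraction: float = 0.66,
    reference_group: str = "uniprot",
) -> FamilyAlignment:
    """Cut the alignment to ``window`` and drop over-gapped non-reference rows.

    A row is kept when its non-gap residue count inside the window is at
    least ``min_fraction`` of the window width; reference rows are always
    kept.
    """
    if window.end_col > alignment.width:
        raise ValueError("trim window exceeds alignment width")
    span = window.end_col - window.start_col
    kept: list[AlignedRow] = []
    for row in alignment.rows:
        sub = row.sequence[window.start_col : window.end_col]
        n_res = span - sub.count("-")
        if row.source_group == reference_group or n_res >= min_fraction * span:
            kept.append(replace(row, sequence=sub))
    if not any(r.source_group != reference_group for r in kept) and len(kept) < len(
        alignment.rows
    ):
        warnings.warn(f"family {alignment.family}: all non-reference rows dropped")
    return FamilyAlignment(family=alignment.family, rows=kept)


def read_alignment(path, family: str, groups: dict[str, str]) -> FamilyAlignment:
    """Read an aligned FASTA; ``groups`` maps protein id -> source group."""
    rows = [
        AlignedRow(rec.id, groups.get(rec.id, "pfam"), str(rec.seq).upper())
        for rec in SeqIO.parse(path, "fasta")
    ]
    return FamilyAlignment(family=family, rows=rows)


def write_alignment(alignment: FamilyAlignment, handle) -> None:
    for row in alignment.rows:
        handle.write(f">{row.protein_id}\n{row.sequence}\n")
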