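"""Six-frame open-reading-frame extraction from bacterial genomes.

An ORF here is a maximal stop-free stretch of one reading frame — no start
codon is required.  Every maximal region whose nucleotide length strictly
exceeds a threshold (default 150 bp) is reported on both strands, with
coordinates given 0-based half-open on the forward strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from Bio import SeqIO
from Bio.Data import CodonTable

VALID_NT = set("ACGTN")


class InvalidAlphabetError(ValueError):
    """Genome contains characters outside {A,C,G,T,N}."""


@dataclass
class GenomeSequence:
    """A DNA replicon (chromosome or plasmid), treated as linear."""

    id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.residues) - VALID_NT
        if bad:
            raise InvalidAlphabetError(
                f"genome {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class OpenReadingFrame:
    """A maximal stop-free framed interval and its translation.

    ``start``/``end`` are 0-based half-open forward-strand nucleotide
    coordinates regardless of strand; ``frame`` is the offset of the first
    codon from the reading 5' end of the strand scanned.
    """

    genome_id: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2
    start: int
    end: int
    protein: str = field(repr=False, default="")

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    @property
    def header(self) -> str:
        return f"{self.genome_id}|{self.strand}|{self.frame}|{self.start}-{self.end}"


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _codon_table(table: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table]


def translate(orf_nt: str, table: int = 11) -> str:
    """Translate a stop-free nucleotide sequence to protein.

    The trailing partial codon (if any) is dropped; any codon containing N
    is rendered as X.  Stop codons translate to ``*`` (they should not occur
    in ORF input).
    """
    orf_nt = orf_nt.upper()
    if len(orf_nt) < 3:
        raise ValueError(f"sequence shorter than one codon: {orf_nt!r}")
    tab = _codon_table(table)
    fwd = tab.forward_table
    stops = set(tab.stop_codons)
    out = []
    for i in range(0, len(orf_nt) - len(orf_nt) % 3, 3):
        codon = orf_nt[i : i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in stops:
            out.append("*")
        else:
            out.append(fwd[codon])
    return "".join(out)


def _scan_frame(seq: str, frame: int, stops: set[str]) -> Iterator[tuple[int, int]]:
    """Yield maximal stop-free intervals (on ``seq`` coordinates) for one frame.

    Intervals start at ``frame`` or just after a stop codon and run to the
    next in-frame stop or to the sequence end (including any partial tail
    codon, which cannot contain a stop).
    """
    n = len(seq)
    region_start = frame
    i = frame
    while i + 3 <= n:
        if seq[i : i + 3] in stops:
            if i > region_start:
                yield region_start, i
            region_start = i + 3
        i += 3
    if n > region_start:
        yield region_start, n


def find_orfs(
    genome: GenomeSequence, min_orf_nt: int = 150, table: int = 11
) -> list[OpenReadingFrame]:
    """Find all maximal stop-free intervals longer than ``min_orf_nt``.

    Both strands and all three frames per strand are scanned.  Codons
    containing N are not treated as stops.  Results are ordered by
    (strand, frame, start).
    """
    if min_orf_nt < 3:
        raise ValueError("min_orf_nt must be >= 3")
    stops = set(_codon_table(table).stop_codons)
    n = len(genome)
    orfs: list[OpenReadingFrame] = []
    for strand, seq in (("+", genome.residues), ("-", reverse_complement(genome.residues))):
        for frame in range(3):
            for s, e in _scan_frame(seq, frame, stops):
                if e - s <= min_orf_nt:
                    continue
                if strand == "+":
                    start, end = s, e
                else:
                    start, end = n - e, n - s
                orfs.append(
                    OpenReadingFrame(
                        genome_id=genome.id,
                        strand=strand,
                        frame=frame,
                        start=start,
                        end=end,
                        protein=translate(seq[s:e], table=table),
                    )
                )
    orfs.sort(key=lambda o: (o.strand, o.frame, o.start))
    return orfs


def read_genomes(path) -> list[GenomeSequence]:
    """Read a multi-record DNA FASTA file."""
    return [
        GenomeSequence(id=rec.id, residues=str(rec.seq)) for rec in SeqIO.parse(path, "fasta")
    ]


def write_orf_fasta(orfs: list[OpenReadingFrame], handle) -> None:
    """Write translated ORFs as protein FASTA with coordinate-encoding headers."""
    for orf in orfs:
        handle.write(f">{orf.header}\n{orf.protein}\n")


def write_orf_bed(orfs: list[OpenReadingFrame], handle) -> None:
    """Write ORF intervals as a BED-like 6-column table."""
    for orf in orfs:
        handle.write(
            f"{orf.genome_id}\t{orf.start}\t{orf.end}\t"
            f"frame{orf.frame}\t{orf.nt_length}\t{orf.strand}\n"
        )
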