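"""Pfam domain annotation of translated ORFs from hmmscan output.

Consumes HMMER3 per-domain tabular output (``--domtblout``), filters hits at
an E-value cutoff (default 1e-5 on the full-sequence E-value), derives the
set of diagnostic pfams from a curated reference set of alkane hydroxylases,
and extracts candidate proteins whose ORFs carry a diagnostic domain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import pandas as pd


@dataclass
class DomainHit:
    """One hmmscan domain match (one domtblout data row)."""

    query_id: str
    pfam_name: str
    pfam_accession: str
    full_sequence_evalue: float
    envelope_start: int  # 1-based inclusive
    envelope_end: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.full_sequence_evalue < 0:
            raise ValueError("E-value must be non-negative")
        if self.envelope_start > self.envelope_end:
            raise ValueError("envelope start > end")


@dataclass
class PfamCatalog:
    """Diagnostic pfams (present in reference alkane hydroxylases) and exclusions."""

    diagnostic: set[str]
    excluded: dict[str, str]  # pfam -> exclusion reason

    def __post_init__(self) -> None:
        overlap = self.diagnostic & set(self.excluded)
        if overlap:
            raise ValueError(f"pfams both diagnostic and excluded: {sorted(overlap)}")


@dataclass
class CandidateProtein:
    """A translated ORF carrying a diagnostic pfam domain."""

    protein_id: str
    sequence: str
    source_group: str  # psychrophile | mesophile | uniprot | pfam
    strain: str
    taxon_pair: str
    pfam_name: str
    evalue: float = float("nan")


class DomtbloutParseError(ValueError):
    pass


# domtblout has 22 whitespace-delimited fields + free-text description
_N_FIELDS = 22


def parse_domtblout(path) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` file (hmmscan orientation).

    The target is the pfam model, the query is the protein.  Comment lines
    (``#``) are skipped; the trailing description field is preserved verbatim.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split(None, _N_FIELDS)
            if len(fields) < _N_FIELDS:
                raise DomtbloutParseError(
                    f"{path}: malformed domtblout row at line {lineno} "
                    f"({len(fields)} fields, expected >= {_N_FIELDS})"
                )
            try:
                hit = DomainHit(
                    query_id=fields[3],
                    pfam_name=fields[0],
                    pfam_accession=fields[1],
                    full_sequence_evalue=float(fields[6]),
                    envelope_start=int(fields[19]),
                    envelope_end=int(fields[20]),
                    description=fields[22] if len(fields) > _N_FIELDS else "",
                )
            except (ValueError, IndexError) as exc:
                raise DomtbloutParseError(
                    f"{path}: malformed domtblout row at line {lineno}: {exc}"
                ) from exc
            hits.append(hit)
    return hits


def filter_hits(hits: list[DomainHit], max_evalue: float = 1e-5) -> list[DomainHit]:
    """Keep hits whose full-sequence E-value is <= ``max_evalue`` (order kept)."""
    return [h for h in hits if h.full_sequence_evalue <= max_evalue]


def default_exclusions() -> list[tuple[str, str]]:
    """The shipped exclusion list: pfams with regulatory or electron-carrier roles."""
    with resources.files("cryoscan.data").joinpath("pfam_exclusions.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return list(df.itertuples(index=False, name=None))


def reference_pfam_hits() -> list[DomainHit]:
    """Synthetic domain hits naming the pfams found in the curated reference set.

    Stand-in rows constructed from the published pfam inventory of the
    reference alkane hydroxylases; only the pfam names are meaningful.
    """
    with resources.files("cryoscan.data").joinpath("reference_pfams.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        DomainHit(
            query_id=f"ref_{i}",
            pfam_name=row.pfam,
            pfam_accession=f"PF{i:05d}",
            full_sequence_evalue=1e-30,
            envelope_start=1,
            envelope_end=100,
            description=row.example,
        )
        for i, row in enumerate(df.itertuples(index=False))
    ]


def build_catalog(
    reference_hits: list[DomainHit],
    exclusions: list[tuple[str, str]] | None = None,
) -> PfamCatalog:
    """Derive the diagnostic pfam set from reference-protein hits minus exclusions."""
    if exclusions is None:
        exclusions = []
    observed = {h.pfam_name for h in reference_hits}
    excluded: dict[str, str] = {}
    for pfam, reason in exclusions:
        if pfam not in observed:
            warnings.warn(f"exclusion {pfam!r} not present among reference hits")
        excluded[pfam] = reason
    return PfamCatalog(diagnostic=observed - set(excluded), excluded=excluded)


def default_catalog() -> PfamCatalog:
    """The shipped catalog: published reference pfams minus the shipped exclusions."""
    return build_catalog(reference_pfam_hits(), default_exclusions())


def extract_candidates(
    orf_hits: list[DomainHit],
    catalog: PfamCatalog,
    group_labels: dict[str, tuple[str, str, str]],
    sequences: dict[str, str] | None = None,
) -> list[CandidateProtein]:
    """Extract one candidate per (ORF, diagnostic pfam) pairing.

    ``group_labels`` maps genome id -> (source_group, taxon_pair, strain).
    The genome id is taken from the ORF header (text before the first ``|``).
    Repeated hits of the same pfam on one ORF collapse to a single candidate
    (the best E-value is kept): genes are counted, not domains.
    """
    best: dict[tuple[str, str], DomainHit] = {}
    for hit in orf_hits:
        if hit.pfam_name not in catalog.diagnostic:
            continue
        key = (hit.query_id, hit.pfam_name)
        if key not in best or hit.full_sequence_evalue < best[key].full_sequence_evalue:
            best[key] = hit
    candidates = []
    for (query_id, pfam), hit in sorted(best.items()):
        genome_id = query_id.split("|", 1)[0]
        if genome_id not in group_labels:
            raise KeyError(f"genome id {genome_id!r} missing from group labels")
        group, pair, strain = group_labels[genome_id]
        candidates.append(
            CandidateProtein(
                protein_id=query_id,
                sequence=(sequences or {}).get(query_id, ""),
                source_group=group,
                strain=strain,
                taxon_pair=pair,
                pfam_name=pfam,
                evalue=hit.full_sequence_evalue,
            )
        )
    return candidates


def candidates_to_frame(candidates: list[CandidateProtein]) -> pd.DataFrame:
    """Tabulate candidates (protein_id, strain, group, pair, pfam, evalue)."""
    return pd.DataFrame(
        [
            {
                "protein_id": c.protein_id,
                "strain": c.strain,
                "group": c.source_group,
                "pair": c.taxon_pair,
                "pfam": c.pfam_name,
                "evalue": c.evalue,
            }
            for c in candidates
        ]
    )
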