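"""Synthetic fixtures with recorded ground truth for every pipeline stage.

The generators emulate the structure of the real study inputs: bacterial
replicons carrying plantable stop-free coding regions, two-group protein
families (psychrophile vs mesophile descendants of a common ancestor) with
planted windows of elevated/depressed flexibility, additive trees with
matching patristic distance matrices, and the external-tool file formats
the pipeline consumes (hmmscan domtblout, PSIPRED ss2, 12-column bit-score
tables).  Each generator records a truth object at generation time; the
pipeline under test never reads it.

Flexibility manipulation draws replacement residues from the top and
bottom quintiles of the Vihinen normalized flexibility scale, mixed with
background substitutions so the expected group mean difference inside a
planted window matches the requested offset.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .domain_annotation import DomainHit
from .family_assembly import AlignedRow, FamilyAlignment
from .orf_caller import GenomeSequence
from .protein_parameters import FLEXIBILITY_SCALE, STANDARD_RESIDUES

_BY_FLEX = sorted(STANDARD_RESIDUES, key=lambda r: FLEXIBILITY_SCALE[r])
LOW_FLEX_POOL = _BY_FLEX[:4]  # bottom quintile of the flexibility scale
HIGH_FLEX_POOL = _BY_FLEX[-4:]  # top quintile

_POOL_GAP = float(
    np.mean([FLEXIBILITY_SCALE[r] for r in HIGH_FLEX_POOL])
    - np.mean([FLEXIBILITY_SCALE[r] for r in LOW_FLEX_POOL])
)


@dataclass
class FamilySpec:
    """Parameters of one synthetic two-group protein family."""

    family: str = "synthetic"
    ancestor_length: int = 300
    n_psy: int = 10
    n_meso: int = 10
    n_reference: int = 4
    substitution_rate: float = 0.05
    group_bias: dict[str, dict[str, float]] | None = None
    deviant_windows: list[tuple[int, int, float]] = field(default_factory=list)
    indel_rate: float = 0.0
    background: dict[str, float] | None = None  # residue weights; uniform when None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must lie in [0, 1]")
        for start, end, _ in self.deviant_windows:
            if not 0 <= start < end <= self.ancestor_length:
                raise ValueError(f"deviant window [{start}, {end}) outside ancestor")


@dataclass
class PlantedTruth:
    """Ground truth recorded at generation time, for scoring only."""

    family: str = ""
    deviant_windows: list[tuple[int, int, float]] = field(default_factory=list)
    composition_deltas: dict[str, dict[str, float]] = field(default_factory=dict)
    cluster_memberships: dict[str, str] = field(default_factory=dict)
    orf_coordinates: list[tuple[str, int, int, str]] = field(default_factory=list)


def _draw_residues(rng: np.random.Generator, n: int, weights: dict[str, float] | None):
    residues = list(STANDARD_RESIDUES)
    if weights is None:
        p = None
    else:
        w = np.array([weights.get(r, 0.0) for r in residues], dtype=float)
        if w.sum() <= 0:
            raise ValueError("background weights sum to zero")
        p = w / w.sum()
    return rng.choice(residues, size=n, p=p)


def generate_family(spec: FamilySpec) -> tuple[FamilyAlignment, PlantedTruth]:
    """Simulate a two-group family around a random ancestor.

    Descendants substitute independently per site at ``substitution_rate``.
    Inside each deviant window the psychrophile group replaces residues
    from the high-flexibility donor pool and the mesophile group from the
    low-flexibility pool, with a mixing probability chosen so the expected
    between-group flexibility difference equals the window's offset.
    Reference ("uniprot") rows are low-divergence copies of the ancestor so
    trim windows stay well defined.  With ``indel_rate`` > 0 descendants
    may carry short deletion runs, emitted as gap characters.
    """
    rng = np.random.default_rng(spec.seed)
    ancestor = _draw_residues(rng, spec.ancestor_length, spec.background)

    window_alpha = []
    for start, end, offset in spec.deviant_windows:
        alpha = abs(offset) / _POOL_GAP if offset != 0 else 0.0
        if alpha > 1:
            raise ValueError(
                f"offset {offset} unattainable: donor pools differ by {_POOL_GAP:.4f}"
            )
        window_alpha.append((start, end, alpha, np.sign(offset)))

    def descend(group: str, rate: float) -> str:
        seq = ancestor.copy()
        mutate = rng.random(spec.ancestor_length) < rate
        bias = (spec.group_bias or {}).get(group)
        n_mut = int(mutate.sum())
        if n_mut:
            seq[mutate] = _draw_residues(rng, n_mut, bias or spec.background)
        if group in ("psychrophile", "mesophile"):
            for start, end, alpha, sign in window_alpha:
                hot = group == "psychrophile"
                pool = HIGH_FLEX_POOL if (hot == (sign > 0)) else LOW_FLEX_POOL
                use = rng.random(end - start) < alpha
                donors = rng.choice(list(pool), size=int(use.sum()))
                idx = np.arange(start, end)[use]
                seq[idx] = donors
        out = seq.copy()
        if spec.indel_rate > 0 and rng.random() < spec.indel_rate:
            run = int(rng.integers(1, 4))
            pos = int(rng.integers(0, spec.ancestor_length - run))
            out[pos : pos + run] = "-"
        return "".join(out)

    rows = []
    for i in range(spec.n_reference):
        rows.append(
            AlignedRow(f"{spec.family}_ref_{i}", "uniprot", descend("uniprot", spec.substitution_rate / 10))
        )
    for i in range(spec.n_psy):
        rows.append(
            AlignedRow(f"{spec.family}_psy_{i}", "psychrophile", descend("psychrophile", spec.substitution_rate))
        )
    for i in range(spec.n_meso):
        rows.append(
            AlignedRow(f"{spec.family}_meso_{i}", "mesophile", descend("mesophile", spec.substitution_rate))
        )
    truth = PlantedTruth(
        family=spec.family,
        deviant_windows=list(spec.deviant_windows),
        cluster_memberships={r.protein_id: r.source_group for r in rows},
    )
    return FamilyAlignment(family=spec.family, rows=rows), truth


def score_deviation_flags(
    sites, truth: PlantedTruth, window: int = 9
) -> tuple[float, float]:
    """(recall over planted columns, false-flag rate over clean columns).

    A column counts as planted when its center lies inside a deviant
    window; it counts as clean when the whole w-residue window around it
    avoids every deviant window (columns in the windowing penumbra are
    scored as neither).  Assumes an ungapped family (columns = residues,
    0-based column c holds residue c+1).
    """
    half = window // 2
    planted_hits = planted_total = clean_flags = clean_total = 0
    for site in sites:
        res = site.column  # 0-based residue index for ungapped families
        in_window = any(s <= res < e for s, e, _ in truth.deviant_windows)
        near_window = any(
            s - half <= res < e + half for s, e, _ in truth.deviant_windows
        )
        if in_window:
            planted_total += 1
            planted_hits += site.flagged
        elif not near_window:
            clean_total += 1
            clean_flags += site.flagged
    recall = planted_hits / planted_total if planted_total else float("nan")
    false_rate = clean_flags / clean_total if clean_total else 0.0
    return recall, false_rate


# --- genome generation -------------------------------------------------------

_CODONS_BY_AA: dict[str, list[str]] = {}


def _codons_by_aa(table: int = 11) -> dict[str, list[str]]:
    if not _CODONS_BY_AA:
        from Bio.Data import CodonTable

        fwd = CodonTable.unambiguous_dna_by_id[table].forward_table
        for codon, aa in fwd.items():
            _CODONS_BY_AA.setdefault(aa, []).append(codon)
    return _CODONS_BY_AA


# short motif with a stop codon in all three of its internal frames (and,
# via its reverse complement, in all reverse frames)
_STOP_MOTIF = "TAGTTAGTTAGTTAG"


def _spacer(rng: np.random.Generator, length: int) -> str:
    """Random intergenic DNA salted with stop motifs so no frame stays open."""
    parts = [_STOP_MOTIF]
    remaining = length
    while remaining > 0:
        chunk = min(remaining, 48)
        parts.append("".join(rng.choice(list("ACGT"), size=chunk)))
        parts.append(_STOP_MOTIF)
        remaining -= chunk
    return "".join(parts)


def generate_genome(
    proteins: dict[str, str],
    intergenic_length: int = 120,
    seed: int = 0,
    genome_id: str = "synthetic_genome",
    table: int = 11,
) -> tuple[GenomeSequence, PlantedTruth]:
    """Reverse-translate proteins into a genome of stop-flanked CDS regions.

    Synonymous codons are chosen uniformly; each CDS is flanked by in-frame
    stop codons and separated by stop-salted spacers, so every planted CDS
    is a maximal stop-free region recoverable by the ORF caller.
    """
    if not proteins:
        raise ValueError("no proteins to plant")
    if intergenic_length <= 0:
        raise ValueError("intergenic_length must be positive")
    rng = np.random.default_rng(seed)
    codons = _codons_by_aa(table)
    parts: list[str] = []
    truth = PlantedTruth(family=genome_id)
    pos = 0
    for pid, protein in proteins.items():
        spacer = _spacer(rng, intergenic_length)
        parts.append(spacer)
        pos += len(spacer)
        parts.append("TAA")
        pos += 3
        cds = "".join(rng.choice(codons[aa]) for aa in protein.upper())
        parts.append(cds)
        truth.orf_coordinates.append((pid, pos, pos + len(cds), "+"))
        pos += len(cds)
        parts.append("TAG")
        pos += 3
    tail = _spacer(rng, intergenic_length)
    parts.append(tail)
    genome = GenomeSequence(id=genome_id, residues="".join(parts))
    return genome, truth


# --- trees -------------------------------------------------------------------


def generate_tree_distances(n_tips: int, seed: int = 0):
    """Random additive binary tree plus its exact patristic distance matrix.

    Built by successive random joins with Uniform(0.1, 1.0) branch lengths;
    the matrix is accumulated from path sums during construction, so it is
    additive by construction.  Returns (newick text, skbio DistanceMatrix).
    """
    from skbio import DistanceMatrix

    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    labels = [f"t{i}" for i in range(n_tips)]
    # each cluster: (newick fragment, {leaf: distance to cluster root})
    clusters: list[tuple[str, dict[str, float]]] = [(lab, {lab: 0.0}) for lab in labels]
    dist = {frozenset((a, b)): 0.0 for i, a in enumerate(labels) for b in labels[i + 1 :]}
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (nwk_a, depth_a) = clusters[i]
        (nwk_b, depth_b) = clusters[j]
        bl_a = float(rng.uniform(0.1, 1.0))
        bl_b = float(rng.uniform(0.1, 1.0))
        for la, da in depth_a.items():
            for lb, db in depth_b.items():
                dist[frozenset((la, lb))] = da + bl_a + db + bl_b
        merged_depths = {la: da + bl_a for la, da in depth_a.items()}
        merged_depths.update({lb: db + bl_b for lb, db in depth_b.items()})
        merged = (f"({nwk_a}:{bl_a:.6f},{nwk_b}:{bl_b:.6f})", merged_depths)
        clusters = [c for p, c in enumerate(clusters) if p not in (i, j)] + [merged]
    newick = clusters[0][0] + ";"
    mat = np.zeros((n_tips, n_tips))
    for i, a in enumerate(labels):
        for j in range(i + 1, n_tips):
            mat[i, j] = mat[j, i] = dist[frozenset((a, labels[j]))]
    return newick, DistanceMatrix(mat, labels)


# --- external-tool file fixtures --------------------------------------------


def write_domtblout(hits: list[DomainHit], path) -> None:
    """Write DomainHits as syntactically valid HMMER3 per-domain table rows."""
    with open(path, "w") as fh:
        fh.write("# target name, accession, tlen, query name, ... (synthetic fixture)\n")
        fh.write("#\n")
        for h in hits:
            qlen = max(h.envelope_end + 10, 100)
            fh.write(
                f"{h.pfam_name} {h.pfam_accession} 200 {h.query_id} - {qlen} "
                f"{h.full_sequence_evalue:.3g} 150.0 0.1 1 1 "
                f"{h.full_sequence_evalue:.3g} {h.full_sequence_evalue:.3g} 149.0 0.1 "
                f"1 200 {h.envelope_start} {h.envelope_end} "
                f"{h.envelope_start} {h.envelope_end} 0.95 {h.description or '-'}\n"
            )


def write_ss2(labels: str, sequence: str, path) -> None:
    """Write a PSIPRED vertical-format file with certainty-one probabilities."""
    if len(labels) != len(sequence):
        raise ValueError("labels and sequence lengths differ")
    with open(path, "w") as fh:
        fh.write("# PSF format file (synthetic fixture)\n\n")
        for i, (aa, lab) in enumerate(zip(sequence, labels), start=1):
            pc = 1.0 if lab == "C" else 0.0
            ph = 1.0 if lab == "H" else 0.0
            pe = 1.0 if lab == "E" else 0.0
            fh.write(f"{i:>4} {aa} {lab}  {pc:.3f} {ph:.3f} {pe:.3f}\n")


def write_bitscore_table(distances, path, seed: int = 0, scale: float = 500.0) -> None:
    """Write reciprocal 12-column search rows with bit score = monotone
    transform of distance (score = scale * exp(-d), with small reciprocal
    jitter that averages out)."""
    rng = np.random.default_rng(seed)
    ids = list(distances.ids)
    with open(path, "w") as fh:
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                if i == j:
                    continue
                d = float(distances.data[i, j])
                score = scale * np.exp(-d) * (1.0 + rng.normal(0, 0.001))
                fh.write(
                    f"{a}\t{b}\t90.0\t100\t5\t1\t1\t100\t1\t100\t1e-30\t{score:.2f}\n"
                )


def write_fixture_outputs(
    alignment: FamilyAlignment,
    out_dir,
    seed: int = 0,
    pfam_name: str = "p450",
) -> dict[str, str]:
    """Emit a bundle of tool-output fixtures for one family.

    Writes a domtblout with planted E-values straddling 1e-5 (even-indexed
    rows pass the filter, odd-indexed fail), per-protein ss2 files with
    planted H/E/C blocks, and a reciprocal bit-score table derived from the
    family's Kimura distances.  Returns the paths written.
    """
    from .similarity_clustering import distance_matrix

    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    hits = []
    for i, row in enumerate(alignment.rows):
        evalue = 1e-6 if i % 2 == 0 else 1e-4
        length = len(row.sequence.replace("-", ""))
        hits.append(
            DomainHit(
                query_id=row.protein_id,
                pfam_name=pfam_name,
                pfam_accession="PF00000",
                full_sequence_evalue=evalue,
                envelope_start=1,
                envelope_end=max(1, length),
            )
        )
    domtbl = os.path.join(out_dir, f"{alignment.family}.domtblout")
    write_domtblout(hits, domtbl)

    ss2_paths = {}
    for row in alignment.rows:
        seq = row.sequence.replace("-", "")
        third = len(seq) // 3
        labels = "H" * third + "E" * third + "C" * (len(seq) - 2 * third)
        p = os.path.join(out_dir, f"{row.protein_id}.ss2")
        write_ss2(labels, seq, p)
        ss2_paths[row.protein_id] = p

    bitscores = os.path.join(out_dir, f"{alignment.family}.bitscores.tsv")
    write_bitscore_table(distance_matrix(alignment), bitscores, seed=int(rng.integers(2**31)))
    return {"domtblout": domtbl, "ss2": ss2_paths, "bitscores": bitscores}
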