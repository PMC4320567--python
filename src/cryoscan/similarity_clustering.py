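"""Sequence-similarity clustering of protein families.

Pairwise Kimura-corrected distances over an alignment feed a nonmetric
multidimensional scaling (NMDS) embedding; far-outlying points are culled
before re-embedding; axis-aligned boxes on the first two NMDS dimensions
select clusters for downstream analysis.  The fidelity of the 2-D embedding
is validated by regressing log embedding distance on patristic tree
distance (log-linear) or on reciprocal-search bit score (log-log).

Kimura correction of an observed difference fraction p:

    d = -ln(1 - p - 0.2 p^2)

computed pairwise over columns where both rows carry a residue.  The
correction diverges as p approaches ~0.8541; such pairs are capped at a
configurable maximum distance so matrices stay complete.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from scipy import stats
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from .family_assembly import FamilyAlignment

# p at which 1 - p - 0.2 p^2 reaches zero
_P_SINGULAR = (math.sqrt(45) - 5) / 2


class UndefinedDistanceError(ValueError):
    """No comparable (both-residue) columns between two rows."""


def kimura_distance(row_a: str, row_b: str, d_max: float = 10.0) -> float:
    """Kimura-corrected distance between two aligned protein sequences.

    Columns with a gap in either row are excluded pairwise.  When the
    observed difference fraction p makes the correction undefined
    (p >= ~0.8541) the distance is capped at ``d_max`` with a warning.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in width")
    a = np.frombuffer(row_a.upper().encode(), dtype="S1")
    b = np.frombuffer(row_b.upper().encode(), dtype="S1")
    comparable = (a != b"-") & (b != b"-")
    n = int(comparable.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable columns between rows")
    p = float((a[comparable] != b[comparable]).sum()) / n
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        warnings.warn(f"p={p:.4f} beyond Kimura correction range; capping at {d_max}")
        return d_max
    return min(-math.log(arg), d_max)


def distance_matrix(alignment: FamilyAlignment, d_max: float = 10.0) -> DistanceMatrix:
    """All-pairs Kimura-corrected distances for an aligned family."""
    rows = alignment.rows
    if len(rows) < 2:
        raise ValueError("need at least two rows for a distance matrix")
    ids = [r.protein_id for r in rows]
    # vectorised pairwise computation over a residue matrix
    arr = np.array([list(r.sequence.upper()) for r in rows], dtype="S1")
    isres = arr != b"-"
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        comp = isres[i] & isres[i + 1 :]
        counts = comp.sum(axis=1)
        if (counts == 0).any():
            j = int(np.nonzero(counts == 0)[0][0]) + i + 1
            raise UndefinedDistanceError(
                f"no comparable columns between {ids[i]} and {ids[j]}"
            )
        mism = ((arr[i] != arr[i + 1 :]) & comp).sum(axis=1)
        p = mism / counts
        arg = 1.0 - p - 0.2 * p * p
        with np.errstate(invalid="ignore"):
            dist = np.where(arg > 0, -np.log(np.where(arg > 0, arg, 1.0)), d_max)
        if (arg <= 0).any():
            warnings.warn("some pairs beyond Kimura correction range; capped")
        dist = np.minimum(dist, d_max)
        d[i, i + 1 :] = dist
        d[i + 1 :, i] = dist
    return DistanceMatrix(d, ids)


def choose_dimensions(n: int) -> int:
    """NMDS dimensionality rule: 3 under 3,000 sequences, 4 up to 6,000, 5 above."""
    if n < 3:
        raise ValueError("need at least 3 sequences")
    if n < 3000:
        return 3
    if n <= 6000:
        return 4
    return 5


@dataclass
class Embedding:
    """An NMDS configuration with its Kruskal stress-1."""

    ids: list[str]
    coordinates: np.ndarray  # n x k
    k: int
    stress: float
    seed: int
    converged: bool = True
    groups: dict[str, str] = field(default_factory=dict)

    def coords_2d(self) -> np.ndarray:
        return self.coordinates[:, :2]


def kruskal_stress(distances: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against input dissimilarities.

    Disparities are the isotonic regression of configuration distances on
    the rank order of the input dissimilarities.
    """
    iu = np.triu_indices(len(distances), k=1)
    diss = distances[iu]
    conf = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))[iu]
    disp = IsotonicRegression().fit_transform(diss, conf)
    denom = (conf**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((conf - disp) ** 2).sum() / denom))


def nmds(
    matrix: DistanceMatrix,
    k: int | None = None,
    seed: int = 0,
    n_starts: int = 4,
    max_iter: int = 300,
    groups: dict[str, str] | None = None,
) -> Embedding:
    """Nonmetric MDS by SMACOF majorization with monotone regression.

    Runs ``n_starts`` random initializations and keeps the lowest-stress
    configuration; reproducible for a fixed seed.
    """
    ids = list(matrix.ids)
    if k is None:
        k = choose_dimensions(len(ids))
    model = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        n_init=n_starts,
        init="random",
        max_iter=max_iter,
        eps=1e-9,
        random_state=seed,
        normalized_stress=True,
    )
    coords = model.fit_transform(matrix.data)
    stress = kruskal_stress(matrix.data, coords)
    converged = model.n_iter_ < max_iter
    if not converged:
        warnings.warn(f"NMDS did not converge within {max_iter} iterations")
    return Embedding(
        ids=ids,
        coordinates=coords,
        k=k,
        stress=stress,
        seed=seed,
        converged=converged,
        groups=groups or {},
    )


def cull_outliers(embedding: Embedding, mad_k: float = 6.0) -> tuple[list[str], list[str]]:
    """Split ids into (kept, culled) by distance from the 2-D median.

    A point is culled when its Euclidean distance from the coordinate-wise
    median on dimensions 1-2 exceeds ``mad_k`` times the median absolute
    deviation of those distances.
    """
    xy = embedding.coords_2d()
    center = np.median(xy, axis=0)
    dist = np.linalg.norm(xy - center, axis=1)
    mad = np.median(np.abs(dist - np.median(dist)))
    cutoff = mad_k * mad
    culled = [i for i, d in zip(embedding.ids, dist) if d > cutoff]
    kept = [i for i in embedding.ids if i not in set(culled)]
    if not kept:
        raise ValueError("outlier culling removed every point")
    return kept, culled


@dataclass
class ClusterSelection:
    """Points inside one axis-aligned box on NMDS dimensions 1-2."""

    cluster_id: str
    dim1: tuple[float, float]
    dim2: tuple[float, float]
    member_ids: list[str]
    group_counts: dict[str, int]
    contains_reference: bool


def select_clusters(
    embedding: Embedding,
    boxes: dict[str, tuple[tuple[float, float], tuple[float, float]]],
    memberships: dict[str, str] | None = None,
    reference_group: str = "uniprot",
) -> list[ClusterSelection]:
    """Assign points to user-supplied boxes by closed-interval containment.

    Selections lacking a reference-group member are flagged not-candidate.
    Overlapping boxes are allowed (points may appear in several) but warned.
    """
    memberships = memberships or embedding.groups
    xy = embedding.coords_2d()
    selections = []
    seen: set[str] = set()
    overlapping = False
    for cid, ((x0, x1), (y0, y1)) in boxes.items():
        if x0 >= x1 or y0 >= y1:
            raise ValueError(f"degenerate box {cid!r}")
        inside = (
            (xy[:, 0] >= x0) & (xy[:, 0] <= x1) & (xy[:, 1] >= y0) & (xy[:, 1] <= y1)
        )
        members = [i for i, flag in zip(embedding.ids, inside) if flag]
        if seen & set(members):
            overlapping = True
        seen |= set(members)
        counts: dict[str, int] = {}
        for m in members:
            g = memberships.get(m, "unknown")
            counts[g] = counts.get(g, 0) + 1
        selections.append(
            ClusterSelection(
                cluster_id=cid,
                dim1=(x0, x1),
                dim2=(y0, y1),
                member_ids=members,
                group_counts=counts,
                contains_reference=counts.get(reference_group, 0) > 0,
            )
        )
    if overlapping:
        warnings.warn("cluster boxes overlap; some points belong to multiple clusters")
    return selections


def patristic_distances(newick_text: str) -> DistanceMatrix:
    """Tip-to-tip summed branch lengths from a newick tree."""
    tree = dendropy.Tree.get(data=newick_text, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            head = edge.head_node
            label = head.taxon.label if head.taxon else "internal node"
            raise ValueError(f"missing branch length on edge above {label}")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(d, ids)


def read_bitscore_table(path) -> pd.DataFrame:
    """Read 12-column tabular search output and average reciprocal bit scores.

    Returns a long DataFrame (id_a, id_b, bitscore) with one row per
    unordered pair, a < b lexicographically.
    """
    cols = [
        "query", "subject", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    df = df[df["query"] != df["subject"]].copy()
    key = df[["query", "subject"]].apply(lambda r: tuple(sorted(r)), axis=1)
    df["id_a"] = [k[0] for k in key]
    df["id_b"] = [k[1] for k in key]
    out = df.groupby(["id_a", "id_b"], as_index=False)["bitscore"].mean()
    return out


@dataclass
class EmbeddingValidation:
    """A linear fit of log 2-D embedding distance against another pair metric."""

    form: str  # 'log-linear' or 'log-log'
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    n_excluded: int
    seed: int


def _pair_values(other, ids: list[str]) -> dict[tuple[str, str], float]:
    if isinstance(other, DistanceMatrix):
        out = {}
        idx = {i: other.ids.index(i) for i in ids if i in set(other.ids)}
        for a_pos, a in enumerate(ids):
            for b in ids[a_pos + 1 :]:
                if a in idx and b in idx:
                    out[tuple(sorted((a, b)))] = float(other.data[idx[a], idx[b]])
        return out
    if isinstance(other, pd.DataFrame):
        return {
            tuple(sorted((r.id_a, r.id_b))): float(r.bitscore)
            for r in other.itertuples(index=False)
        }
    raise TypeError("other must be a DistanceMatrix or a bit-score DataFrame")


def validate_embedding(
    embedding: Embedding,
    other,
    form: str = "log-linear",
    n_sub: int = 10000,
    seed: int = 0,
) -> EmbeddingValidation:
    """Regress ln(2-D embedding distance) on another pairwise metric.

    ``form='log-linear'`` fits ln(euclid) ~ x; ``form='log-log'`` fits
    ln(euclid) ~ ln(x).  Pairs with non-positive values entering a log are
    excluded and counted.  At most ``n_sub`` randomly chosen pairs are fit.
    """
    if form not in ("log-linear", "log-log"):
        raise ValueError(f"unknown form {form!r}")
    pair_vals = _pair_values(other, embedding.ids)
    xy = embedding.coords_2d()
    pos = {pid: p for pid, p in zip(embedding.ids, xy)}
    pairs, ys, xs = [], [], []
    for (a, b), x in pair_vals.items():
        e = float(np.linalg.norm(pos[a] - pos[b]))
        pairs.append((a, b))
        ys.append(e)
        xs.append(x)
    ys = np.asarray(ys)
    xs = np.asarray(xs)
    usable = ys > 0
    if form == "log-log":
        usable &= xs > 0
    n_excluded = int((~usable).sum())
    ys, xs = ys[usable], xs[usable]
    if len(ys) > n_sub:
        rng = np.random.default_rng(seed)
        take = rng.choice(len(ys), size=n_sub, replace=False)
        ys, xs = ys[take], xs[take]
    if len(ys) < 3:
        raise ValueError("fewer than 3 usable pairs for validation fit")
    response = np.log(ys)
    predictor = np.log(xs) if form == "log-log" else xs
    fit = stats.linregress(predictor, response)
    return EmbeddingValidation(
        form=form,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n_points=len(ys),
        n_excluded=n_excluded,
        seed=seed,
    )
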