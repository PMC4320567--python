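"""Group comparisons of windowed protein parameters.

Per-position parameter values are stratified by predicted secondary
structure (α-helix H, β-strand E, coil C), psychrophile and mesophile value
pools are compared with a two-sided Mann–Whitney (Wilcoxon rank-sum) test,
p-values are corrected with the Holm-Bonferroni step-down procedure, and
results are classified as significant (corrected p below α) or trending
(raw p below α but not surviving correction).  Taxon-pair contrasts count,
over all psychrophile × mesophile protein cross-products within a pair, how
often the psychrophile value is strictly higher.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .protein_parameters import ParameterProfile

REGIONS = ("whole", "H", "E", "C")


@dataclass
class SecondaryStructureAnnotation:
    """Per-residue secondary-structure labels over {H, E, C}."""

    protein_id: str
    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - set("HEC")
        if bad:
            raise ValueError(f"invalid secondary-structure labels {sorted(bad)}")


def parse_ss2(path, sequence: str | None = None) -> SecondaryStructureAnnotation:
    """Parse a PSIPRED vertical-format (.ss2) file.

    Each data row is: index, residue, call, p(C), p(H), p(E).  The label
    assigned is the maximum-probability state, with ties broken by the
    precedence C > H > E (coil as the unstructured default).
    """
    residues: list[str] = []
    labels: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or line.startswith("#"):
                continue
            if len(parts) < 6 or not parts[0].isdigit():
                continue
            residues.append(parts[1])
            probs = {"C": float(parts[3]), "H": float(parts[4]), "E": float(parts[5])}
            labels.append(max("EHC", key=lambda s: (probs[s], "EHC".index(s))))
    if not labels:
        raise ValueError(f"{path}: no residue rows in ss2 file")
    if sequence is not None and "".join(residues) != sequence.upper():
        raise ValueError(f"{path}: ss2 residues disagree with supplied sequence")
    protein_id = str(path)
    return SecondaryStructureAnnotation(protein_id=protein_id, labels="".join(labels))


def stratify(
    profile: ParameterProfile, ss: SecondaryStructureAnnotation
) -> dict[str, list[float]]:
    """Assign each windowed value to the region of its center residue.

    Returns lists for 'whole' (all values), 'H', 'E', and 'C'.
    """
    n_res = len(ss.labels)
    if len(profile) and profile.positions[-1] > n_res:
        raise ValueError(
            f"profile for {profile.protein_id} extends past the secondary-structure "
            f"annotation ({profile.positions[-1]} > {n_res})"
        )
    out: dict[str, list[float]] = {r: [] for r in REGIONS}
    for pos, val in zip(profile.positions, profile.values):
        if np.isnan(val):
            continue
        out["whole"].append(float(val))
        out[ss.labels[pos - 1]].append(float(val))
    return out


def mann_whitney(sample_a, sample_b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    ``mode='auto'`` uses the exact permutation distribution when both
    samples have at most 8 observations and there are no ties, otherwise
    the tie-corrected normal approximation with continuity correction.
    Returns (U of the first sample, two-sided p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
        method = "exact" if (len(a) <= 8 and len(b) <= 8 and not ties) else "asymptotic"
    elif mode in ("exact", "asymptotic"):
        method = mode
    else:
        raise ValueError(f"unknown mode {mode!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in input order.

    With p-values sorted ascending, adjusted_(i) = max_{j<=i} min(1, (m-j)·p_(j))
    (0-based j), enforcing monotonicity of the step-down sequence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adjusted[idx] = running
    return adjusted


@dataclass
class ComparisonRecord:
    """One psychrophile-vs-mesophile test for a (family, region, parameter) cell."""

    family: str
    region: str
    parameter: str
    n_psy: int
    n_meso: int
    u_statistic: float
    raw_p: float
    adjusted_p: float = float("nan")
    significant: bool = False
    trending: bool = False
    direction: str = ""  # psychrophile-higher | mesophile-higher


def compare_groups(
    family: str,
    psy_values: dict[str, list[float]],
    meso_values: dict[str, list[float]],
    parameter: str,
) -> list[ComparisonRecord]:
    """Mann–Whitney comparisons of one parameter across all regions."""
    records = []
    for region in REGIONS:
        a = psy_values.get(region, [])
        b = meso_values.get(region, [])
        if not a or not b:
            continue
        u, p = mann_whitney(a, b)
        direction = (
            "psychrophile-higher"
            if float(np.median(a)) >= float(np.median(b))
            else "mesophile-higher"
        )
        records.append(
            ComparisonRecord(
                family=family,
                region=region,
                parameter=parameter,
                n_psy=len(a),
                n_meso=len(b),
                u_statistic=u,
                raw_p=p,
                direction=direction,
            )
        )
    return records


def classify(
    records: list[ComparisonRecord], alpha: float = 0.05, trend_alpha: float = 0.05
) -> list[ComparisonRecord]:
    """Holm-correct raw p-values and set significant/trending flags.

    The correction family is all records passed in (by convention all
    parameters × regions within one pfam).
    """
    if not records:
        return []
    adjusted = holm_bonferroni([r.raw_p for r in records])
    out = []
    for rec, adj in zip(records, adjusted):
        significant = bool(adj < alpha)
        trending = bool(rec.raw_p < trend_alpha and not significant)
        out.append(
            replace(rec, adjusted_p=float(adj), significant=significant, trending=trending)
        )
    return out


@dataclass
class PairwiseCount:
    """Within-taxon-pair cross-product comparisons for one parameter/region."""

    family: str
    region: str
    parameter: str
    n_comparisons: int
    n_psychrophile_higher: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_psychrophile_higher <= self.n_comparisons:
            raise ValueError("psychrophile-higher count out of range")


def pairwise_counts(
    pair_values: dict[str, tuple[list[float], list[float]]],
    family: str = "",
    region: str = "whole",
    parameter: str = "",
) -> PairwiseCount:
    """Count strict psychrophile > mesophile outcomes over all within-pair products.

    ``pair_values`` maps taxon-pair letter -> (psychrophile values,
    mesophile values), one value per candidate protein.  Every psychrophile
    candidate is compared with every mesophile candidate of the same pair;
    ties count as not-higher.
    """
    n_comparisons = 0
    n_higher = 0
    for psy_vals, meso_vals in pair_values.values():
        for pv in psy_vals:
            for mv in meso_vals:
                n_comparisons += 1
                if pv > mv:
                    n_higher += 1
    if n_comparisons == 0:
        warnings.warn("no eligible psychrophile-mesophile pairs for pairwise counts")
    return PairwiseCount(
        family=family,
        region=region,
        parameter=parameter,
        n_comparisons=n_comparisons,
        n_psychrophile_higher=n_higher,
    )


def n_pairwise_comparisons(pair_counts: dict[str, tuple[int, int]]) -> int:
    """Total cross-product comparisons from per-pair (n_psychrophile, n_mesophile)."""
    return sum(n_p * n_m for n_p, n_m in pair_counts.values())
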