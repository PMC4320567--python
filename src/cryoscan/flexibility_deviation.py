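"""Per-alignment-column flexibility deviation between temperature groups.

Windowed flexibility profiles are projected onto a family alignment so that
each residue's value lands in the column holding that residue.  For every
column with enough data in both groups, the psychrophile and mesophile
means and standard deviations are computed; a column is flagged as a
deviation site when |mean difference| strictly exceeds the sum of the two
group standard deviations.  Summaries count flags per direction and sum
the mean differences over all and over flagged columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .family_assembly import FamilyAlignment
from .protein_parameters import ParameterProfile


@dataclass
class AlignedParameterMatrix:
    """Per-column parameter values for every protein in an aligned family.

    ``values`` is a (protein x column) DataFrame with NaN where the row is
    gapped or the column's residue lies outside the profile's center range;
    ``groups`` maps protein id -> source group.
    """

    family: str
    values: pd.DataFrame
    groups: dict[str, str]

    @property
    def width(self) -> int:
        return self.values.shape[1]


def project_profiles(
    profiles: dict[str, ParameterProfile], alignment: FamilyAlignment
) -> AlignedParameterMatrix:
    """Map per-residue profile values onto alignment columns.

    The value at residue position i (1-based) lands in the column holding
    that row's i-th non-gap character.  Rows of the alignment without a
    profile are skipped; empty profiles contribute no values.
    """
    width = alignment.width
    data = {}
    groups = {}
    for row in alignment.rows:
        prof = profiles.get(row.protein_id)
        if prof is None:
            continue
        residue_cols = [c for c, ch in enumerate(row.sequence) if ch != "-"]
        n_res = len(residue_cols)
        if len(prof.positions) and prof.positions[-1] > n_res:
            raise ValueError(
                f"profile for {row.protein_id} longer than its ungapped row "
                f"({prof.positions[-1]} > {n_res})"
            )
        vals = np.full(width, np.nan)
        for pos, val in zip(prof.positions, prof.values):
            vals[residue_cols[pos - 1]] = val
        data[row.protein_id] = vals
        groups[row.protein_id] = row.source_group
    values = pd.DataFrame(data, index=range(width)).T
    return AlignedParameterMatrix(family=alignment.family, values=values, groups=groups)


@dataclass
class DeviationSite:
    """Group statistics for one alignment column."""

    column: int
    mean_psy: float
    mean_meso: float
    sd_psy: float
    sd_meso: float

    @property
    def delta(self) -> float:
        return self.mean_psy - self.mean_meso

    @property
    def flagged(self) -> bool:
        return abs(self.delta) > self.sd_psy + self.sd_meso

    @property
    def direction(self) -> str:
        if not self.flagged:
            return ""
        return "psychrophile-higher" if self.delta > 0 else "mesophile-higher"


def column_stats(
    matrix: AlignedParameterMatrix,
    min_group_n: int = 2,
    ddof: int = 1,
    psy_group: str = "psychrophile",
    meso_group: str = "mesophile",
) -> list[DeviationSite]:
    """Per-column group means and SDs; columns with too little data are skipped.

    A column contributes only when both groups have at least ``min_group_n``
    present values (the default 2 keeps the sample SD defined) — such gaps
    mirror alignment gaps that prevent computing a mean or SD.
    """
    psy_ids = [p for p, g in matrix.groups.items() if g == psy_group]
    meso_ids = [p for p, g in matrix.groups.items() if g == meso_group]
    if not psy_ids or not meso_ids:
        raise ValueError("matrix must contain both temperature groups")
    psy = matrix.values.loc[psy_ids].to_numpy()
    meso = matrix.values.loc[meso_ids].to_numpy()
    sites = []
    for col in range(matrix.width):
        pv = psy[:, col]
        mv = meso[:, col]
        pv = pv[~np.isnan(pv)]
        mv = mv[~np.isnan(mv)]
        if len(pv) < min_group_n or len(mv) < min_group_n:
            continue
        sites.append(
            DeviationSite(
                column=col,
                mean_psy=float(pv.mean()),
                mean_meso=float(mv.mean()),
                sd_psy=float(pv.std(ddof=ddof)),
                sd_meso=float(mv.std(ddof=ddof)),
            )
        )
    return sites


@dataclass
class DeviationSummary:
    n_flagged_psy_higher: int
    n_flagged_meso_higher: int
    sum_delta_all: float
    sum_delta_flagged: float

    @property
    def n_flagged(self) -> int:
        return self.n_flagged_psy_higher + self.n_flagged_meso_higher


def summarize(sites: list[DeviationSite]) -> DeviationSummary:
    """Directional flag counts and delta sums over evaluated and flagged columns."""
    flagged = [s for s in sites if s.flagged]
    return DeviationSummary(
        n_flagged_psy_higher=sum(s.delta > 0 for s in flagged),
        n_flagged_meso_higher=sum(s.delta < 0 for s in flagged),
        sum_delta_all=float(sum(s.delta for s in sites)),
        sum_delta_flagged=float(sum(s.delta for s in flagged)),
    )


def map_to_representative(
    sites: list[DeviationSite], alignment: FamilyAlignment, representative_id: str
) -> tuple[list[tuple[int, str]], int]:
    """Translate flagged columns to a representative's 1-based residue numbering.

    Flagged columns where the representative is gapped are dropped; the
    second return value counts them.
    """
    rows = {r.protein_id: r for r in alignment.rows}
    if representative_id not in rows:
        raise KeyError(f"representative {representative_id!r} not in alignment")
    seq = rows[representative_id].sequence
    col_to_res: dict[int, int] = {}
    res = 0
    for col, ch in enumerate(seq):
        if ch != "-":
            res += 1
            col_to_res[col] = res
    mapped = []
    dropped = 0
    for site in sites:
        if not site.flagged:
            continue
        if site.column in col_to_res:
            mapped.append((col_to_res[site.column], site.direction))
        else:
            dropped += 1
    return mapped, dropped


def sites_to_frame(sites: list[DeviationSite]) -> pd.DataFrame:
    """Tabulate per-column statistics for report output."""
    return pd.DataFrame(
        [
            {
                "column": s.column,
                "mean_psychrophile": s.mean_psy,
                "mean_mesophile": s.mean_meso,
                "sd_psychrophile": s.sd_psy,
                "sd_mesophile": s.sd_meso,
                "delta": s.delta,
                "sd_sum": s.sd_psy + s.sd_meso,
                "flagged": s.flagged,
                "direction": s.direction,
            }
            for s in sites
        ]
    )
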