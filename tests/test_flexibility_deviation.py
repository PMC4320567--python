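"""Projection of flexibility profiles onto alignments and per-column
deviation flagging."""

import numpy as np
import pytest

from cryoscan.family_assembly import AlignedRow, FamilyAlignment
from cryoscan.flexibility_deviation import (
    AlignedParameterMatrix,
    DeviationSite,
    column_stats,
    map_to_representative,
    project_profiles,
    summarize,
)
from cryoscan.protein_parameters import ParameterProfile, flexibility_profile


def profile_from_values(pid, values, w=1):
    values = np.asarray(values, dtype=float)
    return ParameterProfile(
        protein_id=pid,
        parameter="flexibility",
        window=w,
        positions=np.arange(1, len(values) + 1),
        values=values,
        whole_protein=float(values.mean()) if len(values) else float("nan"),
    )


def matrix_from(rows):
    """rows: list of (id, group, per-column values with None for absent)."""
    import pandas as pd

    data = {pid: [np.nan if v is None else v for v in vals] for pid, _, vals in rows}
    df = pd.DataFrame(data).T
    return AlignedParameterMatrix(
        family="t", values=df, groups={pid: g for pid, g, _ in rows}
    )


class TestProjectProfiles:
    def test_ungapped_is_identity(self):
        aln = FamilyAlignment(
            "t",
            [
                AlignedRow("p1", "psychrophile", "ACDEF"),
                AlignedRow("m1", "mesophile", "ACDEF"),
            ],
        )
        profiles = {
            "p1": profile_from_values("p1", [1, 2, 3, 4, 5]),
            "m1": profile_from_values("m1", [5, 4, 3, 2, 1]),
        }
        mat = project_profiles(profiles, aln)
        assert np.allclose(mat.values.loc["p1"], [1, 2, 3, 4, 5])

    def test_gap_offset_bookkeeping(self):
        aln = FamilyAlignment("t", [AlignedRow("p1", "psychrophile", "AC-DEF")])
        mat = project_profiles(
            {"p1": profile_from_values("p1", [10, 20, 30, 40, 50])}, aln
        )
        row = mat.values.loc["p1"]
        # residue 3 (value 30) lands in column 3 (0-based), after the gap
        assert row[3] == 30
        assert np.isnan(row[2])

    def test_windowed_profile_lands_on_centers(self):
        seq = "ACDEFGHIKLMNP"
        aln = FamilyAlignment("t", [AlignedRow("p1", "psychrophile", seq)])
        prof = flexibility_profile(seq, protein_id="p1")
        mat = project_profiles({"p1": prof}, aln)
        row = mat.values.loc["p1"].to_numpy()
        assert np.isnan(row[:4]).all()  # positions before the first center
        assert np.allclose(row[4 : 4 + len(prof)], prof.values)

    def test_empty_profile_contributes_nothing(self):
        aln = FamilyAlignment("t", [AlignedRow("p1", "psychrophile", "ACD")])
        mat = project_profiles({"p1": profile_from_values("p1", [])}, aln)
        assert np.isnan(mat.values.loc["p1"]).all()

    def test_length_mismatch_rejected(self):
        aln = FamilyAlignment("t", [AlignedRow("p1", "psychrophile", "ACD")])
        with pytest.raises(ValueError, match="p1"):
            project_profiles({"p1": profile_from_values("p1", [1, 2, 3, 4])}, aln)


class TestColumnStats:
    def test_worked_example(self):
        mat = matrix_from(
            [
                ("p1", "psychrophile", [1.00]),
                ("p2", "psychrophile", [1.02]),
                ("m1", "mesophile", [0.90]),
                ("m2", "mesophile", [0.91]),
            ]
        )
        sites = column_stats(mat)
        assert len(sites) == 1
        s = sites[0]
        assert s.delta == pytest.approx(0.105)
        assert s.sd_psy == pytest.approx(0.01414, abs=1e-4)
        assert s.sd_meso == pytest.approx(0.00707, abs=1e-4)
        assert s.flagged
        assert s.direction == "psychrophile-higher"

    def test_identical_groups_not_flagged(self):
        mat = matrix_from(
            [
                ("p1", "psychrophile", [1.0]),
                ("p2", "psychrophile", [1.0]),
                ("m1", "mesophile", [1.0]),
                ("m2", "mesophile", [1.0]),
            ]
        )
        s = column_stats(mat)[0]
        assert s.delta == 0.0 and not s.flagged

    def test_single_value_column_skipped(self):
        mat = matrix_from(
            [
                ("p1", "psychrophile", [1.0, 1.0]),
                ("p2", "psychrophile", [None, 1.0]),
                ("m1", "mesophile", [0.9, 0.9]),
                ("m2", "mesophile", [0.9, 0.9]),
            ]
        )
        sites = column_stats(mat)
        assert [s.column for s in sites] == [1]

    def test_label_swap_negates_deltas(self):
        rows = [
            ("p1", "psychrophile", [1.0, 0.5]),
            ("p2", "psychrophile", [1.1, 0.6]),
            ("m1", "mesophile", [0.8, 0.9]),
            ("m2", "mesophile", [0.85, 0.95]),
        ]
        swapped = [
            (pid, "mesophile" if g == "psychrophile" else "psychrophile", v)
            for pid, g, v in rows
        ]
        a = column_stats(matrix_from(rows))
        b = column_stats(matrix_from(swapped))
        for sa, sb in zip(a, b):
            assert sa.delta == pytest.approx(-sb.delta)
            assert sa.flagged == sb.flagged

    def test_translation_invariance_of_flags(self):
        rows = [
            ("p1", "psychrophile", [1.0, 0.5]),
            ("p2", "psychrophile", [1.1, 0.6]),
            ("m1", "mesophile", [0.8, 0.9]),
            ("m2", "mesophile", [0.85, 0.95]),
        ]
        shifted = [(pid, g, [v + 100.0 for v in vals]) for pid, g, vals in rows]
        a = column_stats(matrix_from(rows))
        b = column_stats(matrix_from(shifted))
        assert [s.flagged for s in a] == [s.flagged for s in b]

    def test_missing_group_rejected(self):
        mat = matrix_from([("p1", "psychrophile", [1.0])])
        with pytest.raises(ValueError):
            column_stats(mat)


class TestSummarize:
    def site(self, col, delta, flagged):
        sd = 0.0 if flagged else abs(delta)  # sd sum below/above |delta|
        return DeviationSite(
            column=col, mean_psy=delta, mean_meso=0.0, sd_psy=sd, sd_meso=sd
        )

    def test_sums_and_counts(self):
        sites = [
            self.site(0, +0.105, True),
            self.site(1, -0.02, False),
            self.site(2, +0.01, False),
        ]
        summ = summarize(sites)
        assert summ.sum_delta_all == pytest.approx(0.095)
        assert summ.sum_delta_flagged == pytest.approx(0.105)
        assert summ.n_flagged_psy_higher == 1
        assert summ.n_flagged_meso_higher == 0

    def test_no_flags(self):
        summ = summarize([self.site(0, 0.5, False)])
        assert summ.n_flagged == 0
        assert summ.sum_delta_flagged == 0.0


class TestMapToRepresentative:
    def flagged_sites(self, cols):
        return [
            DeviationSite(column=c, mean_psy=1.0, mean_meso=0.0, sd_psy=0.1, sd_meso=0.1)
            for c in cols
        ]

    def test_ungapped_representative_offsets_by_one(self):
        aln = FamilyAlignment("t", [AlignedRow("r", "uniprot", "ACDEF")])
        mapped, dropped = map_to_representative(self.flagged_sites([0, 2]), aln, "r")
        assert [pos for pos, _ in mapped] == [1, 3]
        assert dropped == 0

    def test_gapped_columns_dropped_and_counted(self):
        aln = FamilyAlignment("t", [AlignedRow("r", "uniprot", "A-C-E")])
        mapped, dropped = map_to_representative(self.flagged_sites([0, 1, 2]), aln, "r")
        assert [pos for pos, _ in mapped] == [1, 2]
        assert dropped == 1

    def test_unknown_representative_rejected(self):
        aln = FamilyAlignment("t", [AlignedRow("r", "uniprot", "ACD")])
        with pytest.raises(KeyError):
            map_to_representative([], aln, "missing")
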