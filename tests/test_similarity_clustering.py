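"""Kimura distances, NMDS embedding, outlier culling, patristic distances,
and embedding validation."""

import io
import math

import numpy as np
import pytest
from Bio import Phylo
from skbio import DistanceMatrix

from cryoscan.family_assembly import AlignedRow, FamilyAlignment
from cryoscan.similarity_clustering import (
    Embedding,
    UndefinedDistanceError,
    choose_dimensions,
    cull_outliers,
    distance_matrix,
    kimura_distance,
    nmds,
    patristic_distances,
    select_clusters,
    validate_embedding,
)
from cryoscan.synthetic_data import generate_tree_distances


class TestKimuraDistance:
    def test_identical_rows_zero(self):
        assert kimura_distance("MKVL", "MKVL") == 0.0

    def test_closed_form_at_p_01(self):
        # 1 mismatch over 10 comparable columns
        a = "AAAAAAAAAA"
        b = "CAAAAAAAAA"
        assert kimura_distance(a, b) == pytest.approx(-math.log(1 - 0.1 - 0.2 * 0.01))
        assert kimura_distance(a, b) == pytest.approx(0.10758, abs=1e-5)

    def test_saturation_capped(self):
        a = "AAAAAAAAAA"
        b = "CCCCCCCCCA"  # p = 0.9
        with pytest.warns(UserWarning, match="capping"):
            assert kimura_distance(a, b) == 10.0

    def test_gap_columns_excluded_pairwise(self):
        # gaps leave 4 comparable columns with 1 mismatch
        a = "AC-DEF"
        b = "ACQD-F"
        d = kimura_distance(a, b)
        assert d == 0.0  # comparable columns A,C,D,F all match
        assert kimura_distance("AC-DEF", "GCQD-F") > 0

    def test_all_gap_overlap_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            kimura_distance("AA--", "--AA")

    def test_symmetry(self, rng):
        residues = list("ACDEFGHIKLMNPQRSTVWY-")
        for _ in range(20):
            a = "".join(rng.choice(residues, size=30))
            b = "".join(rng.choice(residues, size=30))
            try:
                assert kimura_distance(a, b) == pytest.approx(kimura_distance(b, a))
            except UndefinedDistanceError:
                pass


class TestDistanceMatrix:
    def test_pairwise_values_match_scalar_function(self, small_family):
        dm = distance_matrix(small_family)
        rows = {r.protein_id: r.sequence for r in small_family.rows}
        for i, a in enumerate(dm.ids):
            for j, b in enumerate(dm.ids):
                if i < j:
                    assert dm.data[i, j] == pytest.approx(
                        kimura_distance(rows[a], rows[b])
                    )

    def test_symmetric_zero_diagonal(self, small_family):
        dm = distance_matrix(small_family)
        assert np.allclose(dm.data, dm.data.T)
        assert np.allclose(np.diag(dm.data), 0)


class TestChooseDimensions:
    @pytest.mark.parametrize(
        "n,k", [(3, 3), (2999, 3), (3000, 4), (6000, 4), (6001, 5), (50000, 5)]
    )
    def test_rule(self, n, k):
        assert choose_dimensions(n) == k

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            choose_dimensions(2)


class TestNMDS:
    def planted(self, rng, n=10):
        pts = rng.normal(size=(n, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return pts, DistanceMatrix(d, [f"p{i}" for i in range(n)])

    def test_recovers_planted_configuration(self, rng):
        pts, dm = self.planted(rng)
        emb = nmds(dm, k=2, seed=3, n_starts=4, max_iter=1000)
        assert emb.stress < 0.05
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(pts, emb.coordinates)
        assert math.sqrt(1 - disparity) > 0.99

    def test_simplex_embeds_exactly(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(d, list("abcd"))
        emb = nmds(dm, k=3, seed=0, max_iter=1000)
        assert emb.stress < 1e-3

    def test_deterministic_under_seed(self, rng):
        _, dm = self.planted(rng)
        a = nmds(dm, k=2, seed=11)
        b = nmds(dm, k=2, seed=11)
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_stress_non_increasing_in_k(self, rng):
        # random (non-Euclidean) dissimilarities keep stress well away from 0
        d = np.triu(rng.uniform(1, 2, size=(12, 12)), k=1)
        d = d + d.T
        dm = DistanceMatrix(d, [f"p{i}" for i in range(12)])
        stresses = [nmds(dm, k=k, seed=5, max_iter=500).stress for k in (2, 3, 4)]
        assert stresses[0] >= stresses[1] - 1e-3
        assert stresses[1] >= stresses[2] - 1e-3


def embedding_from(coords, groups=None):
    ids = [f"p{i}" for i in range(len(coords))]
    return Embedding(
        ids=ids,
        coordinates=np.asarray(coords, dtype=float),
        k=2,
        stress=0.0,
        seed=0,
        groups=groups or {},
    )


class TestCullOutliers:
    def test_far_point_culled(self):
        # two concentric rings keep the distance spread (hence MAD) wide
        angles = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        ring = np.c_[np.cos(angles), np.sin(angles)]
        coords = np.vstack([0.5 * ring, 1.5 * ring, [[50.0, 50.0]]])
        kept, culled = cull_outliers(embedding_from(coords))
        assert culled == ["p20"]
        assert len(kept) == 20

    def test_identical_points_not_culled(self):
        kept, culled = cull_outliers(embedding_from(np.zeros((5, 2))))
        assert culled == []

    def test_infinite_threshold_keeps_all(self, rng):
        coords = rng.normal(size=(10, 2))
        kept, culled = cull_outliers(embedding_from(coords), mad_k=math.inf)
        assert culled == []


class TestSelectClusters:
    def test_box_containing_all(self):
        emb = embedding_from([[0, 0], [1, 1], [2, 2]], {"p0": "uniprot"})
        sel = select_clusters(emb, {"c0": ((-1, 3), (-1, 3))})
        assert sel[0].member_ids == ["p0", "p1", "p2"]
        assert sel[0].contains_reference

    def test_empty_box(self):
        emb = embedding_from([[0, 0], [1, 1]])
        sel = select_clusters(emb, {"c0": ((10, 20), (10, 20))})
        assert sel[0].member_ids == []
        assert not sel[0].contains_reference

    def test_planted_partition_recovered(self, rng):
        left = rng.normal(loc=(-5, 0), scale=0.3, size=(10, 2))
        right = rng.normal(loc=(5, 0), scale=0.3, size=(10, 2))
        emb = embedding_from(np.vstack([left, right]))
        sel = select_clusters(
            emb, {"L": ((-8, -2), (-3, 3)), "R": ((2, 8), (-3, 3))}
        )
        assert {s.cluster_id: set(s.member_ids) for s in sel} == {
            "L": {f"p{i}" for i in range(10)},
            "R": {f"p{i}" for i in range(10, 20)},
        }

    def test_overlapping_boxes_warn(self):
        emb = embedding_from([[0, 0]])
        with pytest.warns(UserWarning, match="overlap"):
            select_clusters(emb, {"a": ((-1, 1), (-1, 1)), "b": ((-2, 2), (-2, 2))})

    def test_degenerate_box_rejected(self):
        emb = embedding_from([[0, 0]])
        with pytest.raises(ValueError):
            select_clusters(emb, {"bad": ((1, 1), (0, 2))})


class TestPatristic:
    def test_two_leaf_path(self):
        dm = patristic_distances("(A:1,B:2);")
        assert dm["A", "B"] == pytest.approx(3.0)

    def test_three_leaf_paths(self):
        dm = patristic_distances("(A:1,(B:2,C:3):1);")
        assert dm["A", "B"] == pytest.approx(4.0)
        assert dm["A", "C"] == pytest.approx(5.0)
        assert dm["B", "C"] == pytest.approx(5.0)

    def test_missing_branch_length_raises(self):
        with pytest.raises(ValueError, match="branch length"):
            patristic_distances("(A:1,B);")

    @pytest.mark.parametrize("n_tips", [4, 8, 16, 32])
    def test_matches_independent_path_sum_oracle(self, n_tips):
        newick, _ = generate_tree_distances(n_tips, seed=n_tips)
        dm = patristic_distances(newick)
        tree = Phylo.read(io.StringIO(newick), "newick")
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1 :]:
                assert dm[a, b] == pytest.approx(tree.distance(a, b), rel=1e-9)

    def test_four_point_condition(self):
        newick, _ = generate_tree_distances(8, seed=99)
        dm = patristic_distances(newick)
        ids = list(dm.ids)
        rng = np.random.default_rng(0)
        for _ in range(20):
            i, j, k, l = rng.choice(len(ids), size=4, replace=False)
            sums = sorted(
                [
                    dm.data[i, j] + dm.data[k, l],
                    dm.data[i, k] + dm.data[j, l],
                    dm.data[i, l] + dm.data[j, k],
                ]
            )
            assert sums[1] == pytest.approx(sums[2], rel=1e-9)


class TestValidateEmbedding:
    def embedding(self, rng, n=30):
        return embedding_from(rng.normal(size=(n, 2)))

    def other_from(self, emb, transform):
        ids = emb.ids
        xy = emb.coordinates
        n = len(ids)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                e = np.linalg.norm(xy[i] - xy[j])
                d[i, j] = d[j, i] = transform(e)
        return DistanceMatrix(d, ids)

    def test_exact_monotone_transform_gives_r2_one(self, rng):
        emb = self.embedding(rng)
        other = self.other_from(emb, lambda e: 2.0 * math.log(e) + 5.0)
        val = validate_embedding(emb, other, form="log-linear")
        assert val.r_squared > 0.999
        assert val.slope == pytest.approx(0.5, rel=1e-3)

    def test_log_log_power_law_gives_r2_one(self, rng):
        emb = self.embedding(rng)
        other = self.other_from(emb, lambda e: e**1.7)
        val = validate_embedding(emb, other, form="log-log")
        assert val.r_squared > 0.999
        assert val.slope == pytest.approx(1 / 1.7, rel=1e-3)

    def test_decoupled_values_give_r2_near_zero(self, rng):
        emb = self.embedding(rng, n=40)
        other = self.other_from(emb, lambda e: float(rng.uniform(1, 2)))
        val = validate_embedding(emb, other, form="log-linear")
        assert val.r_squared < 0.05

    def test_subsample_larger_than_pairs_uses_all(self, rng):
        emb = self.embedding(rng, n=10)
        other = self.other_from(emb, lambda e: e + 1)
        val = validate_embedding(emb, other, n_sub=10_000)
        assert val.n_points == 45

    def test_too_few_pairs_raises(self, rng):
        emb = embedding_from([[0, 0], [1, 1]])
        other = DistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]), emb.ids)
        with pytest.raises(ValueError):
            validate_embedding(emb, other)
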