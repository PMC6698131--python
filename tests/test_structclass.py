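"""Kabsch superposition, RMSD matrices, trees, cutoff clustering, enrichment."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from nsltpkit import structclass as sc
from nsltpkit.exceptions import GeometryError, InputError, LookupIdError
from nsltpkit.msa import Alignment


def _coords(cid, array):
    array = np.asarray(array, dtype=float)
    return sc.CoordinateSet(cid, array, tuple(range(1, len(array) + 1)))


def _identity_corr(n):
    return sc.Correspondence(tuple((i, i) for i in range(n)))


RNG = np.random.default_rng(42)


class TestKabsch:
    def test_identical_sets(self):
        a = _coords("a", RNG.normal(size=(5, 3)))
        res = sc.kabsch_superpose(a, a, _identity_corr(5))
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_invariance(self):
        pts = RNG.normal(size=(8, 3))
        rot = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        moved = pts @ rot.T + np.array([5.0, -2.0, 1.0])
        a, b = _coords("a", pts), _coords("b", moved)
        res = sc.kabsch_superpose(a, b, _identity_corr(8))
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.transform(moved), pts, atol=1e-8)

    def test_scaled_square_residual(self):
        square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], float)
        a, b = _coords("a", square), _coords("b", 2 * square)
        res = sc.kabsch_superpose(a, b, _identity_corr(4))
        assert res.rmsd == pytest.approx(np.sqrt(0.5), abs=1e-9)

    def test_rotation_always_proper(self):
        # mirror-image configuration must not yield a reflection
        pts = RNG.normal(size=(6, 3))
        mirrored = pts * np.array([1, 1, -1])
        res = sc.kabsch_superpose(_coords("a", pts), _coords("b", mirrored), _identity_corr(6))
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_matches_rotation_search_oracle(self):
        """Optimality vs a coarse rotation-grid search refined numerically."""
        for trial in range(3):
            pa = RNG.normal(size=(5, 3))
            pb = RNG.normal(size=(5, 3))
            a, b = _coords("a", pa), _coords("b", pb)
            res = sc.kabsch_superpose(a, b, _identity_corr(5))
            qa, qb = pa - pa.mean(0), pb - pb.mean(0)

            def rmsd_of(rotvec):
                r = Rotation.from_rotvec(rotvec).as_matrix()
                return np.sqrt(((qa - qb @ r.T) ** 2).sum() / 5)

            best = np.inf
            grid = np.linspace(-np.pi, np.pi, 7)
            for x in grid:
                for y in grid:
                    for z in grid:
                        opt = minimize(rmsd_of, [x, y, z], method="Nelder-Mead",
                                       options={"xatol": 1e-6, "fatol": 1e-9})
                        best = min(best, opt.fun)
            assert res.rmsd == pytest.approx(best, abs=1e-3)
            assert res.rmsd <= best + 1e-9  # Kabsch is the minimiser

    def test_never_worse_than_unrotated(self):
        pa, pb = RNG.normal(size=(7, 3)), RNG.normal(size=(7, 3))
        res = sc.kabsch_superpose(_coords("a", pa), _coords("b", pb), _identity_corr(7))
        qa, qb = pa - pa.mean(0), pb - pb.mean(0)
        unrotated = np.sqrt(((qa - qb) ** 2).sum() / 7)
        assert res.rmsd <= unrotated + 1e-12

    def test_too_few_or_collinear_pairs(self):
        with pytest.raises(GeometryError):
            sc.kabsch_superpose(
                _coords("a", [[0, 0, 0], [1, 0, 0]]),
                _coords("b", [[0, 0, 0], [1, 0, 0]]),
                _identity_corr(2),
            )
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], float)
        with pytest.raises(GeometryError):
            sc.kabsch_superpose(_coords("a", line), _coords("b", line), _identity_corr(4))


class TestPairwiseMatrix:
    def test_identical_structures_zero_matrix(self):
        pts = RNG.normal(size=(6, 3))
        structs = [_coords(f"s{i}", pts) for i in range(3)]
        m = sc.pairwise_rmsd_matrix(structs, sc.identity_correspondences(structs))
        assert np.allclose(m.values, 0.0, atol=1e-9)

    def test_symmetry_and_invariants(self, bundle_fixture):
        structures, _ = bundle_fixture
        m = sc.pairwise_rmsd_matrix(
            structures, sc.identity_correspondences(structures)
        )
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0)
        assert (m.values >= 0).all()

    def test_missing_correspondence_names_pair(self):
        pts = RNG.normal(size=(5, 3))
        structs = [_coords("x", pts), _coords("y", pts)]
        with pytest.raises(LookupIdError, match="x.*y"):
            sc.pairwise_rmsd_matrix(structs, {})

    def test_planted_magnitudes(self, bundle_fixture):
        structures, truth = bundle_fixture
        m = sc.pairwise_rmsd_matrix(
            structures, sc.identity_correspondences(structures)
        )
        within, between = [], []
        for i, a in enumerate(m.ids):
            for b in m.ids[i + 1 :]:
                d = m.distance(a, b)
                if truth.cluster_assignment[a] == truth.cluster_assignment[b]:
                    within.append(d)
                else:
                    between.append(d)
        assert max(within) < 2.0  # ~ sigma*sqrt(6) scale
        assert min(between) > 0.5 * truth.planted_rmsd_scale


class TestDistanceTree:
    def test_additive_four_taxon_round_trip(self):
        # matrix generated from tree ((A:1,B:2):1,(C:3,D:4))
        ids = ("A", "B", "C", "D")
        d = {
            ("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
            ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7,
        }
        values = np.zeros((4, 4))
        for (x, y), v in d.items():
            i, j = ids.index(x), ids.index(y)
            values[i, j] = values[j, i] = v
        tree = sc.build_distance_tree(sc.RMSDMatrix(ids, values))
        for (x, y), v in d.items():
            assert sc.tree_path_distance(tree, x, y) == pytest.approx(v, abs=1e-9)

    def test_three_taxa_closed_form(self):
        ids = ("A", "B", "C")
        values = np.array([[0, 2.0, 3.0], [2.0, 0, 4.0], [3.0, 4.0, 0]])
        tree = sc.build_distance_tree(sc.RMSDMatrix(ids, values))
        # three-point formulas: a=(AB+AC-BC)/2 etc.; path lengths reproduce input
        for i in range(3):
            for j in range(i + 1, 3):
                assert sc.tree_path_distance(tree, ids[i], ids[j]) == pytest.approx(
                    values[i, j], abs=1e-9
                )

    def test_two_taxa_rejected(self):
        with pytest.raises(InputError):
            sc.build_distance_tree(sc.RMSDMatrix(("A", "B"), np.array([[0, 1.0], [1.0, 0]])))


def _random_metricish_matrix(rng, n):
    """Random symmetric non-negative matrix with zero diagonal."""
    values = rng.uniform(0.5, 10.0, size=(n, n))
    values = (values + values.T) / 2
    np.fill_diagonal(values, 0.0)
    return sc.RMSDMatrix(tuple(f"s{i:02d}" for i in range(n)), values)


class TestCutClusters:
    def test_three_point_example(self):
        ids = ("A", "B", "C")
        values = np.array([[0, 1.0, 5.0], [1.0, 0, 5.0], [5.0, 5.0, 0]])
        part = sc.cut_clusters(sc.RMSDMatrix(ids, values), 1.5)
        assert [c.member_ids for c in part] == [("A", "B"), ("C",)]

    def test_large_cutoff_single_cluster(self, bundle_fixture):
        structures, _ = bundle_fixture
        m = sc.pairwise_rmsd_matrix(structures, sc.identity_correspondences(structures))
        part = sc.cut_clusters(m, float(m.values.max()) + 0.1)
        assert len(part) == 1 and len(part[0].member_ids) == len(m.ids)

    def test_tiny_cutoff_all_singletons(self):
        m = _random_metricish_matrix(np.random.default_rng(1), 6)
        part = sc.cut_clusters(m, float(m.values[m.values > 0].min()) / 2)
        assert all(len(c.member_ids) == 1 for c in part)

    def test_partition_and_cutoff_invariants(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            m = _random_metricish_matrix(rng, 10)
            cutoff = float(rng.uniform(1, 9))
            part = sc.cut_clusters(m, cutoff)
            seen = [sid for c in part for sid in c.member_ids]
            assert sorted(seen) == sorted(m.ids)  # disjoint cover
            for c in part:
                for a in c.member_ids:
                    for b in c.member_ids:
                        assert m.distance(a, b) <= cutoff + 1e-12

    def test_nested_cutoffs_refine(self):
        rng = np.random.default_rng(9)
        m = _random_metricish_matrix(rng, 12)
        coarse = {frozenset(c.member_ids) for c in sc.cut_clusters(m, 8.0)}
        fine = sc.cut_clusters(m, 3.0)
        for c in fine:
            members = frozenset(c.member_ids)
            assert any(members <= parent for parent in coarse)

    def test_matches_scipy_complete_linkage(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(13)
        for _ in range(5):
            m = _random_metricish_matrix(rng, 12)  # distinct distances: no ties
            cutoff = float(rng.uniform(2, 8))
            ours = {frozenset(c.member_ids) for c in sc.cut_clusters(m, cutoff)}
            z = linkage(squareform(m.values), method="complete")
            flat = fcluster(z, t=cutoff, criterion="distance")
            theirs = {}
            for sid, lab in zip(m.ids, flat):
                theirs.setdefault(lab, set()).add(sid)
            assert ours == {frozenset(v) for v in theirs.values()}


class TestMedoid:
    def test_singleton(self):
        m = _random_metricish_matrix(np.random.default_rng(2), 4)
        assert sc.select_medoid([m.ids[2]], m) == m.ids[2]

    def test_hand_example(self):
        ids = ("A", "B", "C")
        values = np.array([[0, 1.0, 1.0], [1.0, 0, 3.0], [1.0, 3.0, 0]])
        assert sc.select_medoid(ids, sc.RMSDMatrix(ids, values)) == "A"

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(2, 20))
            m = _random_metricish_matrix(rng, n)
            members = list(m.ids)
            got = sc.select_medoid(members, m)
            sums = {
                sid: sum(m.distance(sid, o) for o in members if o != sid)
                for sid in members
            }
            best = min(sums.values())
            assert sums[got] == pytest.approx(best)
            assert got == min(s for s, v in sums.items() if v == pytest.approx(best))

    def test_absent_member(self):
        m = _random_metricish_matrix(np.random.default_rng(4), 3)
        with pytest.raises(LookupIdError):
            sc.select_medoid(["nope"], m)


class TestEnrichment:
    def test_printed_count_fractions(self):
        # 402-member cluster with 28 annotated; a 43-member cluster capturing
        # 10 of 31 annotated overall
        big = [f"b{i}" for i in range(402)]
        small = [f"d{i}" for i in range(43)]
        ann = {sid: {"defense"} for sid in big[:28]}
        df = sc.annotation_enrichment([big], ann, ["defense"])
        assert df.loc[0, "annotated_fraction"] == pytest.approx(28 / 402)

        ann2 = {sid: {"defense"} for sid in small[:10]}
        ann2.update({f"o{i}": {"defense"} for i in range(21)})
        others = [f"o{i}" for i in range(100)]
        df2 = sc.annotation_enrichment([small, others], ann2, ["defense"])
        assert df2.loc[0, "captured_fraction"] == pytest.approx(10 / 31)

    def test_empty_annotations_all_zero(self):
        df = sc.annotation_enrichment([["a", "b"], ["c"]], {}, ["defense"])
        assert (df["annotated_count"] == 0).all()
        assert (df["captured_fraction"] == 0).all()

    def test_empty_keywords_rejected(self):
        with pytest.raises(InputError):
            sc.annotation_enrichment([["a"]], {}, [])


class TestResiduePairDistance:
    def test_three_four_five(self):
        a = _coords("a", [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        b = _coords("b", [[3, 4, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        sup = sc.SuperpositionResult(np.eye(3), np.zeros(3), 0.0)
        assert sc.residue_pair_distance(a, b, sup, 1, 1) == pytest.approx(5.0)

    def test_coincident_after_superposition(self):
        pts = RNG.normal(size=(4, 3))
        rot = Rotation.from_rotvec([0.2, 0.4, -0.6]).as_matrix()
        moved = pts @ rot.T + 1.5
        a, b = _coords("a", pts), _coords("b", moved)
        sup = sc.kabsch_superpose(a, b, _identity_corr(4))
        assert sc.residue_pair_distance(a, b, sup, 2, 2) == pytest.approx(0.0, abs=1e-8)

    def test_invariant_under_common_rigid_motion(self):
        pa, pb = RNG.normal(size=(5, 3)), RNG.normal(size=(5, 3))
        a, b = _coords("a", pa), _coords("b", pb)
        sup = sc.kabsch_superpose(a, b, _identity_corr(5))
        d0 = sc.residue_pair_distance(a, b, sup, 1, 3)
        extra = Rotation.from_rotvec([1.0, 0.1, -0.3]).as_matrix()
        shift = np.array([2.0, -1.0, 4.0])
        a2 = _coords("a", pa @ extra.T + shift)
        b2 = _coords("b", pb @ extra.T + shift)
        sup2 = sc.kabsch_superpose(a2, b2, _identity_corr(5))
        assert sc.residue_pair_distance(a2, b2, sup2, 1, 3) == pytest.approx(d0, abs=1e-8)


class TestIO:
    def test_pdb_round_trip(self, tmp_path, bundle_fixture):
        structures, _ = bundle_fixture
        p = tmp_path / "s.pdb"
        sc.write_ca_pdb(structures[0], p)
        back = sc.read_ca_coordinates(p)
        assert back.residue_numbers == structures[0].residue_numbers
        assert np.allclose(back.ca_coordinates, structures[0].ca_coordinates, atol=1e-3)

    def test_rmsd_matrix_round_trip(self, tmp_path):
        m = _random_metricish_matrix(np.random.default_rng(6), 5)
        p = tmp_path / "m.tsv"
        sc.write_rmsd_matrix(m, p)
        back = sc.read_rmsd_matrix(p)
        assert back.ids == m.ids
        assert np.allclose(back.values, m.values)

    def test_correspondence_tsv_round_trip(self, tmp_path):
        corrs = {("x", "y"): sc.Correspondence(((0, 1), (2, 3), (4, 5)))}
        p = tmp_path / "c.tsv"
        sc.write_correspondences(corrs, p)
        assert sc.read_correspondences(p) == corrs

    def test_correspondence_from_alignment(self):
        aln = Alignment.from_pairs([("x", "AC.D"), ("y", "A.GD")])
        corr = sc.correspondence_from_alignment(aln, "x", "y")
        assert corr.pairs == ((0, 0), (2, 2))
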