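"""Clonotyping, length-partition and structure clustering."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from repclust.clustering import (
    ClonotypeSettings,
    StructureSettings,
    cdr_rmsd,
    clonotype,
    cluster_length_identity,
    partition_by_cdr_lengths,
    structure_cluster,
    structure_cluster_sweep,
    superpose_framework,
)
from repclust.model_io import AntibodyRecord, BackboneModel
from repclust.pair_curation import normalized_levenshtein
from repclust.synthetic_repertoire import make_backbone_fixture


def _rec(aid, cdr3, v="V1", j="J1"):
    aa = "EVQLV" + cdr3 + "WGQGTLVTV"
    return AntibodyRecord(
        antibody_id=aid,
        heavy_aa=aa,
        regions={
            "heavy": {
                "CDR1": (1, 3),
                "CDR2": (3, 5),
                "CDR3": (5, 5 + len(cdr3)),
                "FR4": (5 + len(cdr3), len(aa)),
            }
        },
        v_call=v,
        j_call=j,
    )


def _partition(assignment):
    groups = {}
    for aid, cid in assignment.assignment.items():
        groups.setdefault(cid, set()).add(aid)
    return {frozenset(g) for g in groups.values()}


class TestClonotype:
    def test_transitive_chaining(self):
        """A–B and A–C at 0.889 identity chain B and C into one cluster
        even though B–C (0.778) is below the 0.8 cutoff."""
        a = "CARDLGYWF"
        b = a[:4] + "Q" + a[5:]
        c = a[:6] + "H" + a[7:]
        assert normalized_levenshtein(a, b, "max") == pytest.approx(8 / 9)
        assert normalized_levenshtein(a, c, "max") == pytest.approx(8 / 9)
        assert normalized_levenshtein(b, c, "max") == pytest.approx(7 / 9)
        result = clonotype([_rec("A", a), _rec("B", b), _rec("C", c)])
        assert _partition(result) == {frozenset({"A", "B", "C"})}

    def test_gene_partition_blocks_identical_cdrh3(self):
        result = clonotype([_rec("A", "CARDY", v="V1"), _rec("B", "CARDY", v="V2")])
        assert _partition(result) == {frozenset({"A"}), frozenset({"B"})}

    def test_all_below_cutoff_all_singletons(self):
        recs = [_rec("A", "CCCCCCCCC"), _rec("B", "DDDDDDDDD"), _rec("C", "EEEEEEEEE")]
        result = clonotype(recs)
        assert result.n_clusters == 3

    def test_missing_gene_call_listed(self):
        rec = _rec("A", "CARDY")
        bad = rec.with_(v_call=None)
        with pytest.raises(ValueError, match="A"):
            clonotype([bad])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        recs = [
            _rec(f"r{i}", "CARD" + "AG"[int(rng.integers(2))] + "YW", v=f"V{rng.integers(2)}")
            for i in range(20)
        ]
        p1 = _partition(clonotype(recs))
        rng.shuffle(recs)
        p2 = _partition(clonotype(recs))
        assert p1 == p2

    def test_matches_transitive_closure_oracle(self):
        """Single linkage equals the connected components of the
        thresholded identity graph (networkx oracle), 200 random
        instances of up to 50 records."""
        rng = np.random.default_rng(77)
        alphabet = "ACDEFG"
        for trial in range(200):
            n = int(rng.integers(3, 51))
            recs = []
            for i in range(n):
                L = int(rng.integers(6, 10))
                cdr3 = "".join(alphabet[k] for k in rng.integers(0, len(alphabet), L))
                recs.append(_rec(f"r{i}", cdr3, v=f"V{rng.integers(2)}", j=f"J{rng.integers(2)}"))
            settings = ClonotypeSettings(identity_cutoff=0.75)
            result = clonotype(recs, settings)
            g = nx.Graph()
            g.add_nodes_from(r.antibody_id for r in recs)
            for a, b in itertools.combinations(recs, 2):
                if (a.v_call, a.j_call) != (b.v_call, b.j_call):
                    continue
                if normalized_levenshtein(a.cdrh3, b.cdrh3, "max") >= 0.75:
                    g.add_edge(a.antibody_id, b.antibody_id)
            oracle = {frozenset(c) for c in nx.connected_components(g)}
            assert _partition(result) == oracle

    def test_raising_cutoff_refines(self):
        """A higher identity cutoff never merges previously separate
        clusters (monotone refinement)."""
        rng = np.random.default_rng(8)
        recs = []
        for i in range(30):
            base = list("CARDLGYWF")
            for p in rng.choice(9, size=int(rng.integers(0, 4)), replace=False):
                base[p] = "AG"[int(rng.integers(2))]
            recs.append(_rec(f"r{i}", "".join(base)))
        loose = clonotype(recs, ClonotypeSettings(identity_cutoff=0.7))
        strict = clonotype(recs, ClonotypeSettings(identity_cutoff=0.9))
        for cluster in _partition(strict):
            holders = {loose.assignment[a] for a in cluster}
            assert len(holders) == 1  # each strict cluster inside one loose cluster

    def test_dropping_j_match_coarsens(self):
        rng = np.random.default_rng(12)
        recs = [
            _rec(f"r{i}", "CARDLGYW", v="V1", j=f"J{rng.integers(3)}") for i in range(15)
        ]
        with_j = clonotype(recs, ClonotypeSettings())
        without_j = clonotype(recs, ClonotypeSettings(j_match=False))
        for cluster in _partition(with_j):
            holders = {without_j.assignment[a] for a in cluster}
            assert len(holders) == 1


class TestLengthPartition:
    def test_equal_tuples_share_label(self):
        a, b = _rec("A", "CARDY"), _rec("B", "CWRDY")
        labels = partition_by_cdr_lengths([a, b])
        assert labels["A"] == labels["B"]

    def test_cdrh3_length_difference_separates(self):
        labels = partition_by_cdr_lengths([_rec("A", "CARDY"), _rec("B", "CARDYW")])
        assert labels["A"] != labels["B"]

    def test_label_count_equals_distinct_tuples(self):
        rng = np.random.default_rng(4)
        recs = [_rec(f"r{i}", "C" * int(rng.integers(5, 10))) for i in range(40)]
        labels = partition_by_cdr_lengths(recs)
        assert len(set(labels.values())) == len({r.cdr_lengths() for r in recs})

    def test_length_only_equals_partition(self):
        recs = [_rec("A", "CARDY"), _rec("B", "CWWWW"), _rec("C", "CARDYW")]
        result = cluster_length_identity(recs, None)
        assert _partition(result) == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_identity_refines_length_partition(self):
        recs = [_rec("A", "CARDYWGAR"), _rec("B", "CARDYWGAW"), _rec("C", "WWWWWWWWW")]
        refined = cluster_length_identity(recs, 0.8)
        coarse = cluster_length_identity(recs, None)
        for cluster in _partition(refined):
            holders = {coarse.assignment[a] for a in cluster}
            assert len(holders) == 1
        assert _partition(refined) == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_strict_threshold(self):
        # same length, identity 7/9 < 0.8
        recs = [_rec("A", "CARDLGYWF"), _rec("B", "CARDLGWWW")]
        result = cluster_length_identity(recs, 0.8)
        assert result.n_clusters == 2


def _toy_model(aid, fw, cdr):
    atoms = [("H:FR1", i, "CA", np.asarray(x, dtype=float)) for i, x in enumerate(fw)]
    atoms += [
        ("H:CDR3", len(fw) + i, "CA", np.asarray(x, dtype=float)) for i, x in enumerate(cdr)
    ]
    return BackboneModel(aid, atoms, backbone_atoms=("CA",))


class TestSuperposition:
    def test_identical_models(self):
        fw = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]]
        m = _toy_model("a", fw, [[2, 2, 2]])
        R, t, rmsd = superpose_framework(m, m)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(1)
        fw = rng.normal(size=(6, 3))
        cdr = rng.normal(size=(4, 3))
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        trans = np.array([5.0, -3.0, 2.0])
        m1 = _toy_model("a", fw, cdr)
        m2 = _toy_model("b", (rot @ fw.T).T + trans, (rot @ cdr.T).T + trans)
        _, _, rmsd = superpose_framework(m1, m2)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert cdr_rmsd(m1, m2) == pytest.approx(0.0, abs=1e-8)

    def test_rotation_is_proper(self):
        rng = np.random.default_rng(2)
        m1 = _toy_model("a", rng.normal(size=(5, 3)), [[0, 0, 0]])
        # mirror image: naive SVD would return a reflection
        fw2 = rng.normal(size=(5, 3))
        m2 = _toy_model("b", fw2 * np.array([-1, 1, 1]), [[0, 0, 0]])
        R, _, _ = superpose_framework(m1, m2)
        assert np.linalg.det(R) == pytest.approx(1.0)

    def test_atom_count_mismatch(self):
        m1 = _toy_model("a", [[0, 0, 0], [1, 0, 0]], [[0, 1, 0]])
        m2 = _toy_model("b", [[0, 0, 0]], [[0, 1, 0]])
        with pytest.raises(ValueError, match="mismatch"):
            superpose_framework(m1, m2)

    def test_two_point_line_geometry(self):
        """Closed form: frameworks both two unit-spaced collinear points;
        superposition is exact, so CDR displacement d over k atoms gives
        RMSD d/sqrt(k) — here a single CDR atom off by d."""
        d = 0.8
        m1 = _toy_model("a", [[0, 0, 0], [1, 0, 0]], [[2, 0, 0]])
        m2 = _toy_model("b", [[0, 0, 0], [1, 0, 0]], [[2, d, 0]])
        assert cdr_rmsd(m1, m2) == pytest.approx(d)


class TestCdrRmsd:
    def test_single_displaced_atom_closed_form(self):
        """One CDR atom displaced by d among k atoms -> d/sqrt(k)."""
        fw = [[0, 0, 0], [1, 0, 0], [0, 1, 0]]
        cdr = [[3.0, 0, 0], [3.0, 1, 0], [3.0, 2, 0], [3.0, 3, 0]]
        m1 = _toy_model("a", fw, cdr)
        moved = [list(x) for x in cdr]
        moved[2][2] += 1.2
        m2 = _toy_model("b", fw, moved)
        assert cdr_rmsd(m1, m2) == pytest.approx(1.2 / np.sqrt(4))

    def test_symmetry(self, study_fixture):
        _, records = study_fixture
        cls = records[0].cdr_lengths()
        same = [r for r in records if r.cdr_lengths() == cls][:2]
        m = make_backbone_fixture(same, 0.6, seed=3)
        assert cdr_rmsd(m[0], m[1]) == pytest.approx(cdr_rmsd(m[1], m[0]), abs=1e-9)

    def test_class_mismatch_rejected(self):
        m1 = _toy_model("a", [[0, 0, 0], [1, 0, 0]], [[2, 0, 0]])
        m2 = _toy_model("b", [[0, 0, 0], [1, 0, 0]], [[2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="class"):
            cdr_rmsd(m1, m2)


class TestStructureCluster:
    def _noisy_models(self, n, scale, seed, cls_split=None):
        rng = np.random.default_rng(seed)
        base_fw = rng.normal(size=(6, 3)) * 5
        models = []
        for i in range(n):
            k = 5 if (cls_split is None or i < cls_split) else 7
            base_cdr = np.arange(k * 3).reshape(k, 3) * 1.0
            cdr = base_cdr + rng.normal(0, scale, size=(k, 3))
            rot = Rotation.random(rng=rng).as_matrix()
            t = rng.normal(0, 10, 3)
            models.append(
                _toy_model(f"m{i}", (rot @ base_fw.T).T + t, (rot @ cdr.T).T + t)
            )
        return models

    def test_all_far_apart_singletons(self):
        models = self._noisy_models(5, scale=5.0, seed=2)
        result = structure_cluster(models, StructureSettings(rmsd_cutoff=0.5))
        assert result.n_clusters == 5

    def test_zero_perturbation_one_cluster_per_class(self, study_fixture):
        _, records = study_fixture
        models = make_backbone_fixture(records[:12], perturbation_scale=0.0, seed=0)
        result = structure_cluster(models)
        assert result.n_clusters == len({m.cdr_length_class() for m in models})

    def test_never_merges_across_classes(self):
        models = self._noisy_models(6, scale=0.0, seed=3, cls_split=3)
        result = structure_cluster(models, StructureSettings(rmsd_cutoff=100.0))
        assert result.n_clusters == 2

    def test_matches_threshold_graph_oracle(self):
        """Single-linkage output equals transitive closure of the
        thresholded RMSD graph (brute force, <=20 models)."""
        rng = np.random.default_rng(31)
        for trial in range(20):
            models = self._noisy_models(int(rng.integers(4, 21)), scale=1.0, seed=100 + trial)
            cutoff = float(rng.uniform(0.5, 3.0))
            result = structure_cluster(models, StructureSettings(rmsd_cutoff=cutoff))
            g = nx.Graph()
            g.add_nodes_from(m.antibody_id for m in models)
            for a, b in itertools.combinations(models, 2):
                if cdr_rmsd(a, b) <= cutoff:
                    g.add_edge(a.antibody_id, b.antibody_id)
            oracle = {frozenset(c) for c in nx.connected_components(g)}
            assert _partition(result) == oracle

    def test_lowering_cutoff_refines(self):
        models = self._noisy_models(12, scale=1.0, seed=9)
        sweep = structure_cluster_sweep(models, StructureSettings(sweep=(1.0, 2.0)))
        fine, coarse = sweep[1.0], sweep[2.0]
        for cluster in _partition(fine):
            holders = {coarse.assignment[a] for a in cluster}
            assert len(holders) == 1

    def test_average_linkage_supported(self):
        models = self._noisy_models(8, scale=0.5, seed=5)
        result = structure_cluster(models, StructureSettings(linkage="average"))
        assert result.n_clustered == 8
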