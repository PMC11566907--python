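"""Hit calling, Tanimoto clustering, scaffolds, diversification, novelty."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from screentriage.hits import (
    ClusterSet,
    FingerprintError,
    build_similarity_graph,
    call_hits,
    canonical_smiles,
    diversify,
    label_scaffolds,
    ligand_efficiency_proxy,
    louvain_cluster,
    mcs_scaffold,
    morgan_fingerprints,
    novelty_counts,
    tanimoto,
    tanimoto_matrix,
    undefined_stereocenters,
)


def bitvec(on_bits, n=16):
    v = np.zeros(n, dtype=np.uint8)
    v[list(on_bits)] = 1
    return v


class TestHitCalling:
    def test_threshold_inclusive(self):
        records = pd.DataFrame(
            {"compound_id": ["a", "b", "c", "d"], "k_norm": [60.0, 40.0, 55.0, 50.0]}
        )
        assert call_hits(records, 50.0) == {"a", "c", "d"}
        assert len(call_hits(records.iloc[:3], 50.0)) == 2

    def test_zero_threshold_takes_nonnegative(self):
        records = pd.DataFrame(
            {"compound_id": ["a", "b", "c"], "k_norm": [0.0, -5.0, 10.0]}
        )
        assert call_hits(records, 0.0) == {"a", "c"}

    def test_missing_k_norm_rejected(self):
        records = pd.DataFrame({"compound_id": ["a"], "k_norm": [np.nan]})
        with pytest.raises(ValueError):
            call_hits(records)


class TestTanimoto:
    def test_handbook_values(self):
        assert tanimoto(bitvec({1, 2, 3}), bitvec({1, 2, 3})) == 1.0
        assert tanimoto(bitvec({0, 1}), bitvec({2, 3})) == 0.0
        assert tanimoto(bitvec({1, 2, 3}), bitvec({2, 3, 4})) == 0.5
        assert tanimoto(bitvec(set()), bitvec(set())) == 1.0  # documented convention

    def test_length_mismatch_rejected(self):
        with pytest.raises(FingerprintError):
            tanimoto(bitvec({1}, 8), bitvec({1}, 16))

    def test_agrees_with_rdkit_on_real_fingerprints(self):
        """Cross-check our bit arithmetic against RDKit's DataStructs."""
        smiles = ["c1ccccc1CCO", "c1ccccc1CCN", "CC(C)Cc1ccc(C)cc1C(C)C(=O)O"]
        fps = morgan_fingerprints(smiles)
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        rd = [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in smiles]
        for i in range(3):
            for j in range(3):
                expected = DataStructs.TanimotoSimilarity(rd[i], rd[j])
                assert tanimoto(fps[i], fps[j]) == pytest.approx(expected, abs=1e-12)
                assert tanimoto_matrix(fps)[i, j] == pytest.approx(expected, abs=1e-12)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_range(self, data):
        a = bitvec(data.draw(st.sets(st.integers(0, 15))))
        b = bitvec(data.draw(st.sets(st.integers(0, 15))))
        s = tanimoto(a, b)
        assert 0.0 <= s <= 1.0
        assert s == tanimoto(b, a)

    def test_salt_stripping(self):
        assert canonical_smiles("CCN.Cl") == canonical_smiles("CCN")


class TestSimilarityGraph:
    def test_impossible_threshold_gives_edgeless_graph(self):
        fps = np.vstack([bitvec({1, 2}), bitvec({1, 2}), bitvec({3})])
        g = build_similarity_graph(["a", "b", "c"], fps, edge_threshold=1.01)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 0

    def test_zero_threshold_gives_complete_graph(self):
        fps = np.vstack([bitvec({i}) for i in range(5)])
        g = build_similarity_graph(list("abcde"), fps, edge_threshold=0.0)
        assert g.number_of_edges() == 5 * 4 // 2

    def test_two_families_split_into_components(self):
        """Two internally-similar, mutually-dissimilar families separate at 0.4."""
        import networkx as nx

        fam1 = [bitvec({0, 1, 2, 3}), bitvec({0, 1, 2, 4}), bitvec({0, 1, 3, 4})]
        fam2 = [bitvec({8, 9, 10, 11}), bitvec({8, 9, 10, 12}), bitvec({8, 9, 11, 12})]
        # within-family TS = 3/5 = 0.6; across = 0
        fps = np.vstack(fam1 + fam2)
        g = build_similarity_graph([f"x{i}" for i in range(6)], fps, 0.4)
        comps = list(nx.connected_components(g))
        assert sorted(map(len, comps)) == [3, 3]


class TestLouvain:
    def test_edgeless_graph_gives_singletons(self):
        import networkx as nx

        g = nx.empty_graph(5)
        cs = louvain_cluster(g, seed=0)
        assert cs.n_clusters == 5 and cs.n_singletons == 5

    def test_two_cliques_recovered_for_any_seed(self):
        import networkx as nx

        g = nx.union(nx.complete_graph(4), nx.complete_graph(4), rename=("a", "b"))
        for seed in range(5):
            cs = louvain_cluster(g, seed=seed)
            parts = {frozenset(m) for m in cs.clusters.values()}
            assert parts == {
                frozenset({"a0", "a1", "a2", "a3"}),
                frozenset({"b0", "b1", "b2", "b3"}),
            }

    def test_partition_property_on_campaign(self, hit_records):
        hit_rec, fps = hit_records
        g = build_similarity_graph(hit_rec["compound_id"].tolist(), fps, 0.4)
        cs = louvain_cluster(g, seed=1)
        members = [m for ms in cs.clusters.values() for m in ms]
        assert sorted(members) == sorted(hit_rec["compound_id"])
        assert len(members) == len(set(members))


class TestScaffolds:
    def test_identical_structures_return_that_structure(self):
        smi = "Cc1ccccc1N"
        scaffold = mcs_scaffold([smi, smi, smi])
        patt = Chem.MolFromSmarts(scaffold)
        mol = Chem.MolFromSmiles(smi)
        assert mol.GetSubstructMatch(patt)
        assert patt.GetNumAtoms() == mol.GetNumAtoms()

    def test_shared_benzene_ring_only(self):
        """Structures sharing only a benzene ring yield a 6-atom aromatic MCS."""
        scaffold = mcs_scaffold(["c1ccccc1CCCO", "c1ccccc1NCC=O"])
        patt = Chem.MolFromSmarts(scaffold)
        assert patt.GetNumAtoms() == 6
        assert Chem.MolFromSmiles("c1ccccc1").HasSubstructMatch(patt)

    def test_singleton_gets_murcko_framework(self):
        scaffold = mcs_scaffold(["Cc1ccc(CC2CCNC2)cc1O"])
        mol = Chem.MolFromSmiles(scaffold)
        assert mol is not None
        # framework drops the acyclic decorations, keeps both rings + linker
        assert mol.GetRingInfo().NumRings() == 2

    def test_no_common_substructure_marks_empty(self):
        assert mcs_scaffold(["CCCC", "c1ccncc1"], min_atoms=3) == ""


class TestDiversify:
    def _clusters_and_records(self):
        members = {0: [f"a{i}" for i in range(7)], 1: ["b0", "b1", "b2"]}
        cs = ClusterSet(clusters=members)
        rows = []
        for i in range(7):
            rows.append({"compound_id": f"a{i}", "k_norm": 50.0 + 5 * i, "mw": 400.0})
        for i in range(3):
            rows.append({"compound_id": f"b{i}", "k_norm": 60.0, "mw": 300.0 + i})
        return cs, pd.DataFrame(rows)

    def test_le_proxy_direct_division_and_monotonicity(self):
        assert ligand_efficiency_proxy(80.0, 400.0) == pytest.approx(0.2)
        assert ligand_efficiency_proxy(0.0, 123.0) == 0.0
        assert ligand_efficiency_proxy(50.0, 200.0) > ligand_efficiency_proxy(50.0, 300.0)
        with pytest.raises(ValueError):
            ligand_efficiency_proxy(50.0, 0.0)

    def test_top_k_selected_small_clusters_kept_whole(self):
        cs, records = self._clusters_and_records()
        table = diversify(cs, records, k_per_cluster=5)
        sel = table[table["selected"]]
        assert len(sel[sel["cluster_id"] == 0]) == 5
        assert len(sel[sel["cluster_id"] == 1]) == 3
        # every selected member of cluster 0 outranks every unselected one
        c0 = table[table["cluster_id"] == 0]
        assert c0[c0.selected]["le_proxy"].min() >= c0[~c0.selected]["le_proxy"].max()
        # size identity: sum of min(k, |c|)
        assert len(sel) == min(5, 7) + min(5, 3)

    def test_ties_broken_by_compound_id(self):
        cs = ClusterSet(clusters={0: ["z", "a", "m"]})
        records = pd.DataFrame(
            {"compound_id": ["z", "a", "m"], "k_norm": [60.0] * 3, "mw": [300.0] * 3}
        )
        table = diversify(cs, records, k_per_cluster=2)
        assert sorted(table[table.selected]["compound_id"]) == ["a", "m"]


class TestLabels:
    def test_label_by_most_potent_member(self):
        cs = ClusterSet(clusters={0: ["a", "b"], 1: ["c"], 2: ["d"]})
        pic50 = {"a": 5.0, "b": 7.3, "c": 5.2}
        cs = label_scaffolds(cs, pic50)
        assert cs.labels[0] == "nanomolar"
        assert cs.labels[1] == "micromolar"
        assert cs.labels[2] == "unlabeled"


class TestNovelty:
    def test_reference_equals_hits_counts_everything(self):
        fps = np.vstack([bitvec({1, 2}), bitvec({3, 4}), bitvec({5, 6})])
        out = novelty_counts(["a", "b", "c"], fps, fps, thresholds=[0.0, 0.5, 0.99])
        assert out["hits"].tolist() == [3, 3, 3]

    def test_disjoint_chemotypes_count_zero(self):
        hits = np.vstack([bitvec({1, 2}), bitvec({3, 4})])
        ref = np.vstack([bitvec({10, 11})])
        out = novelty_counts(["a", "b"], hits, ref, thresholds=[0.4])
        assert out["hits"].tolist() == [0]

    def test_precomputed_nearest_neighbors(self):
        """Nearest-reference TS of {0.3, 0.5, 0.9} gives 2 hits above t=0.4."""
        hits = np.vstack(
            [
                bitvec({0, 1, 2, 3, 4, 5, 6, 7, 8, 9}, 32),   # vs ref0: 3/10 = 0.3
                bitvec({10, 11, 12, 13}, 32),                  # vs ref1: 2/4 = 0.5
                bitvec({20, 21, 22, 23, 24, 25, 26, 27, 28}, 32),  # vs ref2: 9/10
            ]
        )
        ref = np.vstack(
            [
                bitvec({0, 1, 2}, 32),
                bitvec({10, 11}, 32),
                bitvec({20, 21, 22, 23, 24, 25, 26, 27, 28, 29}, 32),
            ]
        )
        # brute-force oracle for the nearest-neighbor similarities
        nn = tanimoto_matrix(hits, ref).max(axis=1)
        np.testing.assert_allclose(nn, [0.3, 0.5, 0.9])
        out = novelty_counts(["a", "b", "c"], hits, ref, thresholds=[0.4])
        assert out["hits"].tolist() == [2]

    def test_monotone_in_threshold_with_scaffolds(self):
        rng = np.random.default_rng(5)
        hits = (rng.random((10, 64)) < 0.2).astype(np.uint8)
        ref = (rng.random((4, 64)) < 0.2).astype(np.uint8)
        cs = ClusterSet(clusters={0: [f"h{i}" for i in range(5)],
                                  1: [f"h{i}" for i in range(5, 10)]})
        out = novelty_counts(
            [f"h{i}" for i in range(10)], hits, ref,
            thresholds=[0.0, 0.2, 0.4, 0.6, 0.8], clusters=cs,
        )
        assert (out["hits"].diff().dropna() <= 0).all()
        assert (out["scaffolds"].diff().dropna() <= 0).all()

    def test_empty_reference_counts_zero(self):
        hits = np.vstack([bitvec({1})])
        out = novelty_counts(["a"], hits, np.zeros((0, 16)), thresholds=[0.1])
        assert out["hits"].tolist() == [0]


def test_undefined_stereocenter_helper():
    assert undefined_stereocenters("CC(O)C(N)CC") == 2
    assert undefined_stereocenters("c1ccccc1") == 0
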