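"""Disease functional similarity: relevance, FNSim, MICA, FNSemSim, normalization."""

import math

import numpy as np
import pandas as pd
import pytest

import lncdisap as ld
from lncdisap.disease_similarity import information_content
from tests.conftest import links_as_dict, oracle_fnsim, random_linkset


@pytest.fixture
def toy_net():
    net = ld.GeneLinkSet("gene")
    net.add("g1", "g2", 0.5)
    net.add("g1", "g3", 0.8)
    net.add("g1", "g4", 0.6)
    return net


class TestGeneSetRelevance:
    def test_membership_gives_one(self, toy_net):
        assert ld.gene_set_relevance("g1", {"g1", "g2"}, toy_net) == 1.0

    def test_no_links_gives_zero(self, toy_net):
        assert ld.gene_set_relevance("g9", {"g2", "g3"}, toy_net) == 0.0

    def test_max_over_links(self, toy_net):
        # g1 links to g3 (0.8) and g4 (0.6): max wins
        assert ld.gene_set_relevance("g1", {"g3", "g4"}, toy_net) == pytest.approx(0.8)

    def test_mean_mode_averages_positive_links(self, toy_net):
        v = ld.gene_set_relevance("g1", {"g3", "g4"}, toy_net, mode="mean")
        assert v == pytest.approx(0.7)


class TestFnsim:
    def test_identical_sets_give_one(self, toy_net):
        assert ld.fnsim({"g1", "g2"}, {"g1", "g2"}, toy_net) == 1.0

    def test_disjoint_sets_empty_net(self):
        assert ld.fnsim({"g1"}, {"g2"}, ld.GeneLinkSet("gene")) == 0.0

    def test_single_link_hand_value(self):
        net = ld.GeneLinkSet("gene")
        net.add("g1", "g2", 0.5)
        assert ld.fnsim({"g1"}, {"g2"}, net) == pytest.approx(0.5)

    def test_empty_set_degenerate(self, toy_net):
        assert ld.fnsim(set(), {"g1"}, toy_net) == 0.0

    def test_symmetry_and_range_on_random_instances(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(15)]
        for _ in range(200):
            net = random_linkset(rng, genes, int(rng.integers(0, 25)))
            Ga = set(rng.choice(genes, size=int(rng.integers(1, 6)), replace=False))
            Gb = set(rng.choice(genes, size=int(rng.integers(1, 6)), replace=False))
            ab = ld.fnsim(Ga, Gb, net)
            assert ab == pytest.approx(ld.fnsim(Gb, Ga, net), abs=1e-15)
            assert 0.0 <= ab <= 1.0
            assert ab == pytest.approx(oracle_fnsim(Ga, Gb, links_as_dict(net)), abs=1e-12)


class TestMica:
    def test_term_is_its_own_ancestor(self, diamond_ontology):
        assert ld.mica("D", "D", diamond_ontology) == "D"

    def test_siblings_under_sole_root(self):
        onto = ld.build_ontology([("B", "A"), ("C", "A")])
        table = ld.AssociationTable("disease", "gene")
        for d, g in [("B", "g1"), ("C", "g2"), ("A", "g3")]:
            table.add(d, g)
        ld.propagate_annotations(onto, table)
        assert ld.mica("B", "C", onto) == "A"

    def test_diamond_prefers_smaller_annotation_ancestor(self):
        # shared ancestors B (2 genes propagated) and C (3 genes): B wins
        onto = ld.build_ontology(
            [("D", "B"), ("D", "C"), ("E", "B"), ("E", "C"), ("B", "A"), ("C", "A")]
        )
        table = ld.AssociationTable("disease", "gene")
        for d, g in [("D", "g1"), ("E", "g2"), ("C", "g3"), ("A", "g4")]:
            table.add(d, g)
        ld.propagate_annotations(onto, table)
        # brute-force IC over the enumerated common-ancestor set
        common = onto.ancestors("D") & onto.ancestors("E")
        best = max(common, key=lambda t: information_content(t, onto))
        assert ld.mica("D", "E", onto) == best == "B"

    def test_disjoint_forest_has_no_mica(self):
        onto = ld.build_ontology([("B", "A"), ("D", "C")])
        table = ld.AssociationTable("disease", "gene")
        table.add("B", "g1")
        table.add("D", "g2")
        ld.propagate_annotations(onto, table)
        assert ld.mica("B", "D", onto) is None

    def test_ic_antitone_in_annotation_size(self, diamond_ontology):
        onto = diamond_ontology
        sizes = {t: len(onto.propagated[t]) for t in onto.terms}
        ics = {t: information_content(t, onto) for t in onto.terms}
        for a in onto.terms:
            for b in onto.terms:
                if sizes[a] < sizes[b]:
                    assert ics[a] > ics[b]

    def test_zero_annotation_term_never_wins(self):
        # Z is a common ancestor with no propagated genes (IC = -inf): the
        # annotated root A must win MICA instead.
        onto = ld.build_ontology([("B", "Z"), ("C", "Z"), ("Z", "A"), ("B", "A"), ("C", "A")])
        table = ld.AssociationTable("disease", "gene")
        table.add("A", "g1")
        table.add("A", "g2")
        onto_genes = ld.AssociationTable("disease", "gene")
        for d, g in [("B", "g3"), ("C", "g4"), ("A", "g1")]:
            onto_genes.add(d, g)
        ld.propagate_annotations(onto, onto_genes)
        onto.propagated["Z"] = set()  # sever Z's inherited genes
        assert information_content("Z", onto) == -math.inf
        assert ld.mica("B", "C", onto) == "A"


class TestFnsemsim:
    def test_self_similarity_collapses_ratio(self, diamond_ontology):
        onto = diamond_ontology
        net = ld.GeneLinkSet("gene")
        gene_sets = {"D": onto.propagated["D"]}
        # Ga = Gb = G_MICA = propagated set of D itself
        v = ld.fnsemsim("D", "D", gene_sets, net, onto)
        assert v == pytest.approx(ld.fnsim(gene_sets["D"], gene_sets["D"], net))

    def test_zero_fnsim_short_circuits(self, diamond_ontology):
        gene_sets = {"B": {"gx"}, "C": {"gy"}}
        assert ld.fnsemsim("B", "C", gene_sets, ld.GeneLinkSet("gene"), diamond_ontology) == 0.0

    def test_hand_evaluated_ratio(self):
        # |Ga|=2, |Gb|=3, |G_MICA|=6, fnsim=0.5 -> 0.5 * 6/36
        onto = ld.build_ontology([("B", "A"), ("C", "A")])
        table = ld.AssociationTable("disease", "gene")
        for g in ("b1", "b2"):
            table.add("B", g)
        for g in ("c1", "c2", "c3"):
            table.add("C", g)
        table.add("A", "a1")
        ld.propagate_annotations(onto, table)
        assert len(onto.propagated["A"]) == 6
        net = ld.GeneLinkSet("gene")
        for b in ("b1", "b2"):
            for c in ("c1", "c2", "c3"):
                net.add(b, c, 0.5)
        gene_sets = {"B": {"b1", "b2"}, "C": {"c1", "c2", "c3"}}
        assert ld.fnsim(gene_sets["B"], gene_sets["C"], net) == pytest.approx(0.5)
        v = ld.fnsemsim("B", "C", gene_sets, net, onto)
        assert v == pytest.approx(0.5 * 6 / 36)

    def test_empty_gene_set_gives_zero(self, diamond_ontology):
        assert ld.fnsemsim("B", "C", {"B": set(), "C": {"g"}},
                           ld.GeneLinkSet("gene"), diamond_ontology) == 0.0


class TestMinmaxNormalize:
    @staticmethod
    def _sym(vals, n, labels=None):
        mat = np.ones((n, n))
        iu = np.triu_indices(n, k=1)
        mat[iu] = vals
        mat[(iu[1], iu[0])] = vals
        labels = labels or [f"d{i}" for i in range(n)]
        return pd.DataFrame(mat, index=labels, columns=labels)

    def test_endpoints_map_to_zero_and_one(self):
        raw = self._sym([0.2, 0.5, 0.8], 3)
        norm = ld.minmax_normalize(raw)
        off = sorted(norm.to_numpy()[np.triu_indices(3, k=1)])
        assert off == pytest.approx([0.0, 0.5, 1.0])

    def test_constant_matrix_maps_to_zero(self):
        norm = ld.minmax_normalize(self._sym([0.3, 0.3, 0.3], 3))
        off = norm.to_numpy()[np.triu_indices(3, k=1)]
        assert (off == 0.0).all()

    def test_four_values_direct_formula(self):
        raw = self._sym([1.0, 3.0, 5.0, 9.0, 9.0, 1.0], 4)
        norm = ld.minmax_normalize(raw)
        vals = norm.to_numpy()[np.triu_indices(4, k=1)]
        assert sorted(set(np.round(vals, 12))) == pytest.approx([0.0, 0.25, 0.5, 1.0])

    def test_diagonal_pinned_to_one_and_order_preserved(self):
        raw = self._sym([0.1, 0.7, 0.4], 3)
        norm = ld.minmax_normalize(raw)
        assert np.allclose(np.diag(norm), 1.0)
        iu = np.triu_indices(3, k=1)
        assert (np.argsort(raw.to_numpy()[iu]) == np.argsort(norm.to_numpy()[iu])).all()
        assert norm.to_numpy().min() >= 0 and norm.to_numpy().max() <= 1


class TestSimilarityMatrix:
    def test_unannotated_disease_similar_only_to_itself(self):
        onto = ld.build_ontology([("B", "A"), ("C", "A"), ("E", "A")])
        table = ld.AssociationTable("disease", "gene")
        table.add("B", "g1")
        table.add("C", "g1")
        ld.propagate_annotations(onto, table)
        sim = ld.disease_similarity_matrix(["B", "C", "E"], onto, ld.GeneLinkSet("gene"))
        assert sim.at["E", "B"] == 0.0
        assert sim.at["E", "C"] == 0.0
        assert sim.at["E", "E"] == 1.0

    def test_matrix_symmetric_in_unit_interval(self, planted_bundle):
        b = planted_bundle
        diseases = sorted(b.lnc_disease_old.rights())
        sim = ld.disease_similarity_matrix(diseases, b.ontology, b.gene_links)
        arr = sim.to_numpy()
        assert np.allclose(arr, arr.T)
        assert arr.min() >= 0.0 and arr.max() <= 1.0
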