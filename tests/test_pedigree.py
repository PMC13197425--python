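"""Pedigree degrees, mitochondrial consistency, exhaustive enumeration
and generational-gap constraints."""

import itertools
import math

import numpy as np
import pytest

from tidechron.pedigree import (
    MATERNAL_GAP,
    PATERNAL_GAP,
    FamilyTree,
    PedigreeError,
    PedigreeIndividual,
    RelationEdge,
    check_pedigree_consistency,
    enumerate_pedigrees,
    pedigree_to_constraints,
)


def ossuary_family_tree() -> FamilyTree:
    """The published ossuary genealogy: grandparents GM/GF; their
    daughter M mothers the half-brothers LHA12 and LHA27 (different,
    unrecorded fathers); their son U fathers LHA34; LHA12 fathers
    LHA14."""
    t = FamilyTree()
    t.set_parent("M", "GM", "mother")
    t.set_parent("M", "GF", "father")
    t.set_parent("U", "GM", "mother")
    t.set_parent("U", "GF", "father")
    t.set_parent("LHA12", "M", "mother")
    t.set_parent("LHA27", "M", "mother")
    t.set_parent("LHA34", "U", "father")
    t.set_parent("LHA14", "LHA12", "father")
    return t


OSSUARY_INDIVIDUALS = [
    PedigreeIndividual("LHA12", "male", "H1"),
    PedigreeIndividual("LHA14", "female", "H2"),
    PedigreeIndividual("LHA27", "male", "H1"),
    PedigreeIndividual("LHA34", "female", "H3"),
    PedigreeIndividual("M", "female", "H1", sampled=False),
    PedigreeIndividual("U", "male", "H1", sampled=False),
    PedigreeIndividual("GM", "female", "H1", sampled=False),
    PedigreeIndividual("GF", "male", None, sampled=False),
]

OSSUARY_EDGES = [
    RelationEdge("LHA12", "LHA14", 1),
    RelationEdge("LHA12", "LHA27", 2),
    RelationEdge("LHA12", "LHA34", 3),
    RelationEdge("LHA27", "LHA34", 3),
    RelationEdge("LHA14", "LHA27", 3),
]


class TestDegrees:
    @pytest.mark.parametrize(
        "pair, want",
        [
            (("LHA12", "LHA14"), 1),  # father-daughter
            (("LHA12", "LHA27"), 2),  # maternal half-brothers
            (("LHA12", "LHA34"), 3),  # first cousins
            (("LHA27", "LHA34"), 3),
            (("LHA14", "LHA27"), 3),  # half-avuncular
            (("LHA14", "LHA34"), None),  # first cousins once removed: >3rd
            (("GM", "LHA12"), 2),  # grandmother
            (("GM", "LHA14"), 3),  # great-grandmother
            (("M", "U"), 1),  # full siblings
        ],
    )
    def test_implied_degree_classes(self, pair, want):
        assert ossuary_family_tree().implied_degree(*pair) == want

    def test_unrelated_founders(self):
        t = FamilyTree()
        t.add_individual("A")
        t.add_individual("B")
        assert t.implied_degree("A", "B") is None


class TestConsistency:
    def test_published_genealogy_is_consistent(self):
        assert (
            check_pedigree_consistency(
                ossuary_family_tree(), OSSUARY_EDGES, OSSUARY_INDIVIDUALS
            )
            == []
        )

    def test_maternal_mt_mismatch_is_a_violation(self):
        # asserting LHA14 is LHA12's *maternal* child while their mt
        # haplotypes differ must be flagged
        t = FamilyTree()
        t.set_parent("LHA14", "LHA12", "mother")
        inds = [
            PedigreeIndividual("LHA12", "unknown", "H1"),
            PedigreeIndividual("LHA14", "female", "H2"),
        ]
        out = check_pedigree_consistency(t, [RelationEdge("LHA12", "LHA14", 1)], inds)
        assert any("mt haplotype mismatch" in v for v in out)

    def test_degree_contradiction(self):
        t = FamilyTree()
        t.set_parent("B", "A", "father")
        inds = [PedigreeIndividual("A", "male"), PedigreeIndividual("B", "male")]
        out = check_pedigree_consistency(t, [RelationEdge("A", "B", 3)], inds)
        assert any("observed degree 3" in v for v in out)

    def test_sex_role_conflict(self):
        t = FamilyTree()
        t.set_parent("B", "A", "mother")
        inds = [PedigreeIndividual("A", "male"), PedigreeIndividual("B", "female")]
        out = check_pedigree_consistency(t, [], inds)
        assert any("is male" in v for v in out)

    def test_cycle_rejected_at_construction(self):
        t = FamilyTree()
        t.set_parent("B", "A", "father")
        t.set_parent("C", "B", "father")
        with pytest.raises(PedigreeError):
            t.set_parent("A", "C", "father")


def _isomorphic(a: FamilyTree, b: FamilyTree, placeholders_a, placeholders_b) -> bool:
    if len(placeholders_a) != len(placeholders_b):
        return False
    eb = set(b.parent_edges())
    for perm in itertools.permutations(placeholders_b):
        relab = dict(zip(placeholders_a, perm))
        ea = {
            (relab.get(c, c), relab.get(p, p), r) for c, p, r in a.parent_edges()
        }
        if ea == eb:
            return True
    return False


class TestEnumeration:
    def test_no_relations_gives_single_empty_tree(self):
        inds = [PedigreeIndividual("A", "male", "X"), PedigreeIndividual("B", "male", "Y")]
        out = enumerate_pedigrees(inds, [], max_unsampled=2)
        assert len(out) == 1
        assert out[0].parent_edges() == []

    def test_first_degree_males_different_mt(self):
        # mother-son excluded by sex, full siblings by mt: only the two
        # father-son orientations remain
        inds = [PedigreeIndividual("A", "male", "X"), PedigreeIndividual("B", "male", "Y")]
        out = enumerate_pedigrees(inds, [RelationEdge("A", "B", 1)], max_unsampled=2)
        got = {tuple(t.parent_edges()) for t in out}
        assert got == {(("B", "A", "father"),), (("A", "B", "father"),)}

    def test_first_degree_same_mt_includes_full_siblings(self):
        inds = [PedigreeIndividual("A", "male", "X"), PedigreeIndividual("B", "male", "X")]
        out = enumerate_pedigrees(inds, [RelationEdge("A", "B", 1)], max_unsampled=2)
        sib = [
            t
            for t in out
            if t.parents["A"]["mother"] is not None
            and t.parents["A"]["mother"] == t.parents["B"]["mother"]
            and t.parents["A"]["father"] == t.parents["B"]["father"]
        ]
        assert sib, "full-sibling configuration missing"

    def test_recovers_randomized_small_truths(self):
        # simulate degrees/mt from a random true tree, enumerate, and
        # require the truth among the results
        truths = {
            "half_sibs": lambda t: (
                t.set_parent("A", "?0", "mother"),
                t.set_parent("B", "?0", "mother"),
            ),
            "grandparent": lambda t: (
                t.set_parent("?0", "A", "mother"),
                t.set_parent("B", "?0", "father"),
            ),
            "parent_chain": lambda t: (
                t.set_parent("B", "A", "mother"),
                t.set_parent("C", "B", "mother"),
            ),
        }
        sexes = {
            "half_sibs": {"A": "male", "B": "male", "?0": "female"},
            "grandparent": {"A": "female", "B": "male", "?0": "male"},
            "parent_chain": {"A": "female", "B": "female", "C": "male"},
        }
        for name, build in truths.items():
            t = FamilyTree()
            build(t)
            sx = sexes[name]
            sampled = [i for i in t.individuals() if not i.startswith("?")]
            placeholders = [i for i in t.individuals() if i.startswith("?")]
            # haplotypes read off the maternal components of the truth
            comp = t.maternal_components()
            hap = {i: f"mt{comp[i]}" for i in sampled}
            inds = [PedigreeIndividual(i, sx[i], hap[i]) for i in sampled]
            edges = [
                RelationEdge(a, b, d)
                for a, b in itertools.combinations(sampled, 2)
                if (d := t.implied_degree(a, b)) is not None
            ]
            out = enumerate_pedigrees(inds, edges, max_unsampled=2)
            assert any(
                _isomorphic(t, cand, placeholders,
                            [i for i in cand.individuals() if i.startswith("?")])
                for cand in out
            ), f"truth {name} not recovered"

    def test_recovers_published_ossuary_genealogy(self):
        sampled = [i for i in OSSUARY_INDIVIDUALS if i.sampled]
        out = enumerate_pedigrees(sampled, OSSUARY_EDGES, max_unsampled=4,
                                  node_budget=10_000_000)
        truth = FamilyTree()
        truth.set_parent("?a", "?c", "mother")
        truth.set_parent("?b", "?c", "mother")
        truth.set_parent("?a", "?d", "father")
        truth.set_parent("?b", "?d", "father")
        truth.set_parent("LHA12", "?a", "mother")
        truth.set_parent("LHA27", "?a", "mother")
        truth.set_parent("LHA34", "?b", "father")
        truth.set_parent("LHA14", "LHA12", "father")
        assert any(
            _isomorphic(truth, cand, ["?a", "?b", "?c", "?d"],
                        [i for i in cand.individuals() if i.startswith("?")])
            for cand in out
        )

    def test_consistency_invariant_under_placeholder_relabeling(self):
        inds = [PedigreeIndividual("A", "male", "X"), PedigreeIndividual("B", "male", "X")]
        edges = [RelationEdge("A", "B", 2)]
        t1 = FamilyTree()
        t1.set_parent("A", "?0", "mother")
        t1.set_parent("B", "?0", "mother")
        t2 = FamilyTree()
        t2.set_parent("A", "?9", "mother")
        t2.set_parent("B", "?9", "mother")
        ph = [PedigreeIndividual("?0", "female", sampled=False),
              PedigreeIndividual("?9", "female", sampled=False)]
        assert check_pedigree_consistency(t1, edges, inds + ph) == []
        assert check_pedigree_consistency(t2, edges, inds + ph) == []


class TestConstraints:
    def test_empty_tree_yields_no_constraints(self):
        assert pedigree_to_constraints(FamilyTree()) == []

    def test_father_edge_gap(self):
        t = FamilyTree()
        t.set_parent("LHA14", "LHA12", "father")
        (g,) = pedigree_to_constraints(t)
        assert (g.parent, g.child) == ("LHA12", "LHA14")
        assert (g.mean, g.sd) == PATERNAL_GAP == (28.0, 7.0)

    def test_two_mother_edges_compose_to_normal_48_sqrt72(self):
        t = FamilyTree()
        t.set_parent("Mo", "GMo", "mother")
        t.set_parent("Kid", "Mo", "mother")
        gaps = pedigree_to_constraints(t)
        assert len(gaps) == 2
        assert sum(g.mean for g in gaps) == pytest.approx(48.0)
        assert math.hypot(*(g.sd for g in gaps)) == pytest.approx(math.sqrt(72.0))
        assert all((g.mean, g.sd) == MATERNAL_GAP for g in gaps)

    def test_constraint_count_equals_parent_edges(self):
        t = ossuary_family_tree()
        assert len(pedigree_to_constraints(t)) == len(t.parent_edges())
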