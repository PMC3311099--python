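"""Label-only path algorithms against printed examples and graph oracles."""

import networkx as nx
import pytest

from pedpaths import (
    add_virtual_root,
    ancestor_set,
    common_ancestors,
    encode_cpe,
    find_path_pairs,
    find_paths,
    identify_parents,
    overlap_matrix,
    prune_nonessential,
    serialize_cpe,
    serialize_pet,
    split_parent_ntes,
    tree_path,
)
from pedpaths.labels import parse_pet
from pedpaths.simulate import random_pedigree

from .conftest import dfs_paths


def pet(text):
    return parse_pet(text)


class TestTreePath:
    def test_single_tree_edge(self):
        p = tree_path(pet("1,"), pet("1,1."))
        assert p is not None and p.length == 1
        assert [serialize_pet(x) for x in p.nodes] == ["1,", "1,1."]

    def test_equal_labels_give_zero_length_path(self):
        p = tree_path(pet("0.0,"), pet("0.0,"))
        assert p.length == 0

    def test_non_prefix_gives_none(self):
        assert tree_path(pet("0."), pet("1,1.")) is None


class TestFindPaths:
    def test_three_printed_paths_to_p6(self, table8):
        paths = find_paths(table8.pet("P1"), table8.cpe("P6"))
        assert [str(p) for p in paths] == [
            "1,->1,1.",
            "1,->0.0,->0.0,0.->1,1.",
            "1,->1,0.->0.0,0.->1,1.",
        ]

    def test_two_printed_paths_to_p5(self, table8):
        paths = find_paths(table8.pet("P1"), table8.cpe("P5"))
        assert [str(p) for p in paths] == [
            "1,->0.0,->0.0,0.->0.0,0.0,",
            "1,->1,0.->0.0,0.->0.0,0.0,",
        ]

    def test_self_query_yields_single_zero_length_path(self, table8):
        paths = find_paths(table8.pet("P4"), table8.cpe("P4"))
        assert len(paths) == 1 and paths[0].length == 0

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_dfs_enumeration_on_random_pedigrees(self, seed):
        ped = random_pedigree(25, n_founders=3, seed=seed)
        table = encode_cpe(add_virtual_root(ped))
        memo = {}
        for a in ped.ids:
            for b in ped.ids:
                got = {
                    tuple(table.id_of(x) for x in p.nodes)
                    for p in find_paths(table.pet(a), table.cpe(b), memo)
                }
                assert got == dfs_paths(ped, a, b), (seed, a, b)

    def test_no_duplicate_paths(self, table8):
        for b in ("P5", "P6", "P7"):
            paths = find_paths(table8.pet("P1"), table8.cpe(b))
            assert len(paths) == len({p.nodes for p in paths})


class TestIdentifyParents:
    def test_p7_parents_from_label_alone(self, table8):
        roles = identify_parents(table8.cpe("P7"))
        assert serialize_pet(roles["father"]) == "0.0,0.0,"
        assert serialize_pet(roles["mother"]) == "1,1."

    def test_founder_has_no_parents(self, table8):
        assert identify_parents(table8.cpe("P0")) == {"father": None, "mother": None}

    def test_single_parent_via_tree_edge_only(self, table8):
        roles = identify_parents(table8.cpe("P5"))
        assert roles["father"] is None
        assert serialize_pet(roles["mother"]) == "0.0,0."

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_pedigree_records_on_random_pedigrees(self, seed):
        ped = random_pedigree(50, seed=seed)
        table = encode_cpe(add_virtual_root(ped))
        for i in ped.ids:
            roles = identify_parents(table.cpe(i), table)
            got = {
                k: (table.id_of(v) if v is not None else None)
                for k, v in roles.items()
            }
            assert got == {
                "father": ped[i].father_id,
                "mother": ped[i].mother_id,
            }


class TestSplitParentNtes:
    def test_p7_edge_split_matches_printed_sets(self, table8):
        parts = split_parent_ntes(table8.cpe("P7"), table8)
        father, mother = parts["father"], parts["mother"]
        assert serialize_cpe(father) == "0.0,0.0,%1,%0.0,%1,0.%0.0,0."
        assert serialize_cpe(mother) == "1,1.%0.0,0.%1,1.%1,%0.0,%1,0.%0.0,0."

    def test_direct_edge_not_inherited_by_either_parent(self, table8):
        parts = split_parent_ntes(table8.cpe("P7"), table8)
        own = table8.cpe("P7").direct_edge.pair
        for side in parts.values():
            assert own not in {e.pair for e in side.ntes}

    def test_two_parent_node_without_other_edges(self):
        ped = random_pedigree(6, n_founders=4, seed=40)
        # construct directly: child of two founders
        from pedpaths import Individual, Pedigree, Sex

        p = Pedigree(
            [
                Individual("f", sex=Sex.MALE),
                Individual("m", sex=Sex.FEMALE),
                Individual("c", father_id="f", mother_id="m", sex=Sex.MALE),
            ]
        )
        table = encode_cpe(add_virtual_root(p))
        parts = split_parent_ntes(table.cpe("c"), table)
        assert parts["father"].ntes == () and parts["mother"].ntes == ()


class TestAncestorSets:
    def test_table_of_p5_prefix_and_edge_sets(self, table8):
        got = {serialize_pet(a) for a in ancestor_set(table8.cpe("P5"))}
        assert got == {"0.", "0.0,", "0.0,0.", "0.0,0.0,", "1,", "1,0."}

    def test_founder_set_is_itself(self, table8):
        assert ancestor_set(table8.cpe("P1")) == frozenset({table8.pet("P1")})

    def test_common_ancestors_of_p5_p6(self, table8):
        parts = split_parent_ntes(table8.cpe("P7"), table8)
        got = common_ancestors(parts["father"], parts["mother"])
        assert {serialize_pet(a) for a in got} == {"1,", "0.", "0.0,", "1,0.", "0.0,0."}

    def test_unrelated_founders_share_nothing(self, table8):
        assert common_ancestors(table8.cpe("P0"), table8.cpe("P1")) == frozenset()

    def test_parent_is_its_own_ancestor_in_parent_child_query(self, table8):
        got = common_ancestors(table8.cpe("P4"), table8.cpe("P5"))
        assert table8.pet("P4") in got

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_reachability_closure_on_random_pedigrees(self, seed):
        ped = random_pedigree(40, seed=seed)
        table = encode_cpe(add_virtual_root(ped))
        g = ped.to_networkx()
        for i in ped.ids:
            want = nx.ancestors(g, i) | {i}
            got = {table.id_of(a) for a in ancestor_set(table.cpe(i))}
            assert got == want


@pytest.fixture(scope="module")
def p7_query(table8):
    parts = split_parent_ntes(table8.cpe("P7"), table8)
    cf, cm = parts["father"], parts["mother"]
    memo = {}
    fps = find_paths(table8.pet("P1"), cf, memo)
    mps = find_paths(table8.pet("P1"), cm, memo)
    return cf, cm, fps, mps


class TestOverlapElimination:
    def test_inverted_index_matches_printed_table(self, table8, p7_query):
        cf, cm, fps, mps = p7_query
        m = overlap_matrix(table8.pet("P1"), fps, mps, common_ancestors(cf, cm))
        index = {serialize_pet(k): set(v) for k, v in m.index.items()}
        assert index == {
            "1,": {"p1", "p2", "p3", "q1", "q2"},
            "0.0,": {"p2", "q1"},
            "1,0.": {"p3", "q2"},
            "0.0,0.": {"p2", "p3", "q1", "q2"},
        }

    def test_matrix_matches_printed_table(self, table8, p7_query):
        cf, cm, fps, mps = p7_query
        m = overlap_matrix(table8.pet("P1"), fps, mps, common_ancestors(cf, cm))
        assert m.cells == {
            ("q1", "p1"): True,
            ("q1", "p2"): False,
            ("q1", "p3"): False,
            ("q2", "p1"): True,
            ("q2", "p2"): False,
            ("q2", "p3"): False,
        }

    def test_nonoverlapping_pairs_from_p1(self, table8, p7_query):
        cf, cm, _, _ = p7_query
        pairs = find_path_pairs(table8.pet("P1"), cf, cm)
        nonov = [p for p in pairs if p.non_overlapping]
        assert len(nonov) == 2
        assert all(p.r == 1 and p.s == 3 for p in nonov)

    def test_single_child_ancestor_gives_all_overlapping(self, table8, p7_query):
        cf, cm, _, _ = p7_query
        pairs = find_path_pairs(table8.pet("P2"), cf, cm)
        assert pairs and not any(p.non_overlapping for p in pairs)

    @pytest.mark.parametrize("seed", range(4))
    def test_flags_equal_brute_force_intersection(self, seed):
        ped = random_pedigree(25, n_founders=3, seed=seed + 50)
        table = encode_cpe(add_virtual_root(ped))
        for i in ped.ids:
            ind = ped[i]
            if ind.father_id is None or ind.mother_id is None:
                continue
            parts = split_parent_ntes(table.cpe(i), table)
            cf, cm = parts["father"], parts["mother"]
            memo = {}
            for a in common_ancestors(cf, cm):
                for pr in find_path_pairs(a, cf, cm, memo=memo):
                    shared = set(pr.to_father.nodes) & set(pr.to_mother.nodes)
                    assert pr.non_overlapping == (shared == {a})


class TestPruneNonessential:
    def test_p2_eliminated_for_the_p5_p6_query(self, table8):
        parts = split_parent_ntes(table8.cpe("P7"), table8)
        cf, cm = parts["father"], parts["mother"]
        full = common_ancestors(cf, cm)
        kept = prune_nonessential(full, cf, cm, table8)
        assert table8.pet("P2") not in kept

    def test_only_p1_and_p4_survive(self, table8):
        parts = split_parent_ntes(table8.cpe("P7"), table8)
        kept = prune_nonessential(
            common_ancestors(parts["father"], parts["mother"]),
            parts["father"],
            parts["mother"],
            table8,
        )
        assert {table8.id_of(a) for a in kept} == {"P1", "P4"}

    def test_ancestor_with_two_subgraph_children_retained(self, table8):
        parts = split_parent_ntes(table8.cpe("P7"), table8)
        kept = prune_nonessential(
            common_ancestors(parts["father"], parts["mother"]),
            parts["father"],
            parts["mother"],
            table8,
        )
        assert table8.pet("P4") in kept  # children P5 and P6 both in subgraph

    @pytest.mark.parametrize("seed", range(4))
    def test_pruned_ancestors_contribute_no_pairs(self, seed):
        """Safety: every pruned ancestor yields zero non-overlapping pairs."""
        ped = random_pedigree(30, n_founders=3, seed=seed + 70)
        table = encode_cpe(add_virtual_root(ped))
        for i in ped.ids:
            ind = ped[i]
            if ind.father_id is None or ind.mother_id is None:
                continue
            parts = split_parent_ntes(table.cpe(i), table)
            cf, cm = parts["father"], parts["mother"]
            full = common_ancestors(cf, cm)
            kept = prune_nonessential(full, cf, cm, table)
            memo = {}
            for a in full - kept:
                pairs = find_path_pairs(a, cf, cm, memo=memo)
                assert not any(p.non_overlapping for p in pairs)
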