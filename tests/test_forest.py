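"""Guide-forest merging, indexing, and grammar generation."""

import numpy as np
import pytest

from acm.forest import (
    MergeError,
    forest_from_tree,
    generate_grammar,
    index_forest,
    merge_forest,
    structure_language,
)
from acm.structure_ops import ConsensusStructure, parse_guide_tree, unparse_guide_tree
from acm.synthetic_fixtures import random_compatible_structures


def trees_for(*structures):
    return [
        parse_guide_tree(ConsensusStructure(s, subfamily=f"f{i}"))
        for i, s in enumerate(structures)
    ]


def build_grammar(*structures):
    trees = trees_for(*structures)
    forest = merge_forest(trees)
    index_forest(forest)
    return generate_grammar(forest, len(structures[0]))


def count_forks(forest):
    return sum(1 for n in forest.walk() if n.kind == "fork")


class TestMergeForest:
    def test_identical_trees_share_everything(self):
        forest = merge_forest(trees_for("<<*>>*", "<<*>>*"))
        assert count_forks(forest) == 0
        assert forest.members == {"f0", "f1"}

    def test_root_divergence_forks_at_root(self):
        forest = merge_forest(trees_for("<>", "**"))
        assert forest.kind == "fork"
        assert len(forest.children) == 2

    def test_two_family_example_forks_below_shared_pairs(self):
        # red <<-*><>> vs purple <<-*>**>: pair(1,8) and pair(2,5) shared,
        # the divergent pair(6,7)/open(6) subtrees hang under one fork
        forest = merge_forest(trees_for("<<-*><>>", "<<-*>**>"))
        assert forest.kind == "pair" and forest.cols == (1, 8)
        assert count_forks(forest) == 1
        inner = forest.children[0]
        assert inner.kind == "pair" and inner.cols == (2, 5)
        fork = inner.children[1]
        assert fork.kind == "fork"
        assert {c.identity for c in fork.children} == {
            ("pair", (6, 7)),
            ("open", (6,)),
        }

    def test_merge_is_idempotent(self):
        t1, t2 = trees_for("<<*>*-->", "<---*<>>")
        once = merge_forest([t1, t2])
        again = merge_forest([t1, t2, t2.copy()])
        assert [n.identity for n in once.walk()] == [n.identity for n in again.walk()]

    def test_length_mismatch_raises(self):
        with pytest.raises(MergeError):
            merge_forest(trees_for("<>", "<*>"))

    def test_node_count_bounded_by_input_sum(self, rng):
        for _ in range(25):
            structs = random_compatible_structures(
                rng, int(rng.integers(2, 16)), int(rng.integers(2, 5))
            )
            trees = trees_for(*structs)
            total = sum(sum(1 for _n in t.walk()) for t in trees)
            forest = merge_forest(trees)
            non_fork = sum(1 for n in forest.walk() if n.kind != "fork")
            assert non_fork <= total

    def test_subfamily_restriction_reproduces_each_tree(self, rng):
        for _ in range(25):
            structs = random_compatible_structures(
                rng, int(rng.integers(2, 14)), int(rng.integers(2, 4))
            )
            forest = merge_forest(trees_for(*structs))
            for i, s in enumerate(structs):
                restricted = _restrict(forest, f"f{i}")
                assert unparse_guide_tree(restricted) == s


def _restrict(node, member):
    """Erase forks, keeping the branch containing the sub-family."""
    from acm.structure_ops import GuideNode

    if node.kind == "fork":
        for alt in node.children:
            if member in alt.members:
                return _restrict(alt, member)
        raise AssertionError(f"{member} lost at a fork")
    return GuideNode(
        node.kind,
        node.cols,
        [_restrict(c, member) for c in node.children],
        set(node.members),
    )


class TestIndexing:
    def test_depth_first_permutation(self):
        forest = merge_forest(trees_for("<<*><>>"))
        index_forest(forest)
        indices = [n.grammar_index for n in forest.walk()]
        assert indices == list(range(1, len(indices) + 1))

    def test_list_indexing_is_consecutive(self):
        f1 = merge_forest(trees_for("<>"))
        f2 = merge_forest(trees_for("**"))
        index_forest([f1, f2])
        max1 = max(n.grammar_index for n in f1.walk())
        min2 = min(n.grammar_index for n in f2.walk())
        assert min2 == max1 + 1

    def test_algebra_keys_shared_across_branches(self):
        # open_6 in one branch and the pair's left column 6 in the other
        # share the per-column emission key
        g = build_grammar("<<-*><>>", "<<-*>**>")
        keys = g.emission_keys()
        assert "un:6" in keys and "pair:6:7" in keys
        open_nodes = [
            i for i, n in g.nodes.items() if n.kind == "open" and n.cols == (6,)
        ]
        assert open_nodes  # purple branch emits through un:6 as well


class TestGenerateGrammar:
    def test_single_open_node_grammar(self):
        g = build_grammar("*")
        assert structure_language(g) == {"*"}
        roles = {p.role for i in g.nodes for p in g.productions(i)}
        assert {"match", "delete", "end"} <= roles

    def test_two_family_language_is_exact(self):
        g = build_grammar("<<-*><>>", "<<-*>**>")
        assert structure_language(g) == {"<<-*><>>", "<<-*>**>"}

    def test_no_unseen_combination(self):
        g = build_grammar("<<*>*-->", "<---*<>>")
        lang = structure_language(g)
        assert lang == {"<<*>*-->", "<---*<>>"}
        assert "<---*-->" not in lang

    def test_independent_region_divergence_stays_exact(self):
        # divergences in two sibling regions must not cross-multiply
        g = build_grammar("<*>*<*>", "<->*<->")
        assert structure_language(g) == {"<*>*<*>", "<->*<->"}

    def test_n1_special_case_equals_classical_build(self):
        s = "<<*><>>"
        tree = trees_for(s)[0]
        merged = merge_forest([tree])
        index_forest(merged)
        g_merge = generate_grammar(merged, len(s))

        classical = forest_from_tree(trees_for(s)[0])
        index_forest(classical)
        g_classic = generate_grammar(classical, len(s))
        assert g_merge.nodes == g_classic.nodes
        assert g_merge.all_productions() == g_classic.all_productions()

    def test_fork_production_per_branch(self):
        g = build_grammar("<>", "**")
        forks = [i for i, n in g.nodes.items() if n.kind == "fork"]
        assert len(forks) == 1
        prods = g.productions(forks[0])
        assert [p.role for p in prods] == ["branch_0", "branch_1"]
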