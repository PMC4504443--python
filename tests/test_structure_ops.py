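"""Guide-tree parsing and consensus-structure compatibility."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from acm.structure_ops import (
    ConsensusStructure,
    StructureError,
    check_compatible_pair,
    check_compatible_set,
    parse_guide_tree,
    unparse_guide_tree,
)
from tests.oracles import random_structure

import numpy as np


def structure_strings(max_len=24):
    """Hypothesis strategy for balanced structure strings."""
    return st.integers(0, 2**31 - 1).flatmap(
        lambda seed: st.integers(0, max_len).map(
            lambda n: random_structure(np.random.default_rng(seed), n)
        )
    )


class TestParseGuideTree:
    def test_empty_string_is_nil(self):
        root = parse_guide_tree(ConsensusStructure(""))
        assert root.kind == "nil" and root.cols == (1,)

    def test_single_pair(self):
        root = parse_guide_tree(ConsensusStructure("<>"))
        assert root.kind == "pair" and root.cols == (1, 2)
        inside, after = root.children
        assert inside.kind == "nil" and after.kind == "nil"

    def test_hairpin_with_adjacent_helix_shape(self):
        # the two-helix match structure of the worked example
        root = parse_guide_tree(ConsensusStructure("<<*><>>"))
        assert root.kind == "pair" and root.cols == (1, 7)
        inner = root.children[0]
        assert inner.kind == "pair" and inner.cols == (2, 4)
        assert inner.children[0].kind == "open" and inner.children[0].cols == (3,)
        second = inner.children[1]
        assert second.kind == "pair" and second.cols == (5, 6)
        assert root.children[1].kind == "nil"

    def test_gap_columns_become_skip_nodes(self):
        root = parse_guide_tree(ConsensusStructure("-*-"))
        kinds = [n.kind for n in root.walk()]
        assert kinds == ["skip", "open", "skip", "nil"]

    @pytest.mark.parametrize("bad", ["<", ">", "<<>", "><"])
    def test_unbalanced_input_raises(self, bad):
        with pytest.raises(StructureError):
            parse_guide_tree(ConsensusStructure.from_raw(bad))

    @given(structure_strings())
    def test_unparse_inverts_parse(self, s):
        assert unparse_guide_tree(parse_guide_tree(ConsensusStructure(s))) == s

    @given(structure_strings())
    def test_inorder_columns_cover_input(self, s):
        root = parse_guide_tree(ConsensusStructure(s))
        cols = sorted(
            c for n in root.walk() if n.kind != "nil" for c in n.cols
        )
        assert cols == list(range(1, len(s) + 1))


class TestCompatibility:
    def test_insertion_variant_pair_is_compatible(self):
        # two consensus rows explaining a common evolution with two extra
        # unpaired bases in the upper structure
        rep = check_compatible_pair(
            ConsensusStructure("<<-*>**>"), ConsensusStructure("<<-*>-->")
        )
        assert rep.compatible

    def test_alternative_partner_is_rejected(self):
        rep = check_compatible_pair(
            ConsensusStructure("<<**>>"), ConsensusStructure("<*<*>>")
        )
        assert not rep.compatible
        assert any(kind == "persistence" for kind, _ in rep.violations)

    def test_crossing_union_is_rejected(self):
        rep = check_compatible_pair(
            ConsensusStructure("<*>***"), ConsensusStructure("*<***>")
        )
        assert not rep.compatible
        assert any(kind == "nesting" for kind, _ in rep.violations)

    def test_deleted_columns_satisfy_persistence(self):
        rep = check_compatible_pair(
            ConsensusStructure("<<*>*-->"), ConsensusStructure("<---*<>>")
        )
        assert rep.compatible

    def test_length_mismatch_raises(self):
        with pytest.raises(StructureError):
            check_compatible_pair(ConsensusStructure("<>"), ConsensusStructure("<*>"))

    def test_single_structure_set_is_compatible(self):
        assert check_compatible_set([ConsensusStructure("<<*>*>")]).compatible

    def test_set_with_incompatible_pair_reports_it(self):
        structs = [
            ConsensusStructure("<<**>>"),
            ConsensusStructure("<<**>>"),
            ConsensusStructure("<*<*>>"),
        ]
        rep = check_compatible_set(structs)
        assert not rep.compatible

    def test_fig8_red_purple_compatible(self):
        rep = check_compatible_set(
            [ConsensusStructure("<<**><>>"), ConsensusStructure("<<**>**>")]
        )
        assert rep.compatible

    @given(structure_strings(max_len=16), st.integers(0, 2**31 - 1))
    def test_symmetry(self, s1, seed):
        s2 = random_structure(np.random.default_rng(seed), len(s1))
        a = check_compatible_pair(ConsensusStructure(s1), ConsensusStructure(s2))
        b = check_compatible_pair(ConsensusStructure(s2), ConsensusStructure(s1))
        assert a.compatible == b.compatible

    @given(structure_strings(max_len=16))
    def test_reflexivity(self, s):
        assert check_compatible_pair(
            ConsensusStructure(s), ConsensusStructure(s)
        ).compatible
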