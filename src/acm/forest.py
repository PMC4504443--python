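"""Ambivalent guide forests and generation of the family model grammar.

Several compatible consensus structures yield several guide trees over the
same alignment columns.  The *ambivalent guide forest* shares their common
parts and introduces *fork* nodes where they diverge; evaluating the indexed
forest produces the family model grammar whose indel-free derivations are
exactly the input structures.

Fork placement.  Two guide trees are overlaid top-down; node identity is
(kind, alignment columns).  Where they diverge, the complete divergent
subtrees go under a fork.  Because fork alternatives are chosen
independently in a context-free derivation, a fork is placed at the lowest
single node whose subtree covers *all* divergence points of the tree being
threaded in (and any previously created fork that could be reached in the
same derivation); otherwise independent forks in sibling regions would
cross-multiply and admit structures never present in the input.  Forks are
therefore "as low as possible" subject to the model admitting no unseen
structure combination.

Indices.  Every forest node receives a unique *grammar index* (depth-first
pre-order), governing transitions; emitting nodes additionally carry an
*algebra index* derived from their alignment columns, shared across fork
branches so that emission statistics are pooled over sub-families.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structure_ops import GuideNode

__all__ = [
    "FamilyGrammar",
    "NodeSpec",
    "Production",
    "merge_forest",
    "forest_from_tree",
    "index_forest",
    "generate_grammar",
    "structure_language",
]


class MergeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# merging guide trees
# ---------------------------------------------------------------------------

def forest_from_tree(tree: GuideNode) -> GuideNode:
    """The trivial one-tree forest (the classical, single-structure case)."""
    return tree.copy()


def _parent_map(root: GuideNode) -> dict[int, GuideNode | None]:
    parents: dict[int, GuideNode | None] = {id(root): None}
    for node in root.walk():
        for child in node.children:
            parents[id(child)] = node
    return parents


def _ancestor_path(node: GuideNode, parents) -> list[GuideNode]:
    path = [node]
    while parents[id(path[-1])] is not None:
        path.append(parents[id(path[-1])])
    return path


def _lca(a: GuideNode, b: GuideNode, parents) -> GuideNode:
    pa = {id(n) for n in _ancestor_path(a, parents)}
    for n in _ancestor_path(b, parents):
        if id(n) in pa:
            return n
    raise AssertionError("nodes share no ancestor")


def _subfamily_of(tree: GuideNode) -> str:
    (name,) = tree.members
    return name


def merge_forest(trees: list[GuideNode]) -> GuideNode:
    """Progressively merge guide trees (input order) into one guide forest.

    Each tree must carry exactly one sub-family name in its ``members`` sets
    and all trees must span the same alignment columns.  Re-merging a tree
    already represented in the forest changes only membership annotations
    (idempotence).
    """
    if not trees:
        raise MergeError("need at least one guide tree")
    spans = {max((c for n in t.walk() for c in n.cols), default=0) for t in trees}
    if len(spans) > 1:
        raise MergeError(f"guide trees span different alignment lengths: {sorted(spans)}")

    forest = trees[0].copy()
    for tree in trees[1:]:
        forest = _thread(forest, tree)
    return forest


def _thread(forest: GuideNode, tree: GuideNode) -> GuideNode:
    name = _subfamily_of(tree)

    # --- phase 1: coupled top-down walk, collect divergences and matches ----
    divergences: list[GuideNode] = []          # forest nodes where tree diverges
    matched: list[tuple[GuideNode, GuideNode]] = []  # (forest node, tree node)

    def walk(fnode: GuideNode, tnode: GuideNode) -> None:
        if fnode.kind == "fork":
            for alt in fnode.children:
                if alt.identity == tnode.identity:
                    matched.append((fnode, tnode))
                    walk(alt, tnode)
                    return
            divergences.append(fnode)
            return
        if fnode.identity != tnode.identity:
            divergences.append(fnode)
            return
        matched.append((fnode, tnode))
        for fc, tc in zip(fnode.children, tnode.children):
            walk(fc, tc)

    walk(forest, tree)

    if not divergences:
        for fnode, _ in matched:
            fnode.members.add(name)
            if fnode.kind != "fork":
                pass
        # membership must also reach nodes below matched fork alternatives;
        # the walk already visited them, so nothing further to do
        return forest

    # --- phase 2: promote the fork position -------------------------------
    parents = _parent_map(forest)
    v = divergences[0]
    for d in divergences[1:]:
        v = _lca(v, d, parents)

    forks = [n for n in forest.walk() if n.kind == "fork"]

    def jointly_reachable(f: GuideNode, w: GuideNode) -> bool:
        if f is w:
            return False
        u = _lca(f, w, parents)
        if u is f or u is w:
            return False  # nested: reachable only inside one branch / subtree
        return u.kind != "fork"  # different fork alternatives exclude each other

    changed = True
    while changed:
        changed = False
        for f in forks:
            if jointly_reachable(f, v):
                v = _lca(v, f, parents)
                changed = True

    # --- phase 3: rebuild with a fork (or new alternative) at v ------------
    # find the tree node corresponding to position v: replay the walk
    def find_tree_node(fnode: GuideNode, tnode: GuideNode) -> GuideNode | None:
        if fnode is v:
            return tnode
        if fnode.kind == "fork":
            for alt in fnode.children:
                if alt.identity == tnode.identity:
                    return find_tree_node(alt, tnode)
            return None
        if fnode.identity != tnode.identity:
            return None
        for fc, tc in zip(fnode.children, tnode.children):
            r = find_tree_node(fc, tc)
            if r is not None:
                return r
        return None

    tsub = find_tree_node(forest, tree)
    assert tsub is not None, "fork position is outside the coupled path"
    new_alt = tsub.copy()

    def rebuild(fnode: GuideNode, tnode: GuideNode | None) -> GuideNode:
        if fnode is v:
            if fnode.kind == "fork":
                fnode.children.append(new_alt)
                fnode.members.add(name)
                return fnode
            return GuideNode(
                "fork", (), [fnode, new_alt], set(fnode.members) | {name}
            )
        if fnode.kind == "fork":
            for alt in fnode.children:
                if tnode is not None and alt.identity == tnode.identity:
                    idx = fnode.children.index(alt)
                    fnode.children[idx] = rebuild(alt, tnode)
                    fnode.members.add(name)
                    return fnode
            # v must be inside one alternative even if tree does not match it
            for idx, alt in enumerate(fnode.children):
                if any(n is v for n in alt.walk()):
                    fnode.children[idx] = rebuild(alt, None)
                    fnode.members.add(name)
                    return fnode
            return fnode
        on_path = any(n is v for n in fnode.walk())
        if not on_path:
            return fnode
        if tnode is not None and fnode.identity == tnode.identity:
            fnode.members.add(name)
            tkids = tnode.children
        else:
            tkids = [None] * len(fnode.children)
        for i, (fc, tc) in enumerate(zip(fnode.children, tkids)):
            if any(n is v for n in fc.walk()) or fc is v:
                fnode.children[i] = rebuild(fc, tc)
        return fnode

    # membership for matched nodes outside the forked subtree
    in_forked = {id(n) for n in v.walk()}
    for fnode, _ in matched:
        if id(fnode) not in in_forked:
            fnode.members.add(name)

    return rebuild(forest, tree)


# ---------------------------------------------------------------------------
# indexing
# ---------------------------------------------------------------------------

def index_forest(forest: GuideNode | list[GuideNode]) -> GuideNode | list[GuideNode]:
    """Assign unique depth-first grammar indices (1-based).

    A list of forests is indexed consecutively: the second forest's indices
    all exceed the first's maximum.  Algebra indices need no assignment pass:
    they are a fixed function of node kind and alignment columns (see
    :func:`algebra_key`) and thereby shared across fork branches.
    """
    forests = forest if isinstance(forest, list) else [forest]
    counter = 0
    for f in forests:
        for node in f.walk():
            counter += 1
            node.grammar_index = counter
    return forest


def algebra_key(kind: str, cols: tuple[int, ...]) -> str | None:
    """Emission-parameter key for a node: shared whenever columns coincide."""
    if kind == "open":
        return f"un:{cols[0]}"
    if kind == "pair":
        return f"pair:{cols[0]}:{cols[1]}"
    return None


# ---------------------------------------------------------------------------
# the family model grammar
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeSpec:
    kind: str
    cols: tuple[int, ...]
    children: tuple[int, ...]
    members: tuple[str, ...]


@dataclass(frozen=True)
class Production:
    """One grammar rule: ``lhs -> rhs`` with a transition role label.

    RHS symbols are tuples:
      ("base", emission_key)      one scored residue
      ("pair_open", key) / ("pair_close", key)   the two coupled residues of
                                  a base pair (scored jointly, 16-way)
      ("region", slot_key)        an insertion region: zero or more residues,
                                  emission at background (0 bits), scored by a
                                  Bernoulli open/closed transition per slot
      ("ref", grammar_index)      a nonterminal reference
    """

    lhs: int
    role: str
    rhs: tuple[tuple, ...]


AXIOM = 0
LEAD_SLOT = "lead"

# canonical role order per node kind; also the tie-break priority in CYK
ROLES = {
    "open": ("match", "delete"),
    "pair": ("match_pair", "match_left", "match_right", "delete"),
    "skip": ("skip",),
    "nil": ("end",),
}


@dataclass
class FamilyGrammar:
    """The generated family model grammar (nodes plus derived productions)."""

    nodes: dict[int, NodeSpec]
    root: int
    n_columns: int
    subfamilies: tuple[str, ...]

    def roles(self, idx: int) -> tuple[str, ...]:
        node = self.nodes[idx]
        if node.kind == "fork":
            return tuple(f"branch_{i}" for i in range(len(node.children)))
        return ROLES[node.kind]

    def productions(self, idx: int) -> list[Production]:
        node = self.nodes[idx]
        kind = node.kind
        if kind == "nil":
            return [Production(idx, "end", ())]
        if kind == "skip":
            (nxt,) = node.children
            return [Production(idx, "skip", (("ref", nxt),))]
        if kind == "open":
            (nxt,) = node.children
            key = algebra_key(kind, node.cols)
            return [
                Production(
                    idx,
                    "match",
                    (("base", key), ("region", f"{idx}:trail"), ("ref", nxt)),
                ),
                Production(idx, "delete", (("ref", nxt),)),
            ]
        if kind == "pair":
            inside, nxt = node.children
            key = algebra_key(kind, node.cols)
            a, b = node.cols
            inl, inr, trail = f"{idx}:inl", f"{idx}:inr", f"{idx}:trail"
            return [
                Production(
                    idx,
                    "match_pair",
                    (
                        ("pair_open", key),
                        ("region", inl),
                        ("ref", inside),
                        ("region", inr),
                        ("pair_close", key),
                        ("region", trail),
                        ("ref", nxt),
                    ),
                ),
                Production(
                    idx,
                    "match_left",
                    (
                        ("base", f"un:{a}"),
                        ("region", inl),
                        ("ref", inside),
                        ("region", trail),
                        ("ref", nxt),
                    ),
                ),
                Production(
                    idx,
                    "match_right",
                    (
                        ("ref", inside),
                        ("region", inr),
                        ("base", f"un:{b}"),
                        ("region", trail),
                        ("ref", nxt),
                    ),
                ),
                Production(
                    idx,
                    "delete",
                    (("ref", inside), ("region", trail), ("ref", nxt)),
                ),
            ]
        if kind == "fork":
            return [
                Production(idx, f"branch_{i}", (("ref", c),))
                for i, c in enumerate(node.children)
            ]
        raise ValueError(f"unknown node kind {kind!r}")

    def axiom_production(self) -> Production:
        return Production(AXIOM, "axiom", (("region", LEAD_SLOT), ("ref", self.root)))

    def all_productions(self) -> list[Production]:
        out = [self.axiom_production()]
        for idx in sorted(self.nodes):
            out.extend(self.productions(idx))
        return out

    def slots(self) -> list[str]:
        keys = [LEAD_SLOT]
        for idx in sorted(self.nodes):
            kind = self.nodes[idx].kind
            if kind == "open":
                keys.append(f"{idx}:trail")
            elif kind == "pair":
                keys.extend((f"{idx}:inl", f"{idx}:inr", f"{idx}:trail"))
        return keys

    def emission_keys(self) -> dict[str, int]:
        """Mapping of emission key -> arity (4 unpaired, 16 pair)."""
        keys: dict[str, int] = {}
        for idx, node in self.nodes.items():
            if node.kind == "open":
                keys[algebra_key("open", node.cols)] = 4
            elif node.kind == "pair":
                a, b = node.cols
                keys[algebra_key("pair", node.cols)] = 16
                keys[f"un:{a}"] = 4
                keys[f"un:{b}"] = 4
        return keys

    def branch_members(self, idx: int) -> list[tuple[str, ...]]:
        """Per-alternative sub-family memberships of a fork node."""
        node = self.nodes[idx]
        assert node.kind == "fork"
        return [self.nodes[c].members for c in node.children]

    def dump(self) -> str:
        """Human-readable one-production-per-line rendering."""

        def sym(s):
            tag = s[0]
            if tag == "ref":
                return f"N{s[1]}"
            if tag == "base":
                return f"b[{s[1]}]"
            if tag in ("pair_open", "pair_close"):
                return f"{'bL' if tag == 'pair_open' else 'bR'}[{s[1]}]"
            return f"r0[{s[1]}]"

        lines = []
        for p in self.all_productions():
            lhs = "S" if p.lhs == AXIOM else f"N{p.lhs}"
            rhs = " ".join(sym(s) for s in p.rhs) or "eps"
            lines.append(f"{lhs} -> {rhs}    ({p.role})")
        return "\n".join(lines)


def generate_grammar(
    forest: GuideNode,
    n_columns: int,
    subfamilies: tuple[str, ...] | None = None,
) -> FamilyGrammar:
    """Evaluate an indexed guide forest into the family model grammar.

    Each forest node becomes one indexed nonterminal with the productions of
    its kind: match variants with their insertion-region slots, a deletion
    variant (pairs additionally match-left-only / match-right-only), fork
    nodes become one alternative production per branch, and the axiom wraps
    the model root with the lead insertion region.  Glocal query flanks are
    applied by the search layer, not encoded as productions.
    """
    nodes: dict[int, NodeSpec] = {}
    for node in forest.walk():
        if node.grammar_index is None:
            raise ValueError("forest is not indexed; call index_forest first")
        nodes[node.grammar_index] = NodeSpec(
            node.kind,
            node.cols,
            tuple(c.grammar_index for c in node.children),
            tuple(sorted(node.members)),
        )
    if subfamilies is None:
        subfamilies = tuple(sorted(forest.members))
    return FamilyGrammar(nodes, forest.grammar_index, n_columns, subfamilies)


def structure_language(grammar: FamilyGrammar) -> set[str]:
    """All structures derivable without insertions or deletions.

    Every derivation that uses only the full match variant of each node (and
    one branch per fork) spells a structure in alignment coordinates: ``<>``
    at pair columns, ``*`` at unpaired columns, ``-`` at columns the chosen
    branch skips.  For a correctly merged forest this set equals the set of
    input (gapped) match structures.
    """

    def lang(idx: int) -> set[str]:
        node = grammar.nodes[idx]
        if node.kind == "nil":
            return {""}
        if node.kind == "open":
            return {"*" + s for s in lang(node.children[0])}
        if node.kind == "skip":
            return {"-" + s for s in lang(node.children[0])}
        if node.kind == "pair":
            inside, nxt = node.children
            return {
                "<" + i + ">" + a for i in lang(inside) for a in lang(nxt)
            }
        if node.kind == "fork":
            out: set[str] = set()
            for c in node.children:
                out |= lang(c)
            return out
        raise ValueError(node.kind)

    return lang(grammar.root)
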