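"""Consensus secondary structures, guide trees, and structure compatibility.

A consensus structure annotates the columns of a multiple alignment with a
pseudoknot-free secondary structure: ``<``/``>`` for the two sides of a base
pair, ``*`` for an unpaired (single-stranded) consensus column and ``-`` for a
column that is absent from this sub-family's consensus (a gap / deleted
column).  Parsing such a string with the unambiguous G5s architecture (pair,
unpaired, gap, end) yields exactly one parse tree -- the *guide tree* that
fixes the topology of the covariance model.

Before several consensus structures can be merged into one ambivalent model
they must be *compatible*: a column may pair with at most one fixed partner
across all structures (base-pair persistence), and the union of all base
pairs must be free of crossings (global nesting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ConsensusStructure",
    "GuideNode",
    "CompatibilityReport",
    "parse_guide_tree",
    "unparse_guide_tree",
    "check_compatible_pair",
    "check_compatible_set",
]

# canonical column alphabet after normalisation
OPEN, CLOSE, UNPAIRED, GAP = "<", ">", "*", "-"

_NORMALISE = {
    "(": OPEN,
    "<": OPEN,
    "[": OPEN,
    "{": OPEN,
    ")": CLOSE,
    ">": CLOSE,
    "]": CLOSE,
    "}": CLOSE,
    "*": UNPAIRED,
    ".": UNPAIRED,
    ":": UNPAIRED,
    ",": UNPAIRED,
    "~": UNPAIRED,
    "-": GAP,
    "_": GAP,
}


class StructureError(ValueError):
    """Raised for unbalanced, crossing or otherwise malformed structures."""


def normalize_structure(raw: str) -> str:
    """Map the many dot-bracket dialects onto the canonical ``<>*-`` alphabet.

    ``(``, ``[``, ``{`` open a pair, their counterparts close one; ``.``,
    ``:``, ``,`` and ``~`` are unpaired; ``_`` is accepted as a gap alias
    (some figures use it for deleted columns).  Alphabetic pseudoknot
    annotation must be removed first (see :func:`acm.preprocess.break_pseudoknots`).
    """
    out = []
    for i, ch in enumerate(raw):
        try:
            out.append(_NORMALISE[ch])
        except KeyError:
            raise StructureError(
                f"unsupported structure character {ch!r} at column {i + 1}"
            ) from None
    return "".join(out)


def pair_table(columns: str) -> dict[int, int]:
    """1-based map of each paired column to its partner (both directions)."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for idx, ch in enumerate(columns, start=1):
        if ch == OPEN:
            stack.append(idx)
        elif ch == CLOSE:
            if not stack:
                raise StructureError(f"unmatched '>' at column {idx}")
            a = stack.pop()
            pairs[a] = idx
            pairs[idx] = a
    if stack:
        raise StructureError(f"unmatched '<' at column {stack[-1]}")
    return pairs


@dataclass(frozen=True)
class ConsensusStructure:
    """A consensus structure over alignment columns (1-based coordinates)."""

    columns: str
    subfamily: str = "default"
    pairs: tuple[tuple[int, int], ...] = field(init=False)

    def __post_init__(self) -> None:
        bad = set(self.columns) - {OPEN, CLOSE, UNPAIRED, GAP}
        if bad:
            raise StructureError(
                f"non-canonical characters {sorted(bad)}; call from_raw() first"
            )
        table = pair_table(self.columns)
        pl = tuple(sorted((a, b) for a, b in table.items() if a < b))
        object.__setattr__(self, "pairs", pl)

    @classmethod
    def from_raw(cls, raw: str, subfamily: str = "default") -> "ConsensusStructure":
        return cls(normalize_structure(raw), subfamily=subfamily)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.columns)


# ---------------------------------------------------------------------------
# guide trees (the unique G5s parse)
# ---------------------------------------------------------------------------

@dataclass
class GuideNode:
    """One node of a guide tree / guide forest.

    kind
        ``open`` (unpaired consensus column), ``pair`` (two paired columns),
        ``skip`` (column deleted in this sub-family), ``nil`` (end of a
        column region) or ``fork`` (branch point of an ambivalent forest).
    cols
        1-based alignment columns: ``open``/``skip`` carry one column,
        ``pair`` carries (open_col, close_col), ``nil`` carries the position
        just after the region it terminates, ``fork`` carries none.
    children
        ``pair``: [inside, after]; ``open``/``skip``: [after]; ``nil``: [];
        ``fork``: one subtree per alternative.
    members
        Names of the sub-families whose guide tree contains this node.
    """

    kind: str
    cols: tuple[int, ...]
    children: list["GuideNode"] = field(default_factory=list)
    members: set[str] = field(default_factory=set)
    grammar_index: int | None = None

    @property
    def identity(self) -> tuple:
        return (self.kind, self.cols)

    def walk(self):
        """Depth-first pre-order traversal (children in declaration order)."""
        yield self
        for child in self.children:
            yield from child.walk()

    def copy(self) -> "GuideNode":
        return GuideNode(
            self.kind,
            self.cols,
            [c.copy() for c in self.children],
            set(self.members),
            self.grammar_index,
        )


def parse_guide_tree(ss: ConsensusStructure) -> GuideNode:
    """Parse a consensus structure into its unique guide tree.

    The G5s architecture has exactly one production per leading symbol
    (``<...>`` -> pair, ``*`` -> open, ``-`` -> skip, end of region -> nil),
    so the parse is deterministic; no search or disambiguation is involved.
    """
    s = ss.columns
    partner = pair_table(s)  # raises on unbalanced input
    name = ss.subfamily

    def region(lo: int, hi: int) -> GuideNode:
        # columns lo..hi inclusive, 1-based
        if lo > hi:
            return GuideNode("nil", (hi + 1,), [], {name})
        ch = s[lo - 1]
        if ch == UNPAIRED:
            return GuideNode("open", (lo,), [region(lo + 1, hi)], {name})
        if ch == GAP:
            return GuideNode("skip", (lo,), [region(lo + 1, hi)], {name})
        if ch == OPEN:
            k = partner[lo]
            if k > hi:
                raise StructureError(f"crossing pair ({lo},{k}) escapes its region")
            inside = region(lo + 1, k - 1)
            after = region(k + 1, hi)
            return GuideNode("pair", (lo, k), [inside, after], {name})
        raise StructureError(f"unexpected '>' at column {lo}")

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 4 * len(s) + 100))
    try:
        return region(1, len(s))
    finally:
        sys.setrecursionlimit(old)


def unparse_guide_tree(node: GuideNode) -> str:
    """In-order reading of a guide tree; inverse of :func:`parse_guide_tree`."""
    parts: list[str] = []

    def visit(n: GuideNode) -> None:
        if n.kind == "nil":
            return
        if n.kind == "open":
            parts.append(UNPAIRED)
            visit(n.children[0])
        elif n.kind == "skip":
            parts.append(GAP)
            visit(n.children[0])
        elif n.kind == "pair":
            parts.append(OPEN)
            visit(n.children[0])
            parts.append(CLOSE)
            visit(n.children[1])
        else:  # pragma: no cover - forks have no single string reading
            raise ValueError("cannot unparse a forest containing fork nodes")

    visit(node)
    return "".join(parts)


# ---------------------------------------------------------------------------
# compatibility of consensus-structure sets
# ---------------------------------------------------------------------------

@dataclass
class CompatibilityReport:
    compatible: bool
    violations: list[tuple[str, tuple[int, ...]]] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.compatible

    def describe(self) -> str:
        if self.compatible:
            return "compatible"
        lines = []
        for kind, cols in self.violations:
            lines.append(f"{kind} violation at columns {cols}")
        return "; ".join(lines)


def check_compatible_pair(
    ss1: ConsensusStructure, ss2: ConsensusStructure
) -> CompatibilityReport:
    """Check base-pair persistence and global nesting for two structures.

    Persistence: a column paired in one structure may, in the other, pair
    only with the same partner, be unpaired, or be deleted -- never pair
    elsewhere.  Nesting: the union of both pair sets must contain no crossing
    (k < k' < l < l' with pairs (k, l) and (k', l')).  Implemented as a
    direct pair-map comparison plus a stack scan over the pair union; the
    equivalent two-track grammar parse serves as a test oracle only.
    """
    if ss1.n_columns != ss2.n_columns:
        raise StructureError(
            f"structure lengths differ: {ss1.n_columns} vs {ss2.n_columns}"
        )
    t1 = {a: b for a, b in ss1.pairs}
    t1.update({b: a for a, b in ss1.pairs})
    t2 = {a: b for a, b in ss2.pairs}
    t2.update({b: a for a, b in ss2.pairs})

    violations: list[tuple[str, tuple[int, ...]]] = []
    seen: set[tuple[int, int]] = set()
    for c in sorted(set(t1) & set(t2)):
        if t1[c] != t2[c]:
            key = tuple(sorted((c, t1[c], t2[c])))
            if key not in seen:
                seen.add(key)  # type: ignore[arg-type]
                violations.append(("persistence", (c, t1[c], t2[c])))

    union = sorted(set(ss1.pairs) | set(ss2.pairs))
    stack: list[tuple[int, int]] = []
    for a, b in union:
        while stack and stack[-1][1] < a:
            stack.pop()
        if stack and a < stack[-1][1] < b:
            violations.append(("nesting", (stack[-1][0], a, stack[-1][1], b)))
        else:
            stack.append((a, b))

    return CompatibilityReport(not violations, violations)


def check_compatible_set(
    structures: list[ConsensusStructure],
) -> CompatibilityReport:
    """Pairwise compatibility over a whole structure set (n choose 2 checks)."""
    if not structures:
        raise ValueError("need at least one consensus structure")
    lengths = {s.n_columns for s in structures}
    if len(lengths) > 1:
        raise StructureError(f"structures have differing lengths: {sorted(lengths)}")
    violations: list[tuple[str, tuple[int, ...]]] = []
    for i in range(len(structures)):
        for j in range(i + 1, len(structures)):
            rep = check_compatible_pair(structures[i], structures[j])
            violations.extend(v for v in rep.violations if v not in violations)
    return CompatibilityReport(not violations, violations)
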