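"""Synthetic sub-family alignments with known ground truth.

Every stage of model construction and search can be exercised without any
external data: :func:`sample_alignment` draws an alignment from a fixture
specification (compatible consensus structures, per-column substitution and
indel rates, a pair-covariation rate for compensatory changes), and
:func:`make_trna_like` builds the canonical two-sub-family scenario -- a
majority sub-family with a four-helix cloverleaf-like consensus and a
minority sub-family carrying one extra helix in the variable region.

Indels are realized as whole alignment columns that are gaps in the rows not
carrying them, so gap-column masking is exercised exactly as on real
alignments.  All sampling is deterministic under the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AnnotatedAlignment
from .structure_ops import ConsensusStructure, check_compatible_set

__all__ = [
    "FixtureSpec",
    "sample_alignment",
    "make_trna_like",
    "random_compatible_structures",
]

COMPLEMENTARY = ["AU", "UA", "CG", "GC", "GU", "UG"]
PAIR_WEIGHTS = np.array([0.24, 0.24, 0.2, 0.2, 0.06, 0.06])
BASES = "ACGU"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic family."""

    structures: dict[str, str]            # subfamily -> canonical structure
    rows_per_subfamily: dict[str, int]
    substitution_rate: float = 0.08
    covariation_rate: float = 0.9         # compensatory double change at pairs
    deletion_rate: float = 0.02
    insertion_rate: float = 0.03          # residues at columns gapped in the consensus
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (
            ("substitution_rate", self.substitution_rate),
            ("covariation_rate", self.covariation_rate),
            ("deletion_rate", self.deletion_rate),
            ("insertion_rate", self.insertion_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} = {rate} outside [0, 1]")
        parsed = [
            ConsensusStructure.from_raw(s, subfamily=f)
            for f, s in self.structures.items()
        ]
        report = check_compatible_set(parsed)
        if not report.compatible:
            raise ValueError(
                f"fixture structures are incompatible: {report.describe()}"
            )


def _family_reference(
    structures: list[ConsensusStructure], rng: np.random.Generator
) -> list[str]:
    """One residue per column for the whole family.

    Drawn once on the union pair skeleton so that sub-families share their
    conserved core; base-pair persistence guarantees the union pairing is a
    function, so complementary sampling is well defined.
    """
    n = structures[0].n_columns
    ref = [""] * n
    union_pairs = sorted({p for ss in structures for p in ss.pairs})
    for a, b in union_pairs:
        duo = COMPLEMENTARY[rng.choice(len(COMPLEMENTARY), p=PAIR_WEIGHTS)]
        ref[a - 1], ref[b - 1] = duo[0], duo[1]
    for c in range(n):
        if not ref[c]:
            ref[c] = BASES[rng.integers(4)]
    return ref


def _subfamily_reference(family_ref: list[str], ss: ConsensusStructure) -> list[str]:
    return [
        "-" if ch == "-" else family_ref[c]
        for c, ch in enumerate(ss.columns)
    ]


def _mutate_row(
    ref: list[str], ss: ConsensusStructure, spec: FixtureSpec, rng: np.random.Generator
) -> str:
    row = list(ref)
    for a, b in ss.pairs:
        if rng.random() < spec.covariation_rate:
            duo = COMPLEMENTARY[rng.choice(len(COMPLEMENTARY), p=PAIR_WEIGHTS)]
            row[a - 1], row[b - 1] = duo[0], duo[1]
        else:
            for c in (a, b):
                if rng.random() < spec.substitution_rate:
                    row[c - 1] = BASES[rng.integers(4)]
    for c, ch in enumerate(ss.columns, start=1):
        if ch == "*" and rng.random() < spec.substitution_rate:
            row[c - 1] = BASES[rng.integers(4)]
        if ch in "<>*":
            if rng.random() < spec.deletion_rate:
                row[c - 1] = "-"
        elif ch == "-":
            if rng.random() < spec.insertion_rate:
                row[c - 1] = BASES[rng.integers(4)]
    return "".join(row)


def sample_alignment(spec: FixtureSpec) -> AnnotatedAlignment:
    """Draw an annotated alignment from the fixture specification.

    Each sub-family gets a structure-respecting reference sequence (paired
    columns complementary), rows are mutated copies (compensatory changes at
    pairs with the covariation rate), deletions gap match columns and
    insertions place residues at columns the consensus marks as gaps.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple[str, str, str]] = []
    n_cols = len(next(iter(spec.structures.values())))
    parsed = {
        fam: ConsensusStructure.from_raw(raw, subfamily=fam)
        for fam, raw in spec.structures.items()
    }
    family_ref = _family_reference(list(parsed.values()), rng)
    for fam, raw in spec.structures.items():
        ss = parsed[fam]
        ref = _subfamily_reference(family_ref, ss)
        for i in range(spec.rows_per_subfamily.get(fam, 0)):
            seq = _mutate_row(ref, ss, spec, rng)
            if set(seq) == {"-"}:
                raise ValueError(
                    f"sampled an empty row in sub-family {fam!r}; rates too extreme"
                )
            rows.append((fam, f"{fam}_{i + 1}", seq))
    return AnnotatedAlignment(rows, dict(spec.structures), n_cols)


def make_trna_like(
    seed: int, rows_major: int = 34, rows_minor: int = 6
) -> AnnotatedAlignment:
    """Two-sub-family fixture mimicking the tRNA variable-loop scenario.

    The majority sub-family (~85% of rows) folds into four helices; the
    minority sub-family carries a fifth helix -- a 4 bp stem with a 4 nt
    loop, the size of a typical class-II tRNA variable arm -- on twelve
    extra columns that are gap columns for the majority.  The structures
    are compatible by construction: the extra pairs live on columns the
    majority deletes.
    """
    accept_open = "<<<<"
    dstem = "<<<****>>>"
    astem = "<<<****>>>"
    var_shared = "**"
    var_extra_major = "-" * 12
    var_extra_minor = "<<<<****>>>>"
    tstem = "<<<****>>>"
    accept_close = ">>>>"
    major = (
        accept_open + "*" + dstem + "*" + astem
        + var_shared + var_extra_major + tstem + accept_close
    )
    minor = (
        accept_open + "*" + dstem + "*" + astem
        + var_shared + var_extra_minor + tstem + accept_close
    )
    spec = FixtureSpec(
        structures={"cloverleaf": major, "varloop": minor},
        rows_per_subfamily={"cloverleaf": rows_major, "varloop": rows_minor},
        seed=seed,
    )
    return sample_alignment(spec)


def random_compatible_structures(
    rng: np.random.Generator,
    n_columns: int,
    n_structures: int,
    pair_density: float = 0.35,
) -> list[str]:
    """Random compatible structure sets via a shared nested pair skeleton.

    A random non-crossing pair skeleton over the columns is drawn once; each
    structure independently keeps a subset of the skeleton pairs (dropped
    pairs and non-skeleton columns become unpaired or gap columns).  Any
    such set satisfies base-pair persistence (partners are fixed by the
    skeleton) and global nesting (subsets of a nested set are nested).
    """
    # build a random non-crossing skeleton with a stack sweep
    skeleton: list[tuple[int, int]] = []
    stack: list[int] = []
    for c in range(1, n_columns + 1):
        r = rng.random()
        if r < pair_density and n_columns - c > len(stack):
            stack.append(c)
        elif stack and r < 0.75:
            skeleton.append((stack.pop(), c))
    while stack:
        stack.pop()  # unclosed opens stay unpaired

    structures = []
    for _ in range(n_structures):
        cols = ["*"] * n_columns
        for c in range(n_columns):
            if rng.random() < 0.2:
                cols[c] = "-"
        for a, b in skeleton:
            if rng.random() < 0.7:
                cols[a - 1], cols[b - 1] = "<", ">"
            else:
                for c in (a, b):
                    cols[c - 1] = "*" if rng.random() < 0.7 else "-"
        structures.append("".join(cols))
    return structures
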