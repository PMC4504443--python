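"""Per-sub-family preprocessing of consensus structures.

Three steps turn a curator-supplied consensus annotation into the inputs of
model construction:

1. ``break_pseudoknots`` removes crossing base pairs annotated with
   upper/lower-case letter sets by turning every letter into an unpaired
   column (profile SCFGs cannot represent pseudoknots).
2. ``mask_gap_columns`` classifies alignment columns of one sub-family into
   match columns (gap ratio <= threshold) and insertion columns (ratio
   strictly above), producing the gapped match structure that keeps full
   alignment coordinates: insertion columns become ``-`` and a base pair with
   exactly one masked side is broken, the surviving side becoming unpaired.
3. ``make_training_structure`` derives, for one alignment row, the structure
   string it is forced through during training, and removes columns that are
   gaps in both the row and the structure (the (+)-reduction), remembering
   the original column of every kept position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .structure_ops import GAP, UNPAIRED, ConsensusStructure, pair_table

__all__ = [
    "ColumnMask",
    "TrainingStructure",
    "break_pseudoknots",
    "mask_gap_columns",
    "make_training_structure",
]

GAP_CHARS = {"-", "."}


def break_pseudoknots(raw: str) -> str:
    """Replace letter-annotated (pseudoknot) pair columns by unpaired columns.

    The conversion is unconditional; unmatched letter sets only trigger a
    warning because the outcome -- every letter becomes ``*`` -- is the same.
    """
    letters = [c for c in raw if c.isalpha()]
    uppers = {c.lower() for c in letters if c.isupper()}
    lowers = {c for c in letters if c.islower()}
    if uppers != lowers:
        warnings.warn(
            f"unmatched pseudoknot letter sets (open {sorted(uppers)}, "
            f"close {sorted(lowers)}); converting to unpaired anyway",
            stacklevel=2,
        )
    return "".join(UNPAIRED if c.isalpha() else c for c in raw)


@dataclass
class ColumnMask:
    """Match/insertion classification of one sub-family's columns."""

    is_match: list[bool]
    gap_ratio: list[float]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        for m, r in zip(self.is_match, self.gap_ratio):
            assert m == (r <= self.threshold)


def mask_gap_columns(
    rows: list[str],
    ss_cons: ConsensusStructure,
    threshold: float = 0.5,
) -> tuple[ConsensusStructure, ColumnMask]:
    """Mask majority-gap columns of one sub-family.

    Returns the gapped match structure (full alignment length, masked columns
    as ``-``) and the column mask.  A column whose gap ratio is strictly
    above ``threshold`` is an insertion column; at the default 0.5 this means
    "more gaps than bases".  Columns already deleted (``-``) in ``ss_cons``
    stay deleted regardless of their gap ratio.
    """
    if not rows:
        raise ValueError(f"sub-family {ss_cons.subfamily!r} has no rows")
    n = ss_cons.n_columns
    if any(len(r) != n for r in rows):
        raise ValueError("row length does not match structure length")

    k = len(rows)
    ratios = [sum(r[c] in GAP_CHARS for r in rows) / k for c in range(n)]
    is_match = [ratio <= threshold for ratio in ratios]

    partner = pair_table(ss_cons.columns)
    out = list(ss_cons.columns)
    for c in range(1, n + 1):
        ch = out[c - 1]
        if ch == GAP:
            continue
        if not is_match[c - 1]:
            out[c - 1] = GAP
            if c in partner:
                p = partner[c]
                if is_match[p - 1] and out[p - 1] != GAP:
                    out[p - 1] = UNPAIRED  # broken pair: surviving side unpaired
    # a pair whose partner was already deleted in ss_cons cannot stand alone
    for a, b in ss_cons.pairs:
        if out[a - 1] != GAP and out[b - 1] == GAP and out[a - 1] != UNPAIRED:
            out[a - 1] = UNPAIRED
        if out[b - 1] != GAP and out[a - 1] == GAP and out[b - 1] != UNPAIRED:
            out[b - 1] = UNPAIRED
    masked = ConsensusStructure("".join(out), subfamily=ss_cons.subfamily)
    return masked, ColumnMask(is_match, ratios, threshold)


@dataclass
class TrainingStructure:
    """A row's forced structure after masking and (+)-reduction.

    ``row`` and ``row_structure`` have equal length and no column that is a
    gap in both; ``columns`` maps each kept position to its original 1-based
    alignment column.
    """

    row: str
    row_structure: str
    columns: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert len(self.row) == len(self.row_structure) == len(self.columns)

    def char_at_column(self, col: int) -> tuple[str, str]:
        """(residue, structure char) at an original alignment column.

        Columns removed by the (+)-reduction were gaps in both inputs.
        """
        try:
            i = self._index[col]
        except AttributeError:
            self._index = {c: i for i, c in enumerate(self.columns)}
            return self.char_at_column(col)
        except KeyError:
            return "-", GAP
        return self.row[i], self.row_structure[i]


def make_training_structure(
    row: str,
    ss_match_gapped: ConsensusStructure,
    mask: ColumnMask | None = None,
) -> TrainingStructure:
    """Pair one alignment row with its training structure.

    The training structure equals the gapped match structure of the row's
    sub-family (insertion columns ``-``, broken-pair survivors ``*``).
    Columns that hold a gap in both the row and the structure are removed
    from both; all other columns are kept, so a row gap at a match column
    survives as a deletion event and a row base at a ``-`` column survives
    as an insertion.
    """
    ss = ss_match_gapped.columns
    if len(row) != len(ss):
        raise ValueError("row length does not match structure length")
    kept_row: list[str] = []
    kept_ss: list[str] = []
    cols: list[int] = []
    for c, (r, s) in enumerate(zip(row, ss), start=1):
        r = "-" if r in GAP_CHARS else r
        if r == "-" and s == GAP:
            continue
        kept_row.append(r)
        kept_ss.append(s)
        cols.append(c)
    return TrainingStructure("".join(kept_row), "".join(kept_ss), cols)
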