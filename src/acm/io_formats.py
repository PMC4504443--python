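"""External representations: annotated Stockholm, FASTA queries, model files.

The multi-structure input convention: a Stockholm 1.0 alignment where every
sequence name and every consensus-structure line carries a sub-family name
followed by an ``@`` delimiter -- rows ``red@seq1 ...`` and structure lines
``#=GC red@SS_cons ...``.  A file without any ``@`` prefixes is the classical
single-structure case and is read as one anonymous sub-family ``default``.

The model flat-file is a versioned JSON document of this package's own
design holding the family grammar, the trained parameters and the build
provenance; floating point values round-trip bit-exactly (shortest-repr
serialization of IEEE doubles).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO, SeqIO

from .forest import FamilyGrammar, NodeSpec
from .params import ALPHABET, ModelParams

__all__ = [
    "AnnotatedAlignment",
    "ModelFile",
    "FormatError",
    "read_stockholm",
    "write_stockholm",
    "read_fasta",
    "write_fasta",
    "read_model",
    "write_model",
]

MODEL_FORMAT_VERSION = "acm-1"
SS_TAG = "SS_cons"
DEFAULT_SUBFAMILY = "default"


class FormatError(ValueError):
    pass


def _normalize_seq(seq: str) -> str:
    """Uppercase, T->U, '.' and '-' both to '-'."""
    out = seq.upper().replace("T", "U").replace(".", "-")
    bad = set(out) - set(ALPHABET) - {"-"}
    if bad:
        raise FormatError(f"non-nucleotide symbols in sequence: {sorted(bad)}")
    return out


@dataclass
class AnnotatedAlignment:
    """Alignment rows tagged with sub-families plus one consensus per sub-family."""

    rows: list[tuple[str, str, str]]  # (subfamily, seq name, aligned sequence)
    structures: dict[str, str]        # subfamily -> raw consensus string
    n_columns: int

    def __post_init__(self) -> None:
        if not self.structures:
            raise FormatError("alignment carries no consensus structure")
        for name in self.structures:
            if "@" in name:
                raise FormatError(f"sub-family name {name!r} contains '@'")
            if len(self.structures[name]) != self.n_columns:
                raise FormatError(
                    f"consensus for {name!r} has length "
                    f"{len(self.structures[name])}, expected {self.n_columns}"
                )
        for fam, name, seq in self.rows:
            if len(seq) != self.n_columns:
                raise FormatError(
                    f"row {name!r} has length {len(seq)}, expected {self.n_columns}"
                )
            if fam not in self.structures:
                raise FormatError(
                    f"row {name!r} refers to sub-family {fam!r} "
                    "with no consensus structure line"
                )

    @property
    def subfamilies(self) -> list[str]:
        """Sub-family names in input order (the progressive merge order)."""
        return list(self.structures)

    def rows_of(self, subfamily: str) -> list[tuple[str, str]]:
        return [(n, s) for f, n, s in self.rows if f == subfamily]

    def ungapped(self) -> list[tuple[str, str, str]]:
        """(subfamily, name, gap-free sequence) per row."""
        return [(f, n, s.replace("-", "")) for f, n, s in self.rows]


def _split_prefix(label: str) -> tuple[str | None, str]:
    if "@" in label:
        fam, rest = label.split("@", 1)
        return fam, rest
    return None, label


def read_stockholm(path: str | Path) -> AnnotatedAlignment:
    """Read a (possibly multi-structure) Stockholm alignment."""
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        raise FormatError(f"not a readable Stockholm file: {exc}") from exc

    structures: dict[str, str] = {}
    ann = aln.column_annotations or {}
    for key, value in ann.items():
        tag = key[3:] if key.startswith("GC:") else None
        if key == "secondary_structure":
            tag = SS_TAG
        if tag is None:
            continue
        fam, rest = _split_prefix(tag)
        if rest != SS_TAG:
            continue
        fam = fam if fam is not None else DEFAULT_SUBFAMILY
        if fam in structures:
            raise FormatError(f"duplicate consensus structure line for {fam!r}")
        structures[fam] = value
    if not structures:
        raise FormatError("no #=GC SS_cons line found")

    rows: list[tuple[str, str, str]] = []
    for rec in aln:
        fam, name = _split_prefix(rec.id)
        if fam is None:
            if len(structures) > 1:
                raise FormatError(
                    f"row {rec.id!r} has no sub-family prefix but the file "
                    "declares several consensus structures"
                )
            fam = next(iter(structures))
        elif fam not in structures:
            raise FormatError(
                f"row {rec.id!r} names sub-family {fam!r} "
                "with no matching SS_cons line"
            )
        rows.append((fam, name, _normalize_seq(str(rec.seq))))

    n_cols = aln.get_alignment_length()
    return AnnotatedAlignment(rows, structures, n_cols)


def write_stockholm(alignment: AnnotatedAlignment, path: str | Path) -> None:
    """Write the annotated alignment (valid Stockholm 1.0).

    Written by hand because standard writers drop unknown ``#=GC`` tags.
    Prefixes are omitted for a single anonymous sub-family.
    """
    single = alignment.subfamilies == [DEFAULT_SUBFAMILY]

    def label(fam: str, name: str) -> str:
        return name if single else f"{fam}@{name}"

    names = [label(f, n) for f, n, _ in alignment.rows]
    gc_tags = {
        fam: (SS_TAG if single else f"{fam}@{SS_TAG}")
        for fam in alignment.subfamilies
    }
    width = max(
        [len(n) for n in names] + [len(f"#=GC {t}") for t in gc_tags.values()]
    )
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for (fam, name, seq), lab in zip(alignment.rows, names):
            fh.write(f"{lab:<{width}} {seq}\n")
        for fam in alignment.subfamilies:
            tag = f"#=GC {gc_tags[fam]}"
            fh.write(f"{tag:<{width}} {alignment.structures[fam]}\n")
        fh.write("//\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read query sequences: gap-free, uppercase RNA."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        bad = set(seq) - set(ALPHABET)
        if bad:
            raise FormatError(
                f"record {rec.id!r} contains non-nucleotide symbols {sorted(bad)}"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# model flat-file
# ---------------------------------------------------------------------------

@dataclass
class ModelFile:
    """A built family model: grammar + parameters + build provenance."""

    grammar: FamilyGrammar
    params: ModelParams
    provenance: dict = field(default_factory=dict)
    format_version: str = MODEL_FORMAT_VERSION


def _grammar_to_jsonable(g: FamilyGrammar) -> dict:
    return {
        "root": g.root,
        "n_columns": g.n_columns,
        "subfamilies": list(g.subfamilies),
        "nodes": {
            str(i): {
                "kind": n.kind,
                "cols": list(n.cols),
                "children": list(n.children),
                "members": list(n.members),
            }
            for i, n in sorted(g.nodes.items())
        },
    }


def _grammar_from_jsonable(d: dict) -> FamilyGrammar:
    nodes = {
        int(i): NodeSpec(
            v["kind"], tuple(v["cols"]), tuple(v["children"]), tuple(v["members"])
        )
        for i, v in d["nodes"].items()
    }
    return FamilyGrammar(
        nodes, int(d["root"]), int(d["n_columns"]), tuple(d["subfamilies"])
    )


def write_model(model: ModelFile, path: str | Path) -> None:
    doc = {
        "format_version": model.format_version,
        "grammar": _grammar_to_jsonable(model.grammar),
        "params": model.params.to_jsonable(),
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model(path: str | Path) -> ModelFile:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"truncated or malformed model file: {exc}") from exc
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"unknown model format version {version!r} "
            f"(this build reads {MODEL_FORMAT_VERSION!r})"
        )
    grammar = _grammar_from_jsonable(doc["grammar"])
    params = ModelParams.from_jsonable(doc["params"])
    params.validate({i: grammar.roles(i) for i in grammar.nodes})
    return ModelFile(grammar, params, doc.get("provenance", {}), version)
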