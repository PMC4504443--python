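"""Independent reference implementations used as test oracles.

Everything here is deliberately naive -- generic grammar interpretation,
interval recursion, exhaustive enumeration -- and shares no code with the
dynamic programs it checks.
"""

from __future__ import annotations

import functools

import numpy as np

from acm.forest import AXIOM, FamilyGrammar, generate_grammar, index_forest, merge_forest
from acm.io_formats import ModelFile
from acm.params import BASE_INDEX, ModelParams, Priors
from acm.structure_ops import ConsensusStructure, parse_guide_tree

UNPAIRED_CHARS = {"*", "-"}
ALPHABET = "ACGU"


# ---------------------------------------------------------------------------
# structure-string enumeration and generic parse counting
# ---------------------------------------------------------------------------

def valid_structures(length: int):
    """All balanced structure strings over ``<>*-`` of exactly this length."""

    def gen(prefix: list[str], open_count: int, remaining: int):
        if remaining == 0:
            if open_count == 0:
                yield "".join(prefix)
            return
        for ch in ("*", "-"):
            prefix.append(ch)
            yield from gen(prefix, open_count, remaining - 1)
            prefix.pop()
        if remaining > open_count:  # room for a closing partner later
            prefix.append("<")
            yield from gen(prefix, open_count + 1, remaining - 1)
            prefix.pop()
        if open_count > 0:
            prefix.append(">")
            yield from gen(prefix, open_count - 1, remaining - 1)
            prefix.pop()

    yield from gen([], 0, length)


def count_parses(s: str) -> int:
    """Number of parses of ``s`` under the architecture CFG
    ``x -> '<' x '>' x | '*' x | '-' x | eps`` (generic interval recursion)."""

    @functools.lru_cache(maxsize=None)
    def count(i: int, j: int) -> int:
        total = 1 if i == j else 0
        if i < j and s[i] in UNPAIRED_CHARS:
            total += count(i + 1, j)
        if i < j and s[i] == "<":
            for k in range(i + 1, j):
                if s[k] == ">":
                    total += count(i + 1, k) * count(k + 1, j)
        return total

    return count(0, len(s))


# ---------------------------------------------------------------------------
# two-track compatibility grammar
# ---------------------------------------------------------------------------

def two_track_compatible(s1: str, s2: str) -> bool:
    """Joint parseability of two equal-length structures.

    The two-track grammar aligns both structures column-wise: a column pair
    is consumed either as two unpaired/gap characters, or as the opening of
    a base pair that closes at one shared later column -- paired on both
    tracks, or paired on one track while the other is unpaired/gap at *both*
    ends.  O(m^3) interval recursion with an explicit candidate loop.
    """
    assert len(s1) == len(s2)

    @functools.lru_cache(maxsize=None)
    def parse(i: int, j: int) -> bool:
        if i > j:
            return True
        a, b = s1[i], s2[i]
        if a in UNPAIRED_CHARS and b in UNPAIRED_CHARS and parse(i + 1, j):
            return True
        if a == "<" or b == "<":
            for k in range(i + 1, j + 1):
                ka, kb = s1[k], s2[k]
                if a == "<" and b == "<":
                    ok = ka == ">" and kb == ">"
                elif a == "<":
                    ok = b in UNPAIRED_CHARS and ka == ">" and kb in UNPAIRED_CHARS
                else:
                    ok = a in UNPAIRED_CHARS and kb == ">" and ka in UNPAIRED_CHARS
                if ok and parse(i + 1, k - 1) and parse(k + 1, j):
                    return True
        return False

    import sys

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(s1) + 100))
    try:
        return parse(0, len(s1) - 1)
    finally:
        sys.setrecursionlimit(old)


def random_structure(rng: np.random.Generator, length: int) -> str:
    """One random balanced structure string (independent, dead-end-free walk)."""
    out: list[str] = []
    open_count = 0
    for pos in range(length):
        remaining = length - pos
        if open_count == remaining:
            ch = ">"  # forced: just enough room to close everything
        else:
            choices = ["*", "-"]
            if remaining >= open_count + 2:
                choices.append("<")
            if open_count > 0:
                choices += [">", ">"]
            ch = choices[rng.integers(len(choices))]
        out.append(ch)
        if ch == "<":
            open_count += 1
        elif ch == ">":
            open_count -= 1
    return "".join(out)


# ---------------------------------------------------------------------------
# brute-force derivation enumeration over the declarative productions
# ---------------------------------------------------------------------------

def _trans_bits(params: ModelParams, idx: int, role: str) -> float:
    if role == "axiom":
        return 0.0
    return params.trans_bits(idx, role)


def enumerate_derivations(model: ModelFile, query: str, mode: str = "glocal"):
    """Yield the bit score of every derivation of ``query``.

    Interprets the grammar's declarative production lists symbol by symbol,
    trying every split point; no tables, no recurrences.
    """
    g, p = model.grammar, model.params
    q = [BASE_INDEX[c] for c in query]
    n = len(q)

    def expand(rhs: tuple, i: int, j: int, pending: list):
        if not rhs:
            if i == j:
                yield 0.0
            return
        head, rest = rhs[0], rhs[1:]
        tag = head[0]
        if tag == "base":
            if i < j:
                sc = float(p.emission_bits(head[1])[q[i]])
                for s2 in expand(rest, i + 1, j, pending):
                    yield sc + s2
        elif tag == "pair_open":
            if i < j:
                pending.append(q[i])
                for s2 in expand(rest, i + 1, j, pending):
                    yield s2
                pending.pop()
        elif tag == "pair_close":
            if i < j:
                left = pending[-1]
                sc = float(p.emission_bits(head[1])[4 * left + q[i]])
                for s2 in expand(rest, i + 1, j, pending):
                    yield sc + s2
        elif tag == "region":
            for u in range(i, j + 1):
                sc = p.region_bits(head[1], u - i)
                for s2 in expand(rest, u, j, pending):
                    yield sc + s2
        elif tag == "ref":
            for u in range(i, j + 1):
                for s1 in derive(head[1], i, u):
                    for s2 in expand(rest, u, j, pending):
                        yield s1 + s2
        else:  # pragma: no cover
            raise ValueError(tag)

    def derive(idx: int, i: int, j: int):
        prods = [g.axiom_production()] if idx == AXIOM else g.productions(idx)
        for prod in prods:
            t = _trans_bits(p, idx, prod.role)
            for s in expand(prod.rhs, i, j, []):
                yield t + s

    if mode == "global":
        yield from derive(AXIOM, 0, n)
    else:
        for i0 in range(n + 1):
            for j0 in range(i0, n + 1):
                yield from derive(AXIOM, i0, j0)


def brute_force_best(model: ModelFile, query: str, mode: str = "glocal") -> float:
    return max(enumerate_derivations(model, query, mode), default=float("-inf"))


def brute_force_count(model: ModelFile, length: int, mode: str = "glocal") -> int:
    query = "A" * length
    return sum(1 for _ in enumerate_derivations(model, query, mode))


# ---------------------------------------------------------------------------
# random models
# ---------------------------------------------------------------------------

def random_model(rng: np.random.Generator, structures: list[str]) -> ModelFile:
    """A model with the grammar of the given structures and random parameters."""
    parsed = [
        ConsensusStructure(s, subfamily=f"f{i}") for i, s in enumerate(structures)
    ]
    trees = [parse_guide_tree(ss) for ss in parsed]
    forest = merge_forest(trees)
    index_forest(forest)
    grammar = generate_grammar(forest, len(structures[0]))

    transition = {}
    for idx in grammar.nodes:
        roles = grammar.roles(idx)
        raw = rng.dirichlet(np.ones(len(roles)))
        for role, v in zip(roles, raw):
            transition[(idx, role)] = float(v)
    slot_open = {s: float(rng.uniform(0.05, 0.6)) for s in grammar.slots()}
    emission = {}
    for key, arity in grammar.emission_keys().items():
        emission[key] = rng.dirichlet(np.ones(arity))
    params = ModelParams(
        transition, slot_open, emission, Priors(),
        ins_extend=float(rng.uniform(0.2, 0.8)),
    )
    return ModelFile(grammar, params, {"random": True})


def random_queries(rng: np.random.Generator, length: int, count: int) -> list[str]:
    return [
        "".join(ALPHABET[rng.integers(4)] for _ in range(length)) for _ in range(count)
    ]
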