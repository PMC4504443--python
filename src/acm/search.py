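"""Glocal CYK alignment of queries to a family model.

The dynamic program fills, bottom-up over the guide forest, one table
``C_g(i, j)`` per grammar index ``g``: the best bit score for deriving the
query subword ``q[i:j]`` from nonterminal ``g``.  Insertion regions and the
single-emission variants reduce to prefix/suffix maxima, so only pair nodes
need a true split (a max-plus matrix product), matching the classical
``O(n * m^3)`` worst case with ``O(n * m^2)`` space.

Scores are log2 (bits) throughout: emissions are log-odds against the flat
background, transitions raw log probabilities; ``-inf`` marks impossible
cells.  Derivation *counting* runs the same recurrences over the counting
semiring (sum/product, exact integers).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .forest import AXIOM, LEAD_SLOT, FamilyGrammar
from .io_formats import ModelFile
from .params import ALPHABET, BASE_INDEX, ModelParams

__all__ = [
    "AlignmentResult",
    "cyk_align",
    "count_search_space",
    "dinucleotide_shuffle",
    "search_many",
    "score_events",
]

NEG_INF = float("-inf")


@dataclass
class AlignmentResult:
    bit_score: float
    emission_bits: float
    transition_bits: float
    traceback: list[tuple]
    query_name: str = ""
    label: str = "positive"

    def __post_init__(self) -> None:
        if math.isfinite(self.bit_score):
            assert abs(self.bit_score - (self.emission_bits + self.transition_bits)) < 1e-9


def encode_query(query: str) -> np.ndarray:
    seq = query.upper().replace("T", "U")
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"query contains non-nucleotide symbols {sorted(bad)}")
    return np.array([BASE_INDEX[c] for c in seq], dtype=np.intp)


# ---------------------------------------------------------------------------
# table construction (max-plus semiring, numpy)
# ---------------------------------------------------------------------------

def _suffix_max(C: np.ndarray) -> np.ndarray:
    """S(i, j) = max_{u >= i} C(u, j)."""
    return np.flip(np.maximum.accumulate(np.flip(C, 0), 0), 0)


def _prefix_max(C: np.ndarray) -> np.ndarray:
    """P(i, j) = max_{v <= j} C(i, v)."""
    return np.maximum.accumulate(C, 1)


def _shift_up(C: np.ndarray) -> np.ndarray:
    """A(i, j) = C(i+1, j); last row -inf."""
    out = np.full_like(C, NEG_INF)
    out[:-1] = C[1:]
    return out


def _compose_left(coeffs: tuple[float, float, float], C: np.ndarray) -> np.ndarray:
    """Best score of [region][C] over (i, j).

    A region of k >= 1 residues costs ``c1 + k * ce`` bits (geometric length
    term), an empty one ``c0``; the affine form folds into a suffix maximum.
    """
    c0, c1, ce = coeffs
    n1 = C.shape[0]
    u = np.arange(n1, dtype=float)
    S = _suffix_max(C + ce * u[:, None])
    S1 = _shift_up(S)  # max over u >= i+1 of C(u, j) + u * ce
    return np.maximum(c0 + C, (c1 - ce * u)[:, None] + S1)


def _compose_right(X: np.ndarray, coeffs: tuple[float, float, float]) -> np.ndarray:
    """Best score of [X][region] over (i, j), region cost affine in length."""
    c0, c1, ce = coeffs
    n1 = X.shape[0]
    v = np.arange(n1, dtype=float)
    P = _prefix_max(X - ce * v[None, :])
    P1 = np.full_like(X, NEG_INF)
    P1[:, 1:] = P[:, :-1]  # max over v <= j-1 of X(i, v) - v * ce
    return np.maximum(c0 + X, c1 + ce * v[None, :] + P1)


def _maxplus(U: np.ndarray, T: np.ndarray) -> np.ndarray:
    """C(i, j) = max_u U(i, u) + T(u, j)."""
    n1 = U.shape[0]
    C = np.full_like(U, NEG_INF)
    for i in range(n1):
        row = U[i]
        finite = row > NEG_INF
        if not finite.any():
            continue
        C[i] = np.max(row[:, None] + T, axis=0)
    return C


def _topological_order(grammar: FamilyGrammar) -> list[int]:
    """Children before parents (the node graph is a tree)."""
    order: list[int] = []
    stack = [(grammar.root, False)]
    while stack:
        idx, done = stack.pop()
        if done:
            order.append(idx)
            continue
        stack.append((idx, True))
        for c in grammar.nodes[idx].children:
            stack.append((c, False))
    return order


class _Tables:
    """All DP tables for one (model, query) pair, kept for traceback."""

    def __init__(self, grammar: FamilyGrammar, params: ModelParams, q: np.ndarray):
        self.grammar = grammar
        self.params = params
        self.q = q
        n = len(q)
        self.n = n
        self.C: dict[int, np.ndarray] = {}
        self.aux: dict[int, dict[str, np.ndarray]] = {}
        self._fill()

    def _slot(self, key: str) -> tuple[float, float, float]:
        return self.params.region_coefficients(key)

    def _fill(self) -> None:
        g, p, q, n = self.grammar, self.params, self.q, self.n
        nil_table = np.full((n + 1, n + 1), NEG_INF)
        np.fill_diagonal(nil_table, 0.0)

        for idx in _topological_order(g):
            node = g.nodes[idx]
            kind = node.kind
            if kind == "nil":
                self.C[idx] = nil_table
                continue
            if kind == "skip":
                self.C[idx] = self.C[node.children[0]]
                continue
            if kind == "fork":
                stacked = [
                    p.trans_bits(idx, f"branch_{m}") + self.C[c]
                    for m, c in enumerate(node.children)
                ]
                self.C[idx] = np.maximum.reduce(stacked)
                continue
            if kind == "open":
                (nxt,) = node.children
                key = f"un:{node.cols[0]}"
                ev = p.emission_bits(key)[q] if n else np.empty(0)
                T = _compose_left(self._slot(f"{idx}:trail"), self.C[nxt])
                match = np.full((n + 1, n + 1), NEG_INF)
                if n:
                    match[:n] = (p.trans_bits(idx, "match") + ev)[:, None] + T[1:]
                delete = p.trans_bits(idx, "delete") + self.C[nxt]
                self.C[idx] = np.maximum(match, delete)
                self.aux[idx] = {"T": T}
                continue
            # pair node
            inside, nxt = node.children
            a, b = node.cols
            C_in = self.C[inside]
            ep = p.emission_bits(f"pair:{a}:{b}").reshape(4, 4)
            ev_a = p.emission_bits(f"un:{a}")[q] if n else np.empty(0)
            ev_b = p.emission_bits(f"un:{b}")[q] if n else np.empty(0)
            inl = self._slot(f"{idx}:inl")
            inr = self._slot(f"{idx}:inr")

            RC1 = _compose_left(inl, C_in)              # [inl][inside]
            D2 = _compose_right(RC1, inr)               # [inl][inside][inr]
            E1 = _compose_right(C_in, inr)              # [inside][inr]

            U_mp = np.full((n + 1, n + 1), NEG_INF)
            if n >= 2:
                ep_mat = ep[q[:, None], q[None, :]]     # (n, n): left i, close j-1
                U_mp[:n, 1:] = p.trans_bits(idx, "match_pair") + ep_mat + D2[1:, :-1]
            U_ml = np.full((n + 1, n + 1), NEG_INF)
            if n:
                U_ml[:n] = (p.trans_bits(idx, "match_left") + ev_a)[:, None] + RC1[1:]
            U_mr = np.full((n + 1, n + 1), NEG_INF)
            if n:
                U_mr[:, 1:] = p.trans_bits(idx, "match_right") + E1[:, :-1] + ev_b[None, :]
            U_del = p.trans_bits(idx, "delete") + C_in
            U = np.maximum.reduce([U_mp, U_ml, U_mr, U_del])
            T = _compose_left(self._slot(f"{idx}:trail"), self.C[nxt])
            self.C[idx] = _maxplus(U, T)
            self.aux[idx] = {
                "U": U, "U_mp": U_mp, "U_ml": U_ml, "U_mr": U_mr,
                "U_del": U_del, "T": T, "RC1": RC1, "D2": D2, "E1": E1,
            }

        self.axiom = _compose_left(self._slot(LEAD_SLOT), self.C[g.root])


# ---------------------------------------------------------------------------
# traceback
# ---------------------------------------------------------------------------

class _Traceback:
    """Deterministic argmax derivation: candidates are examined in the
    canonical order (match variants before delete, insertion-region splits
    with the smaller left part first) and a candidate replaces the incumbent
    only when strictly better, so ties resolve to the first candidate."""

    def __init__(self, tables: _Tables):
        self.t = tables
        self.g = tables.grammar
        self.p = tables.params
        self.q = tables.q
        self.events: list[tuple] = []

    # -- helpers --------------------------------------------------------

    def _emit(self, key: str, cols: tuple[int, ...], positions: tuple[int, ...]):
        bases = "".join(ALPHABET[self.q[p]] for p in positions)
        self.events.append(("emit", key, bases, cols, positions))

    def _slot_ev(self, key: str, span: tuple[int, int]):
        self.events.append(("slot", key, span))

    def _prod(self, idx: int, role: str, span: tuple[int, int]):
        self.events.append(("prod", idx, role, span))

    def _region_then(self, slot: str, child: int, i: int, j: int):
        """Split [region][child] over (i, j); returns the region end."""
        C = self.t.C[child]
        best, arg = NEG_INF, None
        for u in range(i, j + 1):
            val = self.p.region_bits(slot, u - i) + C[u, j]
            if val > best:
                best, arg = val, u
        assert arg is not None
        self._slot_ev(slot, (i, arg))
        return arg

    # -- node dispatch ---------------------------------------------------

    def chain(self, idx: int, i: int, j: int) -> None:
        node = self.g.nodes[idx]
        kind = node.kind
        if kind == "nil":
            assert i == j, f"nil over non-empty span ({i},{j})"
            self._prod(idx, "end", (i, j))
            return
        if kind == "skip":
            self._prod(idx, "skip", (i, j))
            self.chain(node.children[0], i, j)
            return
        if kind == "fork":
            best, arg = NEG_INF, None
            for m, c in enumerate(node.children):
                val = self.p.trans_bits(idx, f"branch_{m}") + self.t.C[c][i, j]
                if val > best:
                    best, arg = val, m
            self._prod(idx, f"branch_{arg}", (i, j))
            self.chain(node.children[arg], i, j)
            return
        if kind == "open":
            self._open(idx, i, j)
            return
        self._pair(idx, i, j)

    def _open(self, idx: int, i: int, j: int) -> None:
        node = self.g.nodes[idx]
        (nxt,) = node.children
        col = node.cols[0]
        T = self.t.aux[idx]["T"]
        match = NEG_INF
        if i < j:
            ev = self.p.emission_bits(f"un:{col}")[self.q[i]]
            match = self.p.trans_bits(idx, "match") + ev + T[i + 1, j]
        delete = self.p.trans_bits(idx, "delete") + self.t.C[nxt][i, j]
        if match >= delete and match > NEG_INF:
            self._prod(idx, "match", (i, j))
            self._emit(f"un:{col}", (col,), (i,))
            u = self._region_then(f"{idx}:trail", nxt, i + 1, j)
            self.chain(nxt, u, j)
        else:
            self._prod(idx, "delete", (i, j))
            self.chain(nxt, i, j)

    def _pair(self, idx: int, i: int, j: int) -> None:
        node = self.g.nodes[idx]
        inside, nxt = node.children
        a, b = node.cols
        aux = self.t.aux[idx]
        U, T = aux["U"], aux["T"]
        # outer split: unit span (i, u), then [trail][next] over (u, j)
        best = NEG_INF
        for u in range(i, j + 1):
            val = U[i, u] + T[u, j]
            if val > best:
                best = val
        assert best > NEG_INF, "pair node has no viable derivation"
        chosen = None
        for role, arr in (
            ("match_pair", aux["U_mp"]),
            ("match_left", aux["U_ml"]),
            ("match_right", aux["U_mr"]),
            ("delete", aux["U_del"]),
        ):
            for u in range(i, j + 1):
                if arr[i, u] + T[u, j] == best:
                    chosen = (role, u)
                    break
            if chosen:
                break
        assert chosen is not None
        role, u = chosen
        self._prod(idx, role, (i, u))
        p = self.p
        if role == "match_pair":
            ep = p.emission_bits(f"pair:{a}:{b}").reshape(4, 4)
            self._emit(f"pair:{a}:{b}", (a, b), (i, u - 1))
            target = aux["U_mp"][i, u] - p.trans_bits(idx, "match_pair") - ep[self.q[i], self.q[u - 1]]
            v = self._split_D2(idx, i + 1, u - 1, target)
            # v = (inl end, inside end); inside spans (v0, v1)
            self.chain(inside, v[0], v[1])
        elif role == "match_left":
            self._emit(f"un:{a}", (a,), (i,))
            v0 = self._split_RC1(idx, i + 1, u)
            self.chain(inside, v0, u)
        elif role == "match_right":
            self._emit(f"un:{b}", (b,), (u - 1,))
            w = self._split_E1(idx, i, u - 1)
            self.chain(inside, i, w)
        else:  # delete
            self.chain(inside, i, u)
        w2 = self._region_then_trail(idx, nxt, u, j)
        self.chain(nxt, w2, j)

    def _region_then_trail(self, idx: int, nxt: int, u: int, j: int) -> int:
        return self._region_then(f"{idx}:trail", nxt, u, j)

    def _split_RC1(self, idx: int, i: int, j: int) -> int:
        """[inl][inside] over (i, j): returns inside start; emits slot event."""
        node = self.g.nodes[idx]
        inside = node.children[0]
        C_in = self.t.C[inside]
        best, arg = NEG_INF, None
        for v in range(i, j + 1):
            val = self.p.region_bits(f"{idx}:inl", v - i) + C_in[v, j]
            if val > best:
                best, arg = val, v
        assert arg is not None
        self._slot_ev(f"{idx}:inl", (i, arg))
        return arg

    def _split_E1(self, idx: int, i: int, j: int) -> int:
        """[inside][inr] over (i, j): returns inside end; emits slot event."""
        node = self.g.nodes[idx]
        inside = node.children[0]
        C_in = self.t.C[inside]
        best, arg = NEG_INF, None
        for w in range(i, j + 1):
            val = C_in[i, w] + self.p.region_bits(f"{idx}:inr", j - w)
            if val > best:
                best, arg = val, w
        assert arg is not None
        self._slot_ev(f"{idx}:inr", (arg, j))
        return arg

    def _split_D2(self, idx: int, i: int, j: int, target: float) -> tuple[int, int]:
        """[inl][inside][inr] over (i, j): returns (inside start, inside end)."""
        node = self.g.nodes[idx]
        inside = node.children[0]
        C_in = self.t.C[inside]
        best, arg = NEG_INF, None
        for v in range(i, j + 1):
            for w in range(v, j + 1):
                val = (
                    self.p.region_bits(f"{idx}:inl", v - i)
                    + C_in[v, w]
                    + self.p.region_bits(f"{idx}:inr", j - w)
                )
                if val > best:
                    best, arg = val, (v, w)
        assert arg is not None
        v, w = arg
        self._slot_ev(f"{idx}:inl", (i, v))
        self._slot_ev(f"{idx}:inr", (w, j))
        return arg


def score_events(params: ModelParams, events: list[tuple]) -> tuple[float, float]:
    """(emission bits, transition bits) of a derivation event list."""
    em = 0.0
    tr = 0.0
    for ev in events:
        tag = ev[0]
        if tag == "emit":
            _, key, bases, _cols, _pos = ev
            vec = params.emission_bits(key)
            if len(bases) == 2:
                em += float(vec[4 * BASE_INDEX[bases[0]] + BASE_INDEX[bases[1]]])
            else:
                em += float(vec[BASE_INDEX[bases[0]]])
        elif tag == "slot":
            _, key, span = ev
            tr += params.region_bits(key, span[1] - span[0])
        elif tag == "prod":
            _, idx, role, _span = ev
            if role in ("end", "skip", "axiom"):
                continue
            tr += params.trans_bits(idx, role)
    return em, tr


def cyk_align(model: ModelFile, query: str, mode: str = "glocal") -> AlignmentResult:
    """Best-derivation (CYK) bit score of a query against the model.

    ``glocal``: the whole model must be used, but it may match any subword
    of the query; the flanks are unscored and unpenalized.  ``global``: the
    model must explain the entire query.
    """
    if mode not in ("glocal", "global"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    q = encode_query(query)
    n = len(q)
    tables = _Tables(model.grammar, model.params, q)
    ax = tables.axiom
    if mode == "global":
        i0, j0 = 0, n
        score = float(ax[0, n])
    else:
        flat = np.argmax(ax)
        i0, j0 = np.unravel_index(flat, ax.shape)
        score = float(ax[i0, j0])
        # prefer the earliest, shortest span among ties
        hits = np.argwhere(ax == score)
        if len(hits) and math.isfinite(score):
            order = sorted((int(i), int(j)) for i, j in hits if i <= j)
            i0, j0 = order[0]
    if not math.isfinite(score):
        return AlignmentResult(NEG_INF, NEG_INF, NEG_INF, [], query_name="")

    tb = _Traceback(tables)
    tb._prod(AXIOM, "axiom", (i0, j0))
    u = tb._region_then(LEAD_SLOT, model.grammar.root, i0, j0)
    tb.chain(model.grammar.root, u, j0)
    em, tr = score_events(model.params, tb.events)
    total = em + tr
    if abs(total - score) > 1e-6:  # pragma: no cover - internal consistency
        warnings.warn(
            f"traceback rescoring ({total}) deviates from DP score ({score})"
        )
    return AlignmentResult(total, em, tr, tb.events)


# ---------------------------------------------------------------------------
# derivation counting (sum-product semiring, exact integers)
# ---------------------------------------------------------------------------

@dataclass
class SearchSpaceCount:
    count: int
    query_length: int


def _count_compose_left(C: list[list[int]]) -> list[list[int]]:
    n1 = len(C)
    out = [[0] * n1 for _ in range(n1)]
    for j in range(n1):
        suf = 0
        for i in range(n1 - 1, -1, -1):
            out[i][j] = C[i][j] + suf  # empty region (u=i) plus all u>i
            suf += C[i][j]
    return out


def _count_compose_right(X: list[list[int]]) -> list[list[int]]:
    n1 = len(X)
    out = [[0] * n1 for _ in range(n1)]
    for i in range(n1):
        pre = 0
        for j in range(n1):
            out[i][j] = X[i][j] + pre
            pre += X[i][j]
    return out


def count_search_space(model: ModelFile, query_length: int, mode: str = "glocal") -> SearchSpaceCount:
    """Exact number of distinct derivations for any query of this length.

    Runs the CYK recurrences with (sum, product) in place of (max, plus);
    the count is residue-independent because every production accepts every
    nucleotide.
    """
    g = model.grammar
    n = query_length
    n1 = n + 1
    C: dict[int, list[list[int]]] = {}

    def zeros() -> list[list[int]]:
        return [[0] * n1 for _ in range(n1)]

    for idx in _topological_order(g):
        node = g.nodes[idx]
        kind = node.kind
        if kind == "nil":
            t = zeros()
            for i in range(n1):
                t[i][i] = 1
            C[idx] = t
            continue
        if kind == "skip":
            C[idx] = C[node.children[0]]
            continue
        if kind == "fork":
            t = zeros()
            for c in node.children:
                Cc = C[c]
                for i in range(n1):
                    for j in range(n1):
                        t[i][j] += Cc[i][j]
            C[idx] = t
            continue
        if kind == "open":
            (nxt,) = node.children
            T = _count_compose_left(C[nxt])
            t = zeros()
            for i in range(n1):
                for j in range(i, n1):
                    v = C[nxt][i][j]  # delete
                    if i < j:
                        v += T[i + 1][j]  # match: base then region then next
                    t[i][j] = v
            C[idx] = t
            continue
        # pair
        inside, nxt = node.children
        C_in = C[inside]
        RC1 = _count_compose_left(C_in)
        D2 = _count_compose_right(RC1)
        E1 = _count_compose_right(C_in)
        T = _count_compose_left(C[nxt])
        U = zeros()
        for i in range(n1):
            for j in range(i, n1):
                v = C_in[i][j]  # delete
                if i < j:
                    v += RC1[i + 1][j]        # match_left
                    v += E1[i][j - 1]         # match_right
                if j - i >= 2:
                    v += D2[i + 1][j - 1]     # match_pair
                U[i][j] = v
        t = zeros()
        for i in range(n1):
            for j in range(i, n1):
                t[i][j] = sum(U[i][u] * T[u][j] for u in range(i, j + 1))
        C[idx] = t

    ax = _count_compose_left(C[g.root])
    if mode == "global":
        total = ax[0][n]
    else:
        total = sum(ax[i][j] for i in range(n1) for j in range(i, n1))
    return SearchSpaceCount(total, n)


# ---------------------------------------------------------------------------
# dinucleotide shuffle (Altschul-Erickson Eulerian walk)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Random permutation preserving all dinucleotide counts and both ends.

    Implements the Eulerian-walk scheme: pick, for every vertex except the
    terminal one, a random outgoing "last edge" such that the picked edges
    form an arborescence toward the terminal vertex; shuffle the remaining
    edges and walk the graph.  Deterministic for a fixed seed.
    """
    if len(seq) < 2:
        return seq
    rng = np.random.default_rng(seed)
    chars = sorted(set(seq))
    edges: dict[str, list[str]] = {c: [] for c in chars}
    for x, y in zip(seq, seq[1:]):
        edges[x].append(y)
    last = seq[-1]

    non_terminal = [c for c in chars if c != last and edges[c]]
    for _attempt in range(1000):
        pick = {c: edges[c][rng.integers(len(edges[c]))] for c in non_terminal}
        ok = True
        for c in non_terminal:
            v, seen = c, set()
            while v != last:
                if v in seen or v not in pick:
                    ok = False
                    break
                seen.add(v)
                v = pick[v]
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - cannot happen for a connected walk graph
        raise RuntimeError("failed to sample an arborescence")

    ordered: dict[str, list[str]] = {}
    for c in chars:
        rest = list(edges[c])
        if c in pick:
            rest.remove(pick[c])
        perm = rng.permutation(len(rest))
        out = [rest[k] for k in perm]
        if c in pick:
            out.append(pick[c])
        ordered[c] = out

    walk = [seq[0]]
    cursor = {c: 0 for c in chars}
    v = seq[0]
    for _ in range(len(seq) - 1):
        nxt = ordered[v][cursor[v]]
        cursor[v] += 1
        walk.append(nxt)
        v = nxt
    return "".join(walk)


def search_many(
    model: ModelFile,
    records: list[tuple[str, str]],
    mode: str = "glocal",
    shuffle_seed: int | None = None,
) -> list[AlignmentResult]:
    """Score records in order; optionally add one shuffled negative each.

    Per-record failures are reported as warnings, not raised, so a single
    bad query does not abort a batch.
    """
    out: list[AlignmentResult] = []
    for k, (name, seq) in enumerate(records):
        try:
            res = cyk_align(model, seq, mode=mode)
            res.query_name = name
            res.label = "positive"
            out.append(res)
            if shuffle_seed is not None:
                neg = dinucleotide_shuffle(seq, seed=shuffle_seed + k)
                nres = cyk_align(model, neg, mode=mode)
                nres.query_name = f"{name}|shuffled"
                nres.label = "negative"
                out.append(nres)
        except ValueError as exc:
            warnings.warn(f"skipping record {name!r}: {exc}")
    return out
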