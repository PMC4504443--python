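"""Turning an annotated alignment into trained model parameters.

Training follows the classical covariance-model recipe: rows are weighted by
Gerstein/Sonnhammer/Chothia tree weights, optionally renormalized so the
mean match-column emission entropy meets a target (the effective sequence
number ``k_eff``), then each row is forced through the single derivation its
sub-family's branch of the guide forest dictates.  Because the derivation is
forced, counting is a deterministic tree walk, not a parse: every production
used adds the row's weight to its transition count and every emitted residue
or residue pair adds it to the emission vector of its algebra index (shared
across fork branches, so common columns are trained sub-family combined).
Priors are added to the counts before normalization; emissions are converted
to log-odds bits against the flat background, transitions stay raw
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .forest import (
    FamilyGrammar,
    generate_grammar,
    index_forest,
    merge_forest,
)
from .io_formats import AnnotatedAlignment, ModelFile
from .params import BASE_INDEX, ModelParams, Priors, pair_cell
from .preprocess import (
    TrainingStructure,
    break_pseudoknots,
    make_training_structure,
    mask_gap_columns,
)
from .structure_ops import (
    ConsensusStructure,
    check_compatible_set,
    parse_guide_tree,
)

__all__ = [
    "BuildConfig",
    "CountTables",
    "SequenceWeights",
    "TrainingError",
    "tree_weights",
    "effective_seq_number",
    "count_training",
    "estimate_params",
    "build_model",
]


class TrainingError(ValueError):
    pass


@dataclass
class BuildConfig:
    gap_threshold: float = 0.5
    target_entropy: float = 1.46       # bits, mean over match-column emissions
    entropy_weighting: bool = True
    weighting: str = "gsc"             # "gsc" | "uniform"
    emission_prior: float = 1.0
    transition_prior: float = 1.0
    slot_prior: float = 1.0
    free_forks: bool = False
    seed: int | None = None


# ---------------------------------------------------------------------------
# sequence weighting
# ---------------------------------------------------------------------------

@dataclass
class SequenceWeights:
    weights: np.ndarray
    k: int

    @property
    def k_eff(self) -> float:
        return float(self.weights.sum())


def _fractional_identity(a: str, b: str) -> float:
    shared = same = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            shared += 1
            if x == y:
                same += 1
    return same / shared if shared else 0.0


def tree_weights(rows: list[str]) -> SequenceWeights:
    """Gerstein/Sonnhammer/Chothia weights on an average-linkage guide tree.

    Distances are 1 - fractional identity over columns where both rows hold
    a residue.  Each tree edge's length is divided equally among the leaves
    below it and summed along root-to-leaf paths; weights are normalized to
    sum to the row count ``k``.  Degenerate trees (all rows identical) fall
    back to uniform weights.
    """
    k = len(rows)
    if k == 0:
        raise TrainingError("cannot weight an empty alignment")
    if k == 1:
        return SequenceWeights(np.ones(1), 1)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = 1.0 - _fractional_identity(rows[i], rows[j])
            dist[i, j] = dist[j, i] = d
    Z = linkage(squareform(dist, checks=False), method="average")

    # ultrametric depth of each node above the leaves
    depth = np.zeros(2 * k - 1)
    leaves_below: list[list[int]] = [[i] for i in range(k)] + [[] for _ in range(k - 1)]
    for m, (ia, ib, h, _cnt) in enumerate(Z):
        node = k + m
        depth[node] = h / 2.0
        leaves_below[node] = leaves_below[int(ia)] + leaves_below[int(ib)]

    w = np.zeros(k)
    for m, (ia, ib, _h, _cnt) in enumerate(Z):
        node = k + m
        for child in (int(ia), int(ib)):
            edge = depth[node] - depth[child]
            below = leaves_below[child]
            if edge > 0:
                w[below] += edge / len(below)
    total = w.sum()
    if total <= 0:
        w = np.ones(k)
    else:
        w = w * (k / total)
    return SequenceWeights(w, k)


# ---------------------------------------------------------------------------
# entropy-based effective sequence number
# ---------------------------------------------------------------------------

def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def _match_column_counts(
    groups: list[tuple[list[tuple[str, float]], ConsensusStructure]],
) -> list[np.ndarray]:
    """Weighted residue-count vectors of every match column slot.

    One 4-vector per unpaired match column and one 16-vector per pair, per
    sub-family (computed on that sub-family's rows only).
    """
    vectors: list[np.ndarray] = []
    for rows, ss in groups:
        paired = {a for a, b in ss.pairs} | {b for a, b in ss.pairs}
        for c, ch in enumerate(ss.columns, start=1):
            if ch != "*" or c in paired:
                continue
            v = np.zeros(4)
            for seq, wt in rows:
                r = seq[c - 1]
                if r in BASE_INDEX:
                    v[BASE_INDEX[r]] += wt
            vectors.append(v)
        for a, b in ss.pairs:
            v = np.zeros(16)
            for seq, wt in rows:
                x, y = seq[a - 1], seq[b - 1]
                if x in BASE_INDEX and y in BASE_INDEX:
                    v[pair_cell(x, y)] += wt
            vectors.append(v)
    return vectors


def effective_seq_number(
    groups: list[tuple[list[tuple[str, float]], ConsensusStructure]],
    k: float,
    target_entropy: float,
    emission_prior: float = 1.0,
    tol: float = 1e-4,
) -> tuple[float, float]:
    """Scale factor and effective sequence number for entropy weighting.

    Finds lambda in (0, 1] by bisection so that the mean posterior emission
    entropy (weighted counts scaled by lambda, plus priors, normalized) of
    all match-column slots meets ``target_entropy``; ``k_eff = lambda * k``.
    If the entropy at lambda = 1 already meets the target, or the target is
    not bracketed, lambda stays 1.
    """
    vectors = _match_column_counts(groups)
    if not vectors:
        return 1.0, k

    def mean_entropy(lam: float) -> float:
        hs = []
        for v in vectors:
            post = lam * v + emission_prior
            hs.append(_entropy_bits(post / post.sum()))
        return float(np.mean(hs))

    if mean_entropy(1.0) >= target_entropy:
        return 1.0, k
    lo, hi = 1e-9, 1.0
    if mean_entropy(lo) < target_entropy:
        return 1.0, k  # not bracketed: priors alone cannot reach the target
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if mean_entropy(mid) >= target_entropy:
            lo = mid
        else:
            hi = mid
    lam = lo
    return lam, lam * k


# ---------------------------------------------------------------------------
# forced-derivation counting
# ---------------------------------------------------------------------------

@dataclass
class CountTables:
    emission: dict[str, np.ndarray] = field(default_factory=dict)
    transition: dict[tuple[int, str], float] = field(default_factory=dict)
    slot: dict[str, np.ndarray] = field(default_factory=dict)  # [open, empty]
    extension: np.ndarray = field(default_factory=lambda: np.zeros(2))  # [extend, end]

    @classmethod
    def zeros(cls, grammar: FamilyGrammar) -> "CountTables":
        t = cls()
        for key, arity in grammar.emission_keys().items():
            t.emission[key] = np.zeros(arity)
        for idx in grammar.nodes:
            for role in grammar.roles(idx):
                t.transition[(idx, role)] = 0.0
        for slot in grammar.slots():
            t.slot[slot] = np.zeros(2)
        return t

    def add_emission(self, key: str, cell: int, weight: float) -> None:
        self.emission[key][cell] += weight

    def add_transition(self, idx: int, role: str, weight: float) -> None:
        self.transition[(idx, role)] += weight

    def add_slot(self, slot: str, nonempty: bool, weight: float) -> None:
        self.slot[slot][0 if nonempty else 1] += weight


def forced_derivation(
    grammar: FamilyGrammar,
    training: TrainingStructure,
    subfamily: str,
) -> list[tuple]:
    """The single derivation a training row is forced through.

    The walk follows the row's sub-family branch at every fork; match
    columns with a residue use the match variant (emitting the residue),
    gapped match columns use the deletion variant, and residues at skipped
    (insertion) columns are assigned to the canonical insertion slot -- the
    first region slot following the previous emission in derivation order.
    Returns derivation events in the same schema as a search traceback.
    """
    events: list[tuple] = []
    tokens: list[tuple] = []  # ("anchor",), ("slot", key), ("ins", base)

    def residue(col: int) -> str:
        r, _s = training.char_at_column(col)
        return r

    def structure_char(col: int) -> str:
        _r, s = training.char_at_column(col)
        return s

    def prod(idx: int, role: str) -> None:
        events.append(("prod", idx, role, ()))

    def emit(key: str, bases: str, cols: tuple[int, ...]) -> None:
        events.append(("emit", key, bases, cols, ()))

    def walk(idx: int) -> None:
        node = grammar.nodes[idx]
        kind = node.kind
        if kind == "nil":
            prod(idx, "end")
            return
        if kind == "fork":
            for m, child in enumerate(node.children):
                if subfamily in grammar.nodes[child].members:
                    prod(idx, f"branch_{m}")
                    walk(child)
                    return
            raise TrainingError(
                f"sub-family {subfamily!r} has no branch at fork {idx}"
            )
        if kind == "skip":
            c = node.cols[0]
            prod(idx, "skip")
            r = residue(c)
            if r != "-":
                tokens.append(("ins", r))
            walk(node.children[0])
            return
        if kind == "open":
            c = node.cols[0]
            sc = structure_char(c)
            if sc != "*":
                raise TrainingError(
                    f"row structure has {sc!r} at unpaired match column {c}"
                )
            r = residue(c)
            if r == "-":
                prod(idx, "delete")
            else:
                prod(idx, "match")
                emit(f"un:{c}", r, (c,))
                tokens.append(("anchor",))
                tokens.append(("slot", f"{idx}:trail"))
            walk(node.children[0])
            return
        # pair: the node exists in this sub-family's tree, so its training
        # structure must hold the intact pair at these columns
        a, b = node.cols
        sa, sb = structure_char(a), structure_char(b)
        if (sa, sb) != ("<", ">"):
            raise TrainingError(
                f"row structure chars ({sa!r},{sb!r}) at pair columns ({a},{b})"
            )
        ra, rb = residue(a), residue(b)
        inside, _nxt = node.children
        if ra != "-" and rb != "-":
            prod(idx, "match_pair")
            emit(f"pair:{a}:{b}", ra + rb, (a, b))
            tokens.append(("anchor",))
            tokens.append(("slot", f"{idx}:inl"))
            walk(inside)
            tokens.append(("slot", f"{idx}:inr"))
            tokens.append(("anchor",))
        elif ra != "-":
            prod(idx, "match_left")
            emit(f"un:{a}", ra, (a,))
            tokens.append(("anchor",))
            tokens.append(("slot", f"{idx}:inl"))
            walk(inside)
        elif rb != "-":
            prod(idx, "match_right")
            walk(inside)
            tokens.append(("slot", f"{idx}:inr"))
            emit(f"un:{b}", rb, (b,))
            tokens.append(("anchor",))
        else:
            prod(idx, "delete")
            walk(inside)
        tokens.append(("slot", f"{idx}:trail"))
        walk(node.children[1])

    tokens.append(("slot", "lead"))
    walk(grammar.root)

    # canonical slot assignment for inserted residues
    active: str | None = None
    awaiting = True
    filled: dict[str, int] = {}
    visited: list[str] = []
    for tok in tokens:
        if tok[0] == "slot":
            visited.append(tok[1])
            if awaiting:
                active = tok[1]
                awaiting = False
        elif tok[0] == "anchor":
            awaiting = True
        else:  # insertion residue
            assert active is not None
            filled[active] = filled.get(active, 0) + 1
    for slot in visited:
        events.append(("slot", slot, (0, filled.get(slot, 0))))
    return events


def count_training(
    grammar: FamilyGrammar,
    counts: CountTables,
    training: TrainingStructure,
    weight: float,
    subfamily: str,
) -> None:
    """Accumulate one row's forced derivation into the count tables."""
    for ev in forced_derivation(grammar, training, subfamily):
        tag = ev[0]
        if tag == "prod":
            counts.add_transition(ev[1], ev[2], weight)
        elif tag == "emit":
            _t, key, bases, _cols, _pos = ev
            if len(bases) == 2:
                counts.add_emission(key, pair_cell(bases[0], bases[1]), weight)
            else:
                counts.add_emission(key, BASE_INDEX[bases], weight)
        else:  # slot
            k = ev[2][1] - ev[2][0]
            counts.add_slot(ev[1], k > 0, weight)
            if k > 0:
                counts.extension[0] += (k - 1) * weight
                counts.extension[1] += weight


# ---------------------------------------------------------------------------
# parameter estimation
# ---------------------------------------------------------------------------

def estimate_params(
    counts: CountTables,
    grammar: FamilyGrammar,
    priors: Priors = Priors(),
    free_forks: bool = False,
) -> ModelParams:
    """Posterior-mean parameters: (count + prior) / row sums.

    With all-zero counts every distribution equals the normalized prior.
    Raises if a zero-prior row has zero counts (undefined distribution).
    """
    transition: dict[tuple[int, str], float] = {}
    for idx in grammar.nodes:
        roles = grammar.roles(idx)
        raw = [counts.transition[(idx, r)] + priors.transition for r in roles]
        total = sum(raw)
        if total <= 0:
            raise TrainingError(f"undefined transition distribution at index {idx}")
        for role, v in zip(roles, raw):
            transition[(idx, role)] = v / total

    slot_open: dict[str, float] = {}
    for slot in grammar.slots():
        opened, empty = counts.slot[slot]
        total = opened + empty + 2 * priors.slot
        if total <= 0:
            raise TrainingError(f"undefined slot distribution at {slot}")
        slot_open[slot] = (opened + priors.slot) / total

    emission: dict[str, np.ndarray] = {}
    for key, vec in counts.emission.items():
        post = vec + priors.emission
        total = post.sum()
        if total <= 0:
            raise TrainingError(f"undefined emission distribution at {key}")
        emission[key] = post / total

    ext, end = counts.extension
    ins_extend = (ext + priors.slot) / (ext + end + 2 * priors.slot)

    params = ModelParams(
        transition, slot_open, emission, priors, free_forks, float(ins_extend)
    )
    params.validate({i: grammar.roles(i) for i in grammar.nodes})
    return params


# ---------------------------------------------------------------------------
# end-to-end build
# ---------------------------------------------------------------------------

def prepare_structures(
    alignment: AnnotatedAlignment, gap_threshold: float = 0.5
) -> dict[str, ConsensusStructure]:
    """Pseudoknot-broken, gap-masked consensus per sub-family (full length)."""
    out: dict[str, ConsensusStructure] = {}
    for fam in alignment.subfamilies:
        raw = break_pseudoknots(alignment.structures[fam])
        ss = ConsensusStructure.from_raw(raw, subfamily=fam)
        rows = [seq for _n, seq in alignment.rows_of(fam)]
        masked, _mask = mask_gap_columns(rows, ss, threshold=gap_threshold)
        out[fam] = masked
    return out


def build_model(alignment: AnnotatedAlignment, config: BuildConfig | None = None) -> ModelFile:
    """Construct and train a (possibly ambivalent) covariance model.

    Pipeline: break pseudoknots -> compatibility check -> per-sub-family gap
    masking -> guide-tree parsing -> forest merge -> indexing -> grammar
    generation -> sequence weighting -> entropy renormalization -> forced
    derivation counting -> parameter estimation.
    """
    cfg = config or BuildConfig()

    raw_structures = [
        ConsensusStructure.from_raw(
            break_pseudoknots(alignment.structures[fam]), subfamily=fam
        )
        for fam in alignment.subfamilies
    ]
    report = check_compatible_set(raw_structures)
    if not report.compatible:
        raise TrainingError(
            f"consensus structures are incompatible: {report.describe()}; "
            "construction aborted"
        )

    masked = prepare_structures(alignment, cfg.gap_threshold)
    trees = [parse_guide_tree(masked[fam]) for fam in alignment.subfamilies]
    forest = merge_forest(trees)
    index_forest(forest)
    grammar = generate_grammar(
        forest, alignment.n_columns, tuple(alignment.subfamilies)
    )

    seqs = [seq for _f, _n, seq in alignment.rows]
    if cfg.weighting == "gsc":
        sw = tree_weights(seqs)
    elif cfg.weighting == "uniform":
        sw = SequenceWeights(np.ones(len(seqs)), len(seqs))
    else:
        raise ValueError(f"unknown weighting scheme {cfg.weighting!r}")
    weights = sw.weights.copy()

    lam = 1.0
    k_eff = float(sw.k)
    if cfg.entropy_weighting:
        groups = []
        offsets: dict[str, list[int]] = {}
        for i, (fam, _n, _s) in enumerate(alignment.rows):
            offsets.setdefault(fam, []).append(i)
        for fam in alignment.subfamilies:
            rows = [(seqs[i], float(weights[i])) for i in offsets.get(fam, [])]
            groups.append((rows, masked[fam]))
        lam, k_eff = effective_seq_number(
            groups, float(sw.k), cfg.target_entropy, cfg.emission_prior
        )
        weights = weights * lam

    counts = CountTables.zeros(grammar)
    for (fam, _name, seq), wt in zip(alignment.rows, weights):
        ts = make_training_structure(seq, masked[fam])
        count_training(grammar, counts, ts, float(wt), fam)

    priors = Priors(cfg.emission_prior, cfg.transition_prior, cfg.slot_prior)
    params = estimate_params(counts, grammar, priors, cfg.free_forks)

    provenance = {
        "gap_threshold": cfg.gap_threshold,
        "target_entropy": cfg.target_entropy,
        "entropy_weighting": cfg.entropy_weighting,
        "entropy_scale": lam,
        "weighting": cfg.weighting,
        "priors": {
            "emission": cfg.emission_prior,
            "transition": cfg.transition_prior,
            "slot": cfg.slot_prior,
        },
        "free_forks": cfg.free_forks,
        "seed": cfg.seed,
        "k": sw.k,
        "k_eff": k_eff,
        "subfamily_sizes": {
            fam: len(alignment.rows_of(fam)) for fam in alignment.subfamilies
        },
    }
    return ModelFile(grammar, params, provenance)
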