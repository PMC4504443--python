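# Methods

## Model

An ambivalent covariance model (aCM) is a profile stochastic context-free
grammar for an RNA family whose members fold into one of several
*compatible* consensus secondary structures.  Compatibility means (a)
**base-pair persistence** — an alignment column paired with partner *l* in
one structure may, in any other, only pair with *l*, be unpaired, or be
deleted — and (b) **global nesting** — the union of all structures' base
pairs contains no crossing.  Both are checked before construction (pairwise
over all structure pairs) and violation aborts the build.  The check is a
direct pair-map comparison plus a stack sweep over the pair union; the test
suite holds an equivalent two-track interval parser as an independent
oracle.

### Guide trees and the guide forest

Each sub-family's consensus (after pseudoknot letters are broken to
unpaired columns and majority-gap columns are masked) is parsed with an
unambiguous four-rule architecture — pair `<...>`, unpaired `*`, deleted
column `-`, end of region — giving exactly one parse tree per structure,
the *guide tree*.  Masked ("insertion") columns are kept as explicit skip
nodes so all guide trees share alignment coordinates; a base pair with
exactly one masked side is broken and the surviving side becomes unpaired.
The gap-ratio rule is "strictly above threshold ⇒ insertion column"
(default threshold 0.5, so a column is an insertion column when it holds
more gaps than residues), computed per sub-family on its own rows.

Guide trees are merged progressively, in input order, into one **ambivalent
guide forest**.  Node identity is (kind, alignment columns); matching nodes
are shared and their children merged positionally, and where a tree
diverges from everything already in the forest, its complete divergent
subtree is added under a **fork** node.

Fork placement balances two goals: forks as low as possible (maximal
sharing, smallest model) and *no unseen structure combination* (the
grammar's indel-free derivations must be exactly the input structure set).
Because fork alternatives are chosen independently in a context-free
derivation, two forks reachable in the same derivation (one inside a pair's
enclosed region, another in a sibling region) would cross-multiply their
branches.  The merge therefore places the fork at the lowest single node
whose subtree covers *all* divergence points of the tree being threaded in,
promoting it further if any previously created fork would otherwise be
jointly reachable with it.  Consequences worth noting:

* a fork's alternatives may share their root node identity (when the
  divergences sit deeper in two independent regions, the fork must still be
  placed above them);
* input sets whose region variants form a full cross-product could in
  principle share more than this construction does — exactness is preferred
  over minimality, and the structure-language test verifies exactness on
  random compatible sets.

Every forest node gets a unique **grammar index** (depth-first pre-order;
a list of forests is numbered consecutively), governing transitions.
Emitting nodes additionally carry an **algebra index** derived from their
alignment columns — `un:<col>` for single-residue emissions and
`pair:<a>:<b>` for pair emissions — shared across fork branches, so
emission statistics at common columns pool all sub-families.  A pair's
single-sided variants (below) emit through the per-column `un:` keys, which
are likewise shared with any unpaired node at the same column in another
branch.

### The family model grammar

Each forest node becomes one nonterminal:

| node  | productions |
|-------|-------------|
| unpaired | match: `b r0 ·` &nbsp;·&nbsp; delete: `·` |
| pair  | match-pair: `b r0 inside r0 b' r0 ·` · match-left: `b r0 inside r0 ·` · match-right: `inside r0 b' r0 ·` · delete: `inside r0 ·` |
| skip  | `·` (no emission, probability 1) |
| fork  | one production per branch |
| end   | ε |

where `·` is the next sibling chain, `b`/`b b'` are scored emissions and
`r0` is an **insertion region**: zero or more residues emitted at the
background (0 bits) whose cost is purely transitional — a per-slot Bernoulli
for opening the region plus a model-wide geometric length term
(`log2 p_open + (k−1)·log2 q + log2(1−q)` for k ≥ 1 residues).  Insertions
are thus regions attached to match emissions, not self-loop states; the
affine-in-length cost is what makes an unmodeled helix in a query cost
bits in a single-structure model, as in classical CMs.  The axiom wraps the
model root with a leading region; glocal search adds free, unscored query
flanks outside the axiom (global mode disables them).

Training forces each row through the single derivation its sub-family's
branch dictates: residues at match columns count the match variant and its
emission, gaps count deletions, and each run of residues at skipped columns
is assigned to a canonical insertion slot — the first region slot following
the previous emission in derivation order (after every emission a slot
follows immediately, so the assignment is total and deterministic; the
grammar itself admits equivalent placements, which the CYK resolves by its
tie rule).  Region slots after the closing base of a pair, and the two
slots flanking a pair's enclosed region, cover all insertion positions.

### Parameters

Weighted counts from the forced derivations are turned into probabilities
by adding pseudocount priors and normalizing: emissions 1.0 per cell,
transitions 1.0 per alternative, insertion slots 1.0 per outcome
(configurable; the geometric extension probability is trained from the
pooled insertion run lengths with the slot prior).  Emission bit scores are
`log2(p / bg0)` with `bg0` uniform (1/4 unpaired, 1/16 pairs); transitions
have no background.  Fork branches are trained like any other transition
from the weighted sub-family counts; `free_forks=True` scores every branch
0 bits instead (both modes exist because branch choice can be viewed either
as part of the family model or as a free structural hypothesis).

Sequence weighting: Gerstein/Sonnhammer/Chothia weights on an
average-linkage tree of 1 − fractional-identity distances (identity over
columns where both rows hold residues), normalized to sum to k; a
`uniform` option exists for i.i.d.-sampled data.  Entropy weighting
rescales the weights by λ ∈ (0, 1], found by bisection (tolerance 1e-4) so
that the mean posterior emission entropy over match-column slots — 4-way
for unpaired columns, 16-way for pairs, each computed per sub-family on its
own rows — meets a target; k_eff = λ·k.  The target default is 1.46 bits;
if the alignment's entropy already meets the target, or the target is
unreachable even at λ → 0, λ stays 1.  `entropy_weighting=False` skips the
step entirely.

## Search

The CYK dynamic program fills one table `C_g(i, j)` per grammar index over
query subwords, children before parents.  Insertion regions have affine
length cost, so region-then-child compositions reduce to prefix/suffix
maxima; single-emission variants place their residue at a span edge; only
pair nodes need a true split (a max-plus matrix product between the pair
unit and its continuation), giving the classical `O(n·m³)` worst case and
`O(n·m²)` space, with everything but the pair split vectorized.
Bifurcation-free chains run in `O(n²)` per node.

Tie-breaking is fixed: production variants in the order match(-pair) >
match-left > match-right > delete (forks by branch order), then the
smaller left split; the traceback examines candidates in exactly this
order and replaces only on strict improvement, so reported derivations are
deterministic.  The bit score is re-derived by summing the traceback's
emission and transition terms (`bit_score = emission_bits +
transition_bits` exactly); an internal consistency check warns if that sum
drifts more than 1e-6 from the table optimum.  Impossible alignments score
−∞ with an empty traceback.

Search-space counting runs the same recurrences over the counting semiring
(sum/product, exact Python integers); the count is residue-independent
because every production accepts every nucleotide.

Negatives for benchmarking are dinucleotide shuffles (Eulerian-walk
scheme): all 16 dinucleotide counts and both terminal residues are
preserved exactly, deterministically under a seed.

## Synthetic data

The generator emulates the structural situation the method targets: a
shared family core (one family-wide reference sequence drawn on the union
pair skeleton, so sub-families agree at common columns), per-row
substitutions at unpaired columns, compensatory double changes at paired
columns (default covariation rate 0.9, substitution rate 0.08), deletions
of match columns (0.02) and insertions realized as residues at columns the
consensus marks as gaps (0.03) — so gap masking is exercised exactly as on
real alignments.  The tRNA-like preset has 34 majority rows with a
four-helix consensus and 6 minority rows (85%/15%) whose structure adds a
fifth helix — a 4 bp stem with a 4 nt loop on twelve extra columns, the
size of a typical class-II tRNA variable arm.

What the generator does **not** emulate: phylogenetic correlation between
rows (rows are i.i.d. mutants of the reference), alignment errors,
non-Watson-Crick structure, sequence-dependent indel hotspots, or
length variation within the variable arm.  Passing tests therefore show the
pipeline's correctness and the qualitative sub-family effect under clean
conditions, not expected performance on curated seed alignments.

## Problem sizes in the test suite

Chosen to give exhaustive or high-power checks at desk scale: unique-parse
enumeration over all 82,499 balanced structure strings of length ≤ 10;
compatibility oracle agreement exhaustively over all same-length structure
pairs of length ≤ 6 (≈ 2·10⁵ pairs) plus 10,000 seeded random pairs of
length ≤ 40; structure-language exactness on 120 random compatible sets
(≤ 20 columns, ≤ 4 structures); CYK and counting against brute-force
derivation enumeration on 50 random-parameter models of ≤ 10 columns for
query lengths ≤ 4; parameter recovery from 400 sequences sampled from a
strongly conserved two-sub-family truth model (total variation ≤ 0.05 per
emitting node); and the five-model sub-family comparison on the 40-row
tRNA-like fixture.

## Known limitations

* Pseudoknots are removed, local alignment, inside/forward scoring and
  E-value calibration are not implemented, and there are no search
  heuristics (banding, filters) — scoring is exact CYK.
* Bit scores are not comparable to production CM software: priors are
  simple pseudocounts rather than fitted Dirichlet mixtures, and the
  grammar architecture differs, which shifts transition contributions.
* Sub-grammar sharing between fork alternatives (identical substructures
  trained separately per branch) is not attempted; highly similar branches
  cost duplicated parameters and tables.
* The progressive merge is input-order dependent in principle; forests are
  canonical up to fork-alternative order, which follows the sub-family
  input order.
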