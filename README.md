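# acm-rna — ambivalent covariance models for RNA homology search

Covariance models (CMs) are profile stochastic context-free grammars: given a
multiple alignment of an RNA family and one consensus secondary structure
`SS_cons`, they score how well a query sequence matches the family's sequence
*and* structure conservation, including base-pair covariation.  A classical CM
encodes exactly one consensus structure, so families with genuine structural
variation — e.g. the minority of tRNAs that fold a fifth, base-paired
"variable arm" in addition to the cloverleaf — get penalized for their extra
structure, or are split into artificial sub-families.

This package builds **ambivalent covariance models (aCMs)**: one model per
family encoding several *compatible* consensus structures.  Each sub-family's
structure is parsed into a guide tree with an unambiguous architecture
grammar; the guide trees are merged into an **ambivalent guide forest** that
shares common parts and branches at *fork* nodes where the structures
diverge; the forest is evaluated into the family model grammar whose
indel-free derivations are exactly the input structures — no structure the
curator never wrote.  Parameters are trained as for classical CMs
(Gerstein/Sonnhammer/Chothia tree weights, entropy-based effective sequence
number, pseudocount priors), and queries are scored with a glocal CYK
alignment as a log-odds **bit score**

```
bits(x) = max over derivations d of [ sum log2 P(emissions in d) / bg0
                                    + sum log2 P(transitions in d) ]
```

against a flat background `bg0` (unpaired 1/4, pairs 1/16).  The classical
single-structure CM is the n = 1 special case of the same construction.

Intended users: developers of RNA family models and homology-search methods
who want multi-structure families testable end to end at desk scale.  The
heavily engineered speed-ups of production search tools (filters, banding,
local mode, E-values) are deliberately out of scope.

## Input conventions

Stockholm 1.0 with one consensus line per sub-family; sub-family membership
is encoded by a name plus `@` prefix on sequence names and `#=GC ...SS_cons`
tags:

```
# STOCKHOLM 1.0
red@seq1               GG-ACGCC
purple@seq2            GGUACAGC
#=GC red@SS_cons       <<**><>>
#=GC purple@SS_cons    <<**>**>
//
```

A file without `@` prefixes is the classical single-structure case.  The
structure alphabet accepts `<>()` for pairs, `*.:,` for unpaired columns,
`-_` for deleted (gap) columns, and upper/lower-case letter pairs for
pseudoknots (which are broken to unpaired columns, as CMs cannot model
them).  All structures must pass the compatibility check: a column may pair
only with one fixed partner across structures (base-pair persistence) and
the union of all pairs must be crossing-free (global nesting).

## Worked example

```python
from acm import AmbivalentCM, dinucleotide_shuffle
from acm.synthetic_fixtures import make_trna_like

alignment = make_trna_like(seed=7)            # 34 cloverleaf + 6 variable-arm rows
results = AmbivalentCM(alignment, seed=7).fit()
print(results.summary())

fam, name, seq = alignment.ungapped()[-1]     # a variable-arm member
hit = results.score(seq)
print(f"{name}: {hit.bit_score:.2f} bits")
print(f"shuffled: {results.score(dinucleotide_shuffle(seq, seed=7)).bit_score:.2f} bits")
```

prints

```
Ambivalent covariance model
===========================
sub-families:        cloverleaf, varloop
alignment columns:   54
grammar nodes:       79 (pair 20, unpaired 24, skip 12, fork 1)
training sequences:  k=40, k_eff=40.00
sub-family sizes:    cloverleaf: 34, varloop: 6
fork 29:             [cloverleaf] p=0.833  [varloop] p=0.167

varloop_6: 37.75 bits
shuffled: -12.22 bits
```

The single fork is where the two consensus structures diverge (the variable
arm); its branch probabilities reflect the 34/6 training split.  The
variable-arm member scores 37.75 bits — its extra helix is rewarded as
covarying base pairs rather than penalized as an insertion — while its
dinucleotide-shuffled negative scores far below zero.

The same pipeline is scriptable from a shell:

```bash
acm fixtures --preset trna-like --seed 7 -o fam.sto
acm check -i fam.sto                      # compatibility report
acm build -i fam.sto -o fam.acm --dump-grammar
acm search -m fam.acm -q queries.fa --with-shuffled --seed 7
acm eval  -i fam.sto --seed 7             # sub-family CMs vs cherry picking vs aCM
```

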