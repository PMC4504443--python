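"""CYK alignment, search-space counting and dinucleotide shuffling."""

import math

import numpy as np
import pytest

from acm.forest import generate_grammar, index_forest, merge_forest
from acm.io_formats import ModelFile
from acm.params import ModelParams, Priors
from acm.search import (
    count_search_space,
    cyk_align,
    dinucleotide_shuffle,
    score_events,
    search_many,
)
from acm.structure_ops import ConsensusStructure, parse_guide_tree
from acm.training import BuildConfig, build_model, count_training, CountTables
from acm.preprocess import make_training_structure
from tests.oracles import brute_force_best, brute_force_count, random_model


def single_open_model(p_match=1.0, p_a=1.0, slot=0.0):
    """Model of the structure '*': one unpaired consensus column."""
    tree = parse_guide_tree(ConsensusStructure("*", subfamily="f0"))
    forest = merge_forest([tree])
    index_forest(forest)
    grammar = generate_grammar(forest, 1)
    rest = (1.0 - p_a) / 3.0
    params = ModelParams(
        transition={
            (1, "match"): p_match,
            (1, "delete"): 1.0 - p_match,
            (2, "end"): 1.0,
        },
        slot_open={s: slot for s in grammar.slots()},
        emission={"un:1": np.array([p_a, rest, rest, rest])},
        priors=Priors(),
    )
    return ModelFile(grammar, params)


class TestCykAlign:
    def test_certain_emission_scores_two_bits(self):
        # P(A) = 1 against background 1/4: log2(4) = 2 bits, no other cost
        model = single_open_model()
        res = cyk_align(model, "A")
        assert res.bit_score == pytest.approx(2.0, abs=1e-12)
        assert res.emission_bits == pytest.approx(2.0, abs=1e-12)
        assert res.transition_bits == pytest.approx(0.0, abs=1e-12)

    def test_empty_query_uses_delete(self):
        model = single_open_model(p_match=0.5)
        res = cyk_align(model, "")
        assert res.bit_score == pytest.approx(math.log2(0.5), abs=1e-12)
        roles = [e[2] for e in res.traceback if e[0] == "prod"]
        assert "delete" in roles

    def test_invalid_symbol_raises(self):
        model = single_open_model()
        with pytest.raises(ValueError):
            cyk_align(model, "ACGN")

    def test_glocal_ignores_flanks(self):
        model = single_open_model()
        assert cyk_align(model, "CCACC").bit_score == pytest.approx(2.0, abs=1e-9)

    def test_global_must_explain_whole_query(self):
        model = single_open_model(slot=0.2)
        g = cyk_align(model, "CCACC", mode="global")
        assert g.bit_score < cyk_align(model, "CCACC").bit_score

    @pytest.mark.parametrize("trial", range(12))
    def test_matches_brute_force_enumeration(self, trial, rng):
        from acm.synthetic_fixtures import random_compatible_structures

        structs = random_compatible_structures(
            rng, int(rng.integers(2, 7)), int(rng.integers(1, 3))
        )
        model = random_model(rng, structs)
        for length in (0, 2, 3, 4):
            q = "".join("ACGU"[rng.integers(4)] for _ in range(length))
            got = cyk_align(model, q).bit_score
            want = brute_force_best(model, q)
            assert got == pytest.approx(want, abs=1e-9), (structs, q)

    def test_score_decomposition_matches_traceback(self, trna_model, trna_alignment):
        _f, _n, seq = trna_alignment.ungapped()[0]
        res = cyk_align(trna_model, seq)
        em, tr = score_events(trna_model.params, res.traceback)
        assert res.emission_bits == pytest.approx(em, abs=1e-12)
        assert res.transition_bits == pytest.approx(tr, abs=1e-12)
        assert res.bit_score == pytest.approx(em + tr, abs=1e-9)

    def test_forced_derivation_never_beats_cyk(self, trna_model, trna_alignment):
        from acm.training import forced_derivation, prepare_structures

        masked = prepare_structures(trna_alignment)
        for fam, _name, row in trna_alignment.rows[:8]:
            ts = make_training_structure(row, masked[fam])
            events = forced_derivation(trna_model.grammar, ts, fam)
            em, tr = score_events(trna_model.params, events)
            res = cyk_align(trna_model, row.replace("-", ""))
            assert math.isfinite(res.bit_score)
            assert em + tr <= res.bit_score + 1e-9


class TestCounting:
    def test_single_open_model_empty_query(self):
        model = single_open_model()
        assert count_search_space(model, 0).count == 1

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_enumeration(self, trial, rng):
        from acm.synthetic_fixtures import random_compatible_structures

        structs = random_compatible_structures(
            rng, int(rng.integers(1, 7)), int(rng.integers(1, 3))
        )
        model = random_model(rng, structs)
        for length in range(0, 5):
            got = count_search_space(model, length).count
            want = brute_force_count(model, length)
            assert got == want, (structs, length)

    def test_count_positive_whenever_accepted(self, trna_model):
        assert count_search_space(trna_model, 4).count >= 1


class TestDinucleotideShuffle:
    def test_homopolymer_is_fixed_point(self):
        assert dinucleotide_shuffle("AAAA", seed=5) == "AAAA"

    def test_short_sequences_returned_unchanged(self):
        assert dinucleotide_shuffle("A", seed=0) == "A"
        assert dinucleotide_shuffle("", seed=0) == ""

    @staticmethod
    def dinuc_counts(s):
        from collections import Counter

        return Counter(zip(s, s[1:]))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_counts_and_endpoints_preserved(self, seed, rng):
        seq = "".join("ACGU"[rng.integers(4)] for _ in range(60))
        out = dinucleotide_shuffle(seq, seed=seed)
        assert self.dinuc_counts(out) == self.dinuc_counts(seq)
        assert out[0] == seq[0] and out[-1] == seq[-1]

    def test_deterministic_under_seed(self):
        seq = "ACGUACGGUUCAGACGUUAGCUAGCUAGCAUCGUAGGGAC"
        assert dinucleotide_shuffle(seq, seed=9) == dinucleotide_shuffle(seq, seed=9)

    def test_different_seeds_usually_differ(self):
        seq = "ACGUACGGUUCAGACGUUAGCUAGCUAGCAUCGUAGGGACAUUGCA"
        outs = {dinucleotide_shuffle(seq, seed=s) for s in range(6)}
        assert len(outs) > 1


class TestSearchMany:
    def test_empty_input_gives_empty_output(self):
        assert search_many(single_open_model(), []) == []

    def test_shuffle_doubles_and_labels(self):
        model = single_open_model()
        records = [("q1", "ACGU"), ("q2", "GGAA")]
        out = search_many(model, records, shuffle_seed=3)
        assert len(out) == 4
        assert [r.label for r in out] == ["positive", "negative"] * 2
        assert [r.query_name for r in out][::2] == ["q1", "q2"]
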