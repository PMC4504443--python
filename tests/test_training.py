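"""Sequence weighting, entropy renormalization, counting and estimation."""

import math

import numpy as np
import pytest

from acm.forest import generate_grammar, index_forest, merge_forest
from acm.params import Priors
from acm.preprocess import make_training_structure
from acm.structure_ops import ConsensusStructure, parse_guide_tree
from acm.training import (
    BuildConfig,
    CountTables,
    TrainingError,
    build_model,
    count_training,
    effective_seq_number,
    estimate_params,
    forced_derivation,
    prepare_structures,
    tree_weights,
)


def grammar_for(*structures):
    trees = [
        parse_guide_tree(ConsensusStructure(s, subfamily=f"f{i}"))
        for i, s in enumerate(structures)
    ]
    forest = merge_forest(trees)
    index_forest(forest)
    return generate_grammar(forest, len(structures[0]))


class TestTreeWeights:
    def test_identical_rows_get_unit_weights(self):
        sw = tree_weights(["ACGU"] * 5)
        assert np.allclose(sw.weights, 1.0)
        assert sw.weights.sum() == pytest.approx(5.0)

    def test_two_rows_always_equal(self):
        sw = tree_weights(["ACGU", "GGGG"])
        assert np.allclose(sw.weights, [1.0, 1.0])

    def test_outlier_outweighs_clones(self):
        rows = ["ACGUACGU", "ACGUACGU", "ACGUACGU", "UGCAUGCA"]
        sw = tree_weights(rows)
        assert sw.weights[3] > sw.weights[0]
        assert np.allclose(sw.weights[:3], sw.weights[0])
        assert sw.weights.sum() == pytest.approx(4.0)


class TestEffectiveSeqNumber:
    @staticmethod
    def groups(rows, ss):
        return [([(r, 1.0) for r in rows], ConsensusStructure(ss))]

    def test_uniform_target_drives_lambda_down(self):
        rows = ["AAAA"] * 20
        lam, k_eff = effective_seq_number(self.groups(rows, "****"), 20, 2.0)
        # target 2.0 bits is the uniform maximum for unpaired columns: only
        # lambda -> 0 approaches it, so lambda collapses to its lower bound
        assert lam < 1e-3
        assert k_eff == pytest.approx(lam * 20)

    def test_high_entropy_alignment_keeps_k(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACGU")) for _ in range(6)) for _ in range(30)]
        lam, k_eff = effective_seq_number(self.groups(rows, "******"), 30, 1.46)
        assert lam == 1.0 and k_eff == 30

    def test_mean_entropy_monotone_in_lambda(self):
        from acm.training import _match_column_counts

        rows = ["AAAA", "AACA", "AAGA", "AAAA", "CAAA"]
        vectors = _match_column_counts(self.groups(rows, "****"))

        def mean_entropy(lam):
            out = []
            for v in vectors:
                post = lam * np.asarray(v) + 1.0
                p = post / post.sum()
                out.append(-(p * np.log2(p)).sum())
            return np.mean(out)

        grid = [mean_entropy(lam) for lam in np.linspace(1.0, 0.01, 25)]
        assert all(b >= a - 1e-12 for a, b in zip(grid, grid[1:]))

    def test_hits_target_within_tolerance(self):
        rows = ["AAAA"] * 40
        target = 1.5
        lam, _ = effective_seq_number(self.groups(rows, "****"), 40, target)
        post = lam * np.array([40.0, 0, 0, 0]) + 1.0
        p = post / post.sum()
        h = -(p * np.log2(p)).sum()
        assert h == pytest.approx(target, abs=1e-2)


class TestCountTraining:
    def test_all_match_row_counts_once_each(self):
        g = grammar_for("<**>")
        counts = CountTables.zeros(g)
        ts = make_training_structure("ACGU", ConsensusStructure("<**>"))
        count_training(g, counts, ts, 1.0, "f0")
        assert counts.transition[(1, "match_pair")] == 1.0
        assert counts.transition[(1, "delete")] == 0.0
        pair_key = "pair:1:4"
        assert counts.emission[pair_key].sum() == 1.0
        # A..U pair cell
        assert counts.emission[pair_key][3] == 1.0
        # no insertion slot was opened
        for vec in counts.slot.values():
            assert vec[0] == 0.0

    def test_gap_at_match_column_counts_delete(self):
        g = grammar_for("***")
        counts = CountTables.zeros(g)
        ts = make_training_structure("A-U", ConsensusStructure("***"))
        count_training(g, counts, ts, 1.0, "f0")
        deletes = [v for (i, r), v in counts.transition.items() if r == "delete"]
        assert sum(deletes) == 1.0

    def test_insertion_residue_opens_canonical_slot(self):
        g = grammar_for("*-*")
        counts = CountTables.zeros(g)
        ts = make_training_structure("AGU", ConsensusStructure("*-*"))
        count_training(g, counts, ts, 1.0, "f0")
        # the residue at the skipped column follows the first emission: it
        # fills the first open node's trailing slot
        assert counts.slot["1:trail"][0] == 1.0
        assert counts.slot["lead"][1] == 1.0

    def test_insertion_before_first_emission_uses_lead(self):
        g = grammar_for("-**")
        counts = CountTables.zeros(g)
        ts = make_training_structure("GAU", ConsensusStructure("-**"))
        count_training(g, counts, ts, 1.0, "f0")
        assert counts.slot["lead"][0] == 1.0

    def test_emission_mass_conservation(self, rng):
        from acm.synthetic_fixtures import FixtureSpec, sample_alignment

        spec = FixtureSpec(
            structures={"x": "<<**>>**--", "y": "<<**>>**<>"},
            rows_per_subfamily={"x": 5, "y": 5},
            seed=7,
        )
        aln = sample_alignment(spec)
        masked = prepare_structures(aln)
        trees = [parse_guide_tree(masked[f]) for f in aln.subfamilies]
        forest = merge_forest(trees)
        index_forest(forest)
        g = generate_grammar(forest, aln.n_columns, tuple(aln.subfamilies))
        for fam, _name, row in aln.rows:
            counts = CountTables.zeros(g)
            ts = make_training_structure(row, masked[fam])
            count_training(g, counts, ts, 2.0, fam)
            emitted = sum(float(v.sum()) for v in counts.emission.values())
            # residues at this sub-family's match columns, weighted; pairs
            # count once per two residues
            match_cols = {
                c
                for c, ch in enumerate(masked[fam].columns, start=1)
                if ch in "<>*"
            }
            pair_cols = {c for p in masked[fam].pairs for c in p}
            n_res = sum(
                1 for c in match_cols if row[c - 1] != "-" and c not in pair_cols
            )
            n_pairs = sum(
                1
                for a, b in masked[fam].pairs
                if row[a - 1] != "-" and row[b - 1] != "-"
            )
            n_half = sum(
                1
                for a, b in masked[fam].pairs
                if (row[a - 1] != "-") != (row[b - 1] != "-")
            )
            assert emitted == pytest.approx(2.0 * (n_res + n_pairs + n_half))

    def test_wrong_branch_raises(self):
        g = grammar_for("<>", "**")
        counts = CountTables.zeros(g)
        ts = make_training_structure("AU", ConsensusStructure("<>"))
        with pytest.raises(TrainingError):
            count_training(g, counts, ts, 1.0, "nosuch")


class TestEstimateParams:
    def test_zero_counts_give_normalized_priors(self):
        g = grammar_for("<*>")
        params = estimate_params(CountTables.zeros(g), g)
        for idx in g.nodes:
            roles = g.roles(idx)
            for role in roles:
                assert params.transition[(idx, role)] == pytest.approx(1 / len(roles))
        assert np.allclose(params.emission["un:2"], 0.25)
        assert np.allclose(params.emission["pair:1:3"], 1 / 16)

    def test_single_observation_laplace(self):
        g = grammar_for("*")
        counts = CountTables.zeros(g)
        counts.add_emission("un:1", 0, 1.0)
        params = estimate_params(counts, g)
        assert np.allclose(params.emission["un:1"], [2 / 5, 1 / 5, 1 / 5, 1 / 5])

    def test_background_emission_scores_zero_bits(self):
        g = grammar_for("*")
        params = estimate_params(CountTables.zeros(g), g)
        assert np.allclose(params.emission_bits("un:1"), 0.0)

    def test_zero_prior_zero_counts_raises(self):
        g = grammar_for("*")
        with pytest.raises(TrainingError):
            estimate_params(CountTables.zeros(g), g, Priors(0.0, 0.0, 0.0))


class TestBuildModel:
    def test_built_model_is_normalized(self, fig_family_alignment):
        model = build_model(fig_family_alignment, BuildConfig(seed=1))
        model.params.validate(
            {i: model.grammar.roles(i) for i in model.grammar.nodes}
        )

    def test_incompatible_structures_abort(self, fig_family_alignment):
        fig_family_alignment.structures["purple"] = "<*<*>>**"
        with pytest.raises(TrainingError):
            build_model(fig_family_alignment, BuildConfig(seed=1))

    def test_fork_branch_counts_stay_subfamily_specific(self, trna_model):
        g = trna_model.grammar
        forks = [i for i, n in g.nodes.items() if n.kind == "fork"]
        assert forks
        # branch probabilities reflect the 34/6 sub-family split plus the
        # symmetric transition prior
        idx = forks[0]
        p0 = trna_model.params.transition_prob(idx, "branch_0")
        p1 = trna_model.params.transition_prob(idx, "branch_1")
        assert p0 > p1

    def test_shared_columns_pool_both_subfamilies(self, fig_family_alignment):
        model = build_model(
            fig_family_alignment,
            BuildConfig(seed=1, entropy_weighting=False, weighting="uniform"),
        )
        counts = CountTables.zeros(model.grammar)
        masked = prepare_structures(fig_family_alignment)
        for fam, _n, row in fig_family_alignment.rows:
            ts = make_training_structure(row, masked[fam])
            count_training(model.grammar, counts, ts, 1.0, fam)
        # column 1 pairs column 8 in both sub-families: all five rows count
        assert counts.emission["pair:1:8"].sum() == pytest.approx(5.0)

    def test_forced_derivation_exists_for_every_row(self, trna_alignment, trna_model):
        masked = prepare_structures(trna_alignment)
        for fam, _n, row in trna_alignment.rows:
            ts = make_training_structure(row, masked[fam])
            events = forced_derivation(trna_model.grammar, ts, fam)
            assert any(e[0] == "prod" for e in events)
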