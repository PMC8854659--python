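import math

import numpy as np
import pytest

from oracles import enumeration_log_likelihood

from accelscan.phylo import (LikelihoodEngine, NeutralModel, NewickError,
                             ScaleConfig, SubstitutionModel,
                             column_log_likelihood, element_log_likelihood,
                             parse_newick, prune_to_species, simulate_element,
                             transition_matrix)
from accelscan.synth import make_rev_model, make_tree


# ---------------------------------------------------------------------------
# newick parsing
# ---------------------------------------------------------------------------

class TestParseNewick:
    def test_two_leaves(self):
        tree = parse_newick("(A:0.1,B:0.2);")
        assert sorted(tree.leaf_names) == ["A", "B"]
        assert tree.total_length() == pytest.approx(0.3)

    def test_three_leaves_one_internal(self):
        tree = parse_newick("((A:0.1,B:0.1):0.05,C:0.2);")
        assert tree.n_leaves == 3
        internal = [n for n in tree.postorder()
                    if not n.is_leaf and n is not tree.root]
        assert len(internal) == 1

    @pytest.mark.parametrize("seed", range(100))
    def test_write_parse_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        tree = make_tree(int(rng.integers(4, 15)), seed,
                         depth=rng.uniform(0.2, 2.0))
        again = parse_newick(tree.to_newick())
        assert again.to_newick() == tree.to_newick()
        a = dict(zip(again.leaf_names,
                     [n.length for n in again.leaves]))
        b = dict(zip(tree.leaf_names, [n.length for n in tree.leaves]))
        for name in b:
            assert a[name] == pytest.approx(b[name], abs=1e-9)

    def test_malformed_reports_position(self):
        with pytest.raises(NewickError) as err:
            parse_newick("(A:0.1,B:0.2)")
        assert err.value.position == 13

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            parse_newick("(A:0.1,A:0.2);")

    def test_bad_branch_length(self):
        with pytest.raises(NewickError, match="branch length"):
            parse_newick("(A:zzz,B:0.2);")


# ---------------------------------------------------------------------------
# substitution models and transition matrices
# ---------------------------------------------------------------------------

class TestTransitionMatrix:
    def test_zero_time_is_identity(self, jc):
        assert np.allclose(transition_matrix(jc, 0.0), np.eye(4), atol=1e-12)

    def test_negative_time_rejected(self, jc):
        with pytest.raises(ValueError):
            transition_matrix(jc, -0.1)

    def test_rows_sum_to_one(self):
        model = make_rev_model(7)
        for t in (0.01, 0.3, 2.5):
            p = transition_matrix(model, t)
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
            assert np.all(p >= 0)

    def test_ergodic_limit_is_pi(self):
        model = make_rev_model(3)
        p = transition_matrix(model, 1e3)
        assert np.allclose(p, np.tile(model.freqs, (4, 1)), atol=1e-6)

    def test_jc_closed_form(self, jc):
        # JC69 diagonal: (1 + 3 exp(-4t/3)) / 4
        t = 0.3
        p = transition_matrix(jc, t)
        diag = (1 + 3 * math.exp(-4 * t / 3)) / 4
        off = (1 - math.exp(-4 * t / 3)) / 4
        assert np.allclose(np.diag(p), diag, atol=1e-12)
        assert p[0, 1] == pytest.approx(off, abs=1e-12)

    def test_detailed_balance_enforced(self):
        model = make_rev_model(11)
        model.validate()
        flux = model.freqs[:, None] * model.rate_matrix
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_rate_normalization(self):
        assert make_rev_model(5).expected_rate() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

class TestColumnLikelihood:
    def test_single_leaf_is_log_pi(self):
        subst = make_rev_model(1)
        model = NeutralModel(parse_newick("A;"), subst)
        ll = column_log_likelihood(model, ScaleConfig(), {"A": "G"})
        assert ll == pytest.approx(math.log(subst.freqs[2]))

    def test_zero_branches_identical_leaves(self, jc):
        model = NeutralModel(parse_newick("(A:0.0,B:0.0);"), jc)
        ll = column_log_likelihood(model, ScaleConfig(), {"A": "C", "B": "C"})
        assert ll == pytest.approx(math.log(0.25))

    def test_zero_branches_conflicting_leaves(self, jc):
        model = NeutralModel(parse_newick("(A:0.0,B:0.0);"), jc)
        ll = column_log_likelihood(model, ScaleConfig(), {"A": "C", "B": "T"})
        assert ll == -math.inf

    def test_unknown_leaf_listed(self, jc_model):
        with pytest.raises(ValueError, match="nosuch"):
            column_log_likelihood(jc_model, ScaleConfig(), {"nosuch": "A"})

    def test_bad_symbol_rejected(self, jc_model):
        with pytest.raises(ValueError, match="'X'"):
            column_log_likelihood(jc_model, ScaleConfig(),
                                  {"A": "X", "B": "C", "C": "C", "D": "C"})

    def test_result_nonpositive(self, rev_model_factory):
        model = rev_model_factory(4)
        ll = column_log_likelihood(
            model, ScaleConfig(),
            {name: "A" for name in model.leaf_names})
        assert ll <= 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_with_scaling(self, seed,
                                              rev_model_factory):
        rng = np.random.default_rng(seed + 500)
        model = rev_model_factory(seed, n_leaves=4)
        subtree = frozenset({model.leaf_names[0]})
        column = {name: "ACGT-"[rng.integers(0, 5)]
                  for name in model.leaf_names}
        sc = ScaleConfig(s=float(rng.uniform(0.3, 3.0)),
                         rho=float(rng.uniform(1.0, 8.0)), subtree=subtree)
        got = column_log_likelihood(model, sc, column)
        want = enumeration_log_likelihood(model, column, sc.s, sc.rho,
                                          subtree)
        assert got == pytest.approx(want, abs=1e-10)


class TestElementLikelihood:
    def test_empty_alignment_is_zero(self, jc_model):
        aln = {name: "" for name in jc_model.leaf_names}
        assert element_log_likelihood(jc_model, ScaleConfig(), aln) == 0.0

    def test_rho_one_equals_no_subtree(self, rev_model_factory):
        model = rev_model_factory(9, n_leaves=5)
        aln = simulate_element(model, ScaleConfig(), 40, seed=0)
        plain = element_log_likelihood(model, ScaleConfig(), aln)
        with_sub = element_log_likelihood(
            model, ScaleConfig(rho=1.0,
                               subtree=frozenset({model.leaf_names[0]})), aln)
        assert with_sub == pytest.approx(plain, abs=1e-12)

    def test_additivity_over_columns(self, rev_model_factory):
        model = rev_model_factory(13, n_leaves=5)
        sc = ScaleConfig(s=1.4, rho=3.0,
                         subtree=frozenset({model.leaf_names[1]}))
        aln = simulate_element(model, ScaleConfig(), 25, seed=3)
        total = element_log_likelihood(model, sc, aln)
        per_col = sum(
            column_log_likelihood(model, sc,
                                  {k: v[i] for k, v in aln.items()})
            for i in range(25))
        assert total == pytest.approx(per_col, abs=1e-9)

    def test_ragged_rejected(self, jc_model):
        aln = {"A": "ACGT", "B": "ACG", "C": "ACGT", "D": "ACGT"}
        with pytest.raises(ValueError, match="ragged"):
            element_log_likelihood(jc_model, ScaleConfig(), aln)


class TestPulleyPrinciple:
    """Likelihood is invariant to sliding the root along an edge (REV)."""

    @pytest.mark.parametrize("split", [0.0, 0.05, 0.12, 0.2])
    def test_root_slide_along_internal_edge(self, split):
        subst = make_rev_model(21)
        total = 0.2
        left = (
            f"((A:0.1,B:0.2):{split:.6f},(C:0.3,D:0.4):{total - split:.6f});")
        base = f"((A:0.1,B:0.2):0.1,(C:0.3,D:0.4):{total - 0.1:.6f});"
        column = {"A": "A", "B": "C", "C": "G", "D": "T"}
        ll_a = column_log_likelihood(
            NeutralModel(parse_newick(left), subst), ScaleConfig(), column)
        ll_b = column_log_likelihood(
            NeutralModel(parse_newick(base), subst), ScaleConfig(), column)
        assert ll_a == pytest.approx(ll_b, abs=1e-9)

    def test_reroot_at_leaf_edge(self):
        subst = make_rev_model(22)
        column = {"A": "A", "B": "C", "C": "G"}
        t1 = "((A:0.1,B:0.3):0.05,C:0.2);"
        # same unrooted tree, root placed on A's terminal edge
        t2 = "(A:0.04,(B:0.3,C:0.25):0.06);"
        ll1 = column_log_likelihood(
            NeutralModel(parse_newick(t1), subst), ScaleConfig(), column)
        ll2 = column_log_likelihood(
            NeutralModel(parse_newick(t2), subst), ScaleConfig(), column)
        assert ll1 == pytest.approx(ll2, abs=1e-9)


class TestNormalization:
    @pytest.mark.parametrize("n_leaves", [2, 3, 4])
    def test_column_probabilities_sum_to_one(self, n_leaves,
                                             rev_model_factory):
        model = rev_model_factory(33, n_leaves=n_leaves)
        sc = ScaleConfig(s=1.7, rho=2.5,
                         subtree=frozenset({model.leaf_names[0]}))
        names = model.leaf_names
        total = 0.0
        import itertools
        for bases in itertools.product("ACGT", repeat=n_leaves):
            ll = column_log_likelihood(model, sc, dict(zip(names, bases)))
            total += math.exp(ll)
        assert total == pytest.approx(1.0, abs=1e-8)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

class TestSimulateElement:
    def test_zero_branches_all_identical(self, jc):
        tree = parse_newick("((A:0.0,B:0.0):0.0,C:0.0);")
        model = NeutralModel(tree, jc)
        aln = simulate_element(model, ScaleConfig(), 200, seed=5)
        assert aln["A"] == aln["B"] == aln["C"]

    def test_determinism(self, rev_model_factory):
        model = rev_model_factory(8, n_leaves=6)
        a = simulate_element(model, ScaleConfig(s=2.0), 100, seed=42)
        b = simulate_element(model, ScaleConfig(s=2.0), 100, seed=42)
        assert a == b
        c = simulate_element(model, ScaleConfig(s=2.0), 100, seed=43)
        assert a != c

    def test_distant_leaves_factorize_to_pi(self):
        from scipy.stats import chisquare
        subst = make_rev_model(17)
        model = NeutralModel(parse_newick("(A:8.0,B:8.0);"), subst)
        aln = simulate_element(model, ScaleConfig(), 100_000, seed=11)
        idx = {b: i for i, b in enumerate("ACGT")}
        counts = np.zeros((4, 4))
        for x, y in zip(aln["A"], aln["B"]):
            counts[idx[x], idx[y]] += 1
        expected = np.outer(subst.freqs, subst.freqs) * 100_000
        stat = chisquare(counts.ravel(), expected.ravel())
        assert stat.pvalue > 0.01

    def test_length_validation(self, jc_model):
        with pytest.raises(ValueError):
            simulate_element(jc_model, ScaleConfig(), 0, seed=1)


# ---------------------------------------------------------------------------
# pruning to species subsets
# ---------------------------------------------------------------------------

class TestPruneToSpecies:
    def test_all_leaves_identity(self, jc_model):
        pruned = prune_to_species(jc_model, set(jc_model.leaf_names))
        assert pruned.tree.to_newick() == jc_model.tree.to_newick()

    def test_path_length_addition(self, jc):
        model = NeutralModel(parse_newick("((A:0.1,B:0.1):0.05,C:0.2);"), jc)
        pruned = prune_to_species(model, {"A", "C"})
        lengths = {n.name: n.length for n in pruned.tree.leaves}
        assert lengths == {"A": pytest.approx(0.15), "C": pytest.approx(0.2)}

    def test_empty_intersection_rejected(self, jc_model):
        with pytest.raises(ValueError):
            prune_to_species(jc_model, {"nope"})

    @pytest.mark.parametrize("seed", range(10))
    def test_marginalization_identity(self, seed, rev_model_factory):
        model = rev_model_factory(seed + 40, n_leaves=5)
        names = model.leaf_names
        keep = set(names[:3])
        pruned = prune_to_species(model, keep)
        rng = np.random.default_rng(seed)
        column = {name: "ACGT"[rng.integers(0, 4)] for name in names}
        full = column_log_likelihood(
            model, ScaleConfig(),
            {k: (v if k in keep else "-") for k, v in column.items()})
        small = column_log_likelihood(
            pruned, ScaleConfig(), {k: column[k] for k in keep})
        assert small == pytest.approx(full, abs=1e-10)


class TestScaleConfig:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            ScaleConfig(s=0.0)
        with pytest.raises(ValueError):
            ScaleConfig(rho=0.5)
        with pytest.raises(ValueError):
            ScaleConfig(rho=2.0)  # rho > 1 without a subtree

    def test_subtree_must_be_clade(self, jc_model):
        engine = LikelihoodEngine(jc_model)
        with pytest.raises(ValueError, match="not a clade"):
            engine.subtree_mask({"A", "C"})  # A,C not monophyletic

    def test_subtree_all_leaves_rejected(self, jc_model):
        engine = LikelihoodEngine(jc_model)
        with pytest.raises(ValueError, match="unidentifiable"):
            engine.subtree_mask(set(jc_model.leaf_names))


class TestScaleRecovery:
    def test_global_scale_mle_within_5_percent(self, desk_model):
        from accelscan.accel import fit_null
        engine = LikelihoodEngine(desk_model)
        seqs = engine.simulate(10_000, np.random.default_rng(99), s=0.8)
        _, s_hat = fit_null(engine, seqs)
        assert 0.76 <= s_hat <= 0.84
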