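"""Mk transition probabilities, pruning likelihood and Mkv conditioning."""

from itertools import product

import numpy as np
import pytest
from scipy.linalg import expm

from osteoasr.matrix_io import CharacterMatrix
from osteoasr.mk_likelihood import (
    LikelihoodError,
    MkParameters,
    character_likelihood,
    gamma_category_rates,
    mkv_correct,
    total_log_likelihood,
    transition_matrix,
)
from osteoasr.synthetic_data import simulate_tree
from osteoasr.trees import Tree

from conftest import brute_likelihood, random_tip_states, single_char_matrix


class TestTransitionMatrix:
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_zero_length_is_identity(self, k):
        assert np.allclose(transition_matrix(k, 0.0), np.eye(k))

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_stationary_at_long_branches(self, k):
        P = transition_matrix(k, 1e3)
        assert np.allclose(P, 1.0 / k, atol=1e-12)

    @pytest.mark.parametrize("k,t", [(2, 0.5), (3, 0.17), (4, 1.3)])
    def test_matches_matrix_exponential(self, k, t):
        # generator: off-diagonal 1/(k-1), total rate 1
        Q = np.full((k, k), 1.0 / (k - 1))
        np.fill_diagonal(Q, -1.0)
        assert np.allclose(transition_matrix(k, t), expm(Q * t), atol=1e-12)

    def test_binary_half_branch_value(self):
        assert transition_matrix(2, 0.5)[0, 0] == pytest.approx(0.6839, abs=5e-5)

    @pytest.mark.parametrize("k", [2, 3])
    def test_rows_sum_to_one_and_symmetric(self, k, rng):
        for t in rng.exponential(0.5, size=10):
            P = transition_matrix(k, t)
            assert np.allclose(P.sum(axis=1), 1.0)
            assert np.allclose(P, P.T)

    def test_chapman_kolmogorov(self, rng):
        for k in (2, 3):
            t1, t2 = rng.exponential(0.3, size=2)
            lhs = transition_matrix(k, t1) @ transition_matrix(k, t2)
            assert np.allclose(lhs, transition_matrix(k, t1 + t2), atol=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(LikelihoodError):
            transition_matrix(1, 0.5)
        with pytest.raises(LikelihoodError):
            transition_matrix(2, -0.1)


class TestGammaCategories:
    @pytest.mark.parametrize("alpha", [0.2, 0.5, 1.0, 3.0])
    def test_mean_one(self, alpha):
        for n_cat in (1, 4, 8):
            r = gamma_category_rates(alpha, n_cat)
            assert r.mean() == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(r) >= 0)

    def test_known_four_category_values(self):
        # category means for shape 0.5 (standard discretisation)
        r = gamma_category_rates(0.5, 4)
        assert np.allclose(r, [0.0334, 0.2519, 0.8203, 2.8944], atol=2e-4)


class TestCharacterLikelihood:
    def test_single_tip_is_root_frequency(self):
        t = Tree.from_newick("(A:1.0);")
        m = single_char_matrix({"A": 0})
        assert character_likelihood(t, m, 0) == pytest.approx(0.5)

    def test_two_tip_hand_sum(self):
        t = Tree.from_newick("(A:0.5,B:0.5);")
        m = single_char_matrix({"A": 0, "B": 0})
        P = transition_matrix(2, 0.5)
        expected = 0.5 * (P[0, 0] ** 2 + P[0, 1] ** 2)
        assert character_likelihood(t, m, 0) == pytest.approx(expected, abs=1e-12)

    def test_missing_tip_absent_from_matrix_rejected(self):
        t = Tree.from_newick("(A:0.5,Z:0.5);")
        m = single_char_matrix({"A": 0, "B": 0})
        with pytest.raises(LikelihoodError):
            character_likelihood(t, m, 0)

    def test_pattern_probabilities_sum_to_one(self, rng):
        for k in (2, 3):
            tree = simulate_tree(4, 0.3, rng)
            labs = sorted(tree.tip_labels())
            total = 0.0
            for pat in product(range(k), repeat=4):
                m = single_char_matrix(dict(zip(labs, pat)), k=k)
                total += character_likelihood(tree, m, 0)
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_reroot_invariance(self, rng):
        """Pulley principle: likelihood is a property of the unrooted tree."""
        t1 = Tree.from_newick("((A:0.3,B:0.4):0.2,(C:0.1,D:0.6):0.3);")
        # same unrooted tree, root slid onto the A branch
        t2 = Tree.from_newick("(A:0.1,(B:0.4,(C:0.1,D:0.6):0.5):0.2);")
        m = single_char_matrix({"A": 0, "B": 1, "C": 0, "D": None})
        l1 = character_likelihood(t1, m, 0)
        l2 = character_likelihood(t2, m, 0)
        assert l1 == pytest.approx(l2, rel=1e-12)

    def test_against_exhaustive_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 6))
            k = int(rng.choice([2, 3]))
            tree = simulate_tree(n, 0.4, rng)
            states = random_tip_states(tree, k, rng)
            alpha = float(rng.uniform(0.3, 2.0)) if rng.random() < 0.5 else None
            rates = gamma_category_rates(alpha, 4) if alpha else None
            m = single_char_matrix(states, k=k)
            ours = character_likelihood(tree, m, 0, alpha=alpha)
            oracle = brute_likelihood(tree, states, k, rates)
            assert ours == pytest.approx(oracle, abs=1e-10)


class TestMkv:
    def test_two_tip_symmetric_half(self):
        t = Tree.from_newick("(A:0.7,B:0.7);")
        for pat in ({"A": 0, "B": 1}, {"A": 1, "B": 0}):
            m = single_char_matrix(pat)
            raw = character_likelihood(t, m, 0)
            assert mkv_correct(t, None, 2, raw) == pytest.approx(0.5, abs=1e-12)

    def test_variable_patterns_sum_to_one_four_tips(self, rng):
        tree = simulate_tree(4, 0.25, rng)
        labs = sorted(tree.tip_labels())
        total = 0.0
        for pat in product(range(2), repeat=4):
            if len(set(pat)) == 1:
                continue
            m = single_char_matrix(dict(zip(labs, pat)))
            raw = character_likelihood(tree, m, 0)
            total += mkv_correct(tree, None, 2, raw)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_zero_length_tree_is_degenerate(self):
        t = Tree.from_newick("(A:0.0,B:0.0);")
        m = single_char_matrix({"A": 0, "B": 1})
        raw = character_likelihood(t, m, 0)
        with pytest.raises(LikelihoodError):
            mkv_correct(t, None, 2, raw)


class TestTotalLogLikelihood:
    def test_single_character_equals_character_likelihood(self):
        t = Tree.from_newick("(A:0.5,B:0.5);")
        m = single_char_matrix({"A": 0, "B": 0})
        assert total_log_likelihood(t, m) == pytest.approx(
            np.log(character_likelihood(t, m, 0))
        )

    def test_rate_length_confounding(self, rng):
        """Only the product rate x branch length matters."""
        tree = simulate_tree(5, 0.3, rng)
        states = random_tip_states(tree, 2, rng)
        m = single_char_matrix(states)
        half = tree.copy()
        for node in half.postorder():
            node.length *= 0.5
        l_full = character_likelihood(tree, m, 0, rate=1.0)
        l_half = character_likelihood(half, m, 0, rate=2.0)
        assert l_full == pytest.approx(l_half, rel=1e-12)

    def test_raw_rate_scale_invariance(self, rng):
        """Multipliers are normalised to weighted mean 1, so scaling every
        raw partition rate by a constant cannot change the likelihood."""
        tree = simulate_tree(5, 0.3, rng)
        states = random_tip_states(tree, 2, rng)
        m = CharacterMatrix(
            taxa=sorted(states),
            states=[[None if states[t] is None else
                     (frozenset({states[t]}) if isinstance(states[t], int)
                      else frozenset(states[t]))] * 2 for t in sorted(states)],
            k=[2, 2], character_labels=["a", "b"], partition_of=["pa", "pb"],
        )
        la = total_log_likelihood(
            tree, m, params=MkParameters(partition_rate={"pa": 1.0, "pb": 3.0})
        )
        lb = total_log_likelihood(
            tree, m, params=MkParameters(partition_rate={"pa": 7.0, "pb": 21.0})
        )
        assert la == pytest.approx(lb, rel=1e-10)

    def test_partitioned_matches_per_character_assembly(self, rng):
        from osteoasr.synthetic_data import (
            PartitionSpec,
            SimulationScenario,
            simulate_characters,
        )

        tree = simulate_tree(6, 0.3, rng)
        scen = SimulationScenario(
            tree=tree,
            partitions=[
                PartitionSpec("a", 8, 2, alpha=0.8, variable_only=True),
                PartitionSpec("b", 4, 3, alpha=1.2),
                PartitionSpec("trough", 1, 2),
            ],
            missing_fraction=0.2, seed=9,
        )
        mat, _ = simulate_characters(tree, scen)
        params = MkParameters(
            alpha={"a": 0.8, "b": 1.2}, n_cat=4,
            partition_rate={"a": 1.3, "b": 0.7, "trough": 2.0},
            ascertainment={"a": "variable", "trough": "variable"},
        )
        engine_total = total_log_likelihood(tree, mat, None, params)
        norm = params.normalized_rates(mat.partition_scheme())
        manual = 0.0
        for c in range(mat.n_char):
            pname = mat.partition_of[c]
            al = params.alpha.get(pname)
            L = character_likelihood(tree, mat, c, alpha=al, rate=norm[pname])
            if params.ascertainment.get(pname) == "variable":
                L = mkv_correct(tree, MkParameters(n_cat=4), mat.k[c], L,
                                rate=norm[pname], alpha=al)
            manual += np.log(L)
        assert engine_total == pytest.approx(manual, abs=1e-9)
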