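"""Pruning-algorithm likelihood and ARD maximum-likelihood fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ordevo as ov
from conftest import enumeration_loglik
from ordevo.mk import RATE_KEYS, RATE_CELLS
from ordevo.simulate import TipStates


def _random_chars(tree, rng):
    return TipStates(states={lf.taxon.label: int(rng.integers(1, 5))
                             for lf in tree.leaf_node_iter()})


def test_rate_key_layout_is_row_major():
    cells = list(RATE_CELLS.values())
    assert len(RATE_KEYS) == 12 and len(set(cells)) == 12
    assert cells == [(i, j) for i in range(1, 5) for j in range(1, 5) if i != j]


def test_all_tips_same_state_zero_rates_gives_quarter(five_tip_tree):
    chars = TipStates(states={f"t{i+1}": 2 for i in range(5)})
    ll = ov.log_likelihood(five_tip_tree, chars, np.zeros(12))
    assert ll == pytest.approx(math.log(0.25), abs=1e-12)


@pytest.mark.parametrize("tree_seed", [0, 1, 2])
@pytest.mark.parametrize("n_taxa", [3, 4, 5])
def test_pruning_matches_enumeration_on_small_trees(n_taxa, tree_seed):
    tree = ov.generate_coalescent_tree(n_taxa, rng_seed=tree_seed)
    rng = np.random.default_rng(100 * n_taxa + tree_seed)
    for _ in range(4):
        chars = _random_chars(tree, rng)
        rates = rng.uniform(0, 4, size=12)
        ll = ov.log_likelihood(tree, chars, rates)
        assert ll == pytest.approx(enumeration_loglik(tree, chars, rates),
                                   abs=1e-8)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 5.0), min_size=12, max_size=12))
def test_pruning_matches_enumeration_for_arbitrary_rates(five_tip_tree, rates):
    chars = TipStates(states={"t1": 1, "t2": 2, "t3": 3, "t4": 4, "t5": 2})
    ll = ov.log_likelihood(five_tip_tree, chars, np.array(rates))
    oracle = enumeration_loglik(five_tip_tree, chars, np.array(rates))
    if math.isfinite(oracle) and oracle > -1e11:
        assert ll == pytest.approx(oracle, abs=1e-8)


def test_likelihood_invariant_to_child_order():
    a = ov.read_newick("(t1:1.0,(t2:0.5,t3:0.5):0.5);")
    b = ov.read_newick("((t3:0.5,t2:0.5):0.5,t1:1.0);")
    chars = TipStates(states={"t1": 1, "t2": 3, "t3": 4})
    rates = np.linspace(0.1, 1.2, 12)
    assert ov.log_likelihood(a, chars, rates) == pytest.approx(
        ov.log_likelihood(b, chars, rates), abs=1e-12)


def test_likelihood_rejects_bad_inputs(five_tip_tree):
    chars = TipStates(states={f"t{i+1}": (i % 4) + 1 for i in range(5)})
    with pytest.raises(ValueError):
        ov.log_likelihood(five_tip_tree, chars, np.full(12, -1.0))
    with pytest.raises(ValueError):
        ov.log_likelihood(five_tip_tree, chars.subset(["t1", "t2"]), np.ones(12))


def test_fit_requires_two_distinct_states(five_tip_tree):
    chars = TipStates(states={f"t{i+1}": 1 for i in range(5)})
    with pytest.raises(ValueError):
        ov.fit_ard_model(five_tip_tree, chars)


def test_fitted_likelihood_dominates_generating_rates():
    """The ML optimum is at least as good as the true parameters."""
    tree = ov.generate_coalescent_tree(15, rng_seed=21)
    q = ov.build_q_matrix(True, True, "equal_rates")
    chars = ov.simulate_retained(tree, q, n_keep=2, max_attempts=200, rng_seed=22)[0]
    est = ov.fit_ard_model(tree, chars, ov.FitSettings(seed=23))
    assert est.converged
    truth_ll = ov.log_likelihood(tree, chars, ov.rates_from_q(q))
    assert est.log_likelihood >= truth_ll - 1e-6
    assert np.all(est.rates >= 0) and np.isfinite(est.log_likelihood)


def test_optimum_is_stable_across_restart_seeds():
    tree = ov.generate_coalescent_tree(15, rng_seed=31)
    q = ov.build_q_matrix(False, True, "equal_rates")
    chars = ov.simulate_retained(tree, q, n_keep=1, max_attempts=200, rng_seed=32)[0]
    a = ov.fit_ard_model(tree, chars, ov.FitSettings(seed=1))
    b = ov.fit_ard_model(tree, chars, ov.FitSettings(seed=2))
    assert a.log_likelihood == pytest.approx(b.log_likelihood, abs=1e-4)


def test_nonzero_rates_recovered_within_factor_two():
    """On a large tree the ML estimates of truly nonzero rates are
    consistent; checked on a 1000-taxon tree at reduced replication
    (10 datasets, ordered reversible equal-rates generator)."""
    tree = ov.generate_coalescent_tree(1000, rng_seed=41)
    q = ov.build_q_matrix(True, True, "equal_rates")
    sims = ov.simulate_retained(tree, q, n_keep=10, max_attempts=20, rng_seed=42)
    assert len(sims) >= 8
    fits = [ov.fit_ard_model(tree, chars, ov.FitSettings(seed=43 + i))
            for i, chars in enumerate(sims)]
    fits = [f for f in fits if f.converged]
    truth = ov.rates_from_q(q)
    medians = np.median(np.array([f.rates for f in fits]), axis=0)
    for k, (true_rate, est) in enumerate(zip(truth, medians)):
        if true_rate > 0:
            assert 0.5 * true_rate <= est <= 2.0 * true_rate, RATE_KEYS[k]


def test_rate_estimates_validation():
    with pytest.raises(ValueError):
        ov.RateEstimates(rates=np.ones(11), log_likelihood=0.0, converged=True)
    with pytest.raises(ValueError):
        ov.RateEstimates(rates=np.full(12, -1.0), log_likelihood=0.0, converged=True)
    est = ov.RateEstimates(rates=np.arange(12.0), log_likelihood=-1.0, converged=True)
    assert est["A"] == 0.0 and est["L"] == 11.0
    assert est.as_dict()["C"] == 2.0
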