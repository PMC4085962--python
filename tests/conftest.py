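"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the code paths they check: the
likelihood oracle enumerates all internal-node state assignments with
scipy's matrix exponential, and the Gillespie oracle simulates the full
jump process along a branch instead of sampling branch endpoints.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

import ordevo as ov


@pytest.fixture(scope="session")
def catalog():
    return ov.generating_catalog()


@pytest.fixture(scope="session")
def five_tip_tree():
    return ov.read_newick("((t1:0.3,t2:0.3):0.7,((t3:0.4,t4:0.4):0.2,t5:0.6):0.4);")


def rates_to_q(rates: np.ndarray) -> np.ndarray:
    """4x4 generator from 12 off-diagonal rates in A..L (row-major) order."""
    q = np.zeros((4, 4))
    k = 0
    for i in range(4):
        for j in range(4):
            if i != j:
                q[i, j] = rates[k]
                k += 1
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def enumeration_loglik(tree, chars, rates, root_prior=None) -> float:
    """Brute-force likelihood: sum over every internal-node state
    assignment of the product of branch transition probabilities."""
    prior = np.full(4, 0.25) if root_prior is None else np.asarray(root_prior)
    q = rates_to_q(np.asarray(rates, dtype=float))
    branch_p = {}
    internals = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            branch_p[id(node)] = expm(q * node.edge.length)
        if node.child_nodes():
            internals.append(node)
    total = 0.0
    for assignment in itertools.product(range(4), repeat=len(internals)):
        state = {id(nd): s for nd, s in zip(internals, assignment)}
        for leaf in tree.leaf_node_iter():
            state[id(leaf)] = chars.states[leaf.taxon.label] - 1
        prob = prior[state[id(tree.seed_node)]]
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                prob *= branch_p[id(node)][state[id(node.parent_node)],
                                           state[id(node)]]
        total += prob
    return math.log(total) if total > 0 else -math.inf


def gillespie_endpoint(q: np.ndarray, t_total: float, start: int,
                       rng: np.random.Generator) -> int:
    """Endpoint state (0-based) of one full jump-process realization."""
    s = start
    t = 0.0
    while True:
        rate = -q[s, s]
        if rate <= 0:
            return s
        t += rng.exponential(1.0 / rate)
        if t >= t_total:
            return s
        probs = q[s].copy()
        probs[s] = 0.0
        probs /= probs.sum()
        s = int(rng.choice(4, p=probs))
    return s
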