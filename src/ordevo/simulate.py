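"""Continuous-time Markov simulation of a 4-state trait along a tree.

Character change follows a continuous-time Markov chain with generator
``Q``: over a branch of length ``t`` the transition probabilities are
``P(t) = expm(Q t)``.  Simulation samples branch endpoints directly from
``P(t)`` in a preorder pass from the root (exact marginals; no path
storage), which matches the distribution of event-based (Gillespie)
simulation of the full path.

The study keeps only simulated datasets in which all four states are
realized at the tips; :func:`simulate_retained` applies that retention
rule (by default the first 10 usable datasets out of at most 200
attempts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import expm

from .qmatrices import N_STATES, QMatrix

__all__ = [
    "TipStates",
    "transition_probabilities",
    "branch_probabilities",
    "simulate_tip_states",
    "simulate_retained",
]

logger = logging.getLogger(__name__)

ALL_STATES = frozenset({1, 2, 3, 4})


@dataclass
class TipStates:
    """Simulated tip data: one state in {1,2,3,4} per taxon of one tree."""

    states: dict[str, int]
    tree_id: str = ""
    matrix_label: str = ""
    replicate_index: int = 0
    root_state: int = 1
    rng_seed: int | None = None

    def __post_init__(self):
        bad = {s for s in self.states.values() if s not in ALL_STATES}
        if bad:
            raise ValueError(f"tip states outside 1..4: {sorted(bad)}")

    @property
    def state_set(self) -> frozenset[int]:
        return frozenset(self.states.values())

    def all_states_present(self) -> bool:
        return self.state_set == ALL_STATES

    def subset(self, labels) -> "TipStates":
        """TipStates restricted to ``labels`` (same provenance)."""
        return TipStates(
            states={lab: self.states[lab] for lab in labels},
            tree_id=self.tree_id,
            matrix_label=self.matrix_label,
            replicate_index=self.replicate_index,
            root_state=self.root_state,
            rng_seed=self.rng_seed,
        )


def transition_probabilities(q: QMatrix | np.ndarray, t: float) -> np.ndarray:
    """``P(t) = expm(Q t)`` for branch length ``t`` (>= 0).

    Rows are renormalized after clipping round-off so each is an exact
    probability distribution; rows of an absorbing state come out as the
    corresponding unit vector.
    """
    if t < 0:
        raise ValueError(f"branch length must be >= 0, got {t}")
    rates = q.rates if isinstance(q, QMatrix) else np.asarray(q, dtype=float)
    p = expm(rates * t)
    p = np.clip(p, 0.0, 1.0)
    p /= p.sum(axis=1, keepdims=True)
    return p


def branch_probabilities(
    tree: dendropy.Tree, q: QMatrix | np.ndarray
) -> dict[int, np.ndarray]:
    """Per-branch transition matrices, keyed by ``id(child_node)``.

    Computing these once per (tree, Q) pair amortizes the matrix
    exponentials over repeated simulation attempts.
    """
    probs: dict[int, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            probs[id(node)] = transition_probabilities(q, node.edge.length or 0.0)
    return probs


def simulate_tip_states(
    tree: dendropy.Tree,
    q: QMatrix | np.ndarray,
    root_state: int = 1,
    rng_seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    _branch_probs: dict[int, np.ndarray] | None = None,
    **provenance,
) -> TipStates:
    """Simulate one tip-state dataset on ``tree`` under ``q``.

    The root receives ``root_state``; each descendant's state is drawn
    from the parent-state row of its branch's ``P(t)`` in a fixed
    preorder traversal, so output is reproducible given the seed.
    """
    if root_state not in ALL_STATES:
        raise ValueError(f"root_state must be in 1..4, got {root_state}")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    probs = _branch_probs if _branch_probs is not None else branch_probabilities(tree, q)
    # cumulative rows + inverse-CDF sampling: much cheaper than rng.choice
    cum = {key: np.cumsum(p, axis=1) for key, p in probs.items()}

    state: dict[int, int] = {id(tree.seed_node): root_state - 1}
    tips: dict[str, int] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            row = cum[id(node)][state[id(node.parent_node)]]
            state[id(node)] = min(int(np.searchsorted(row, rng.random(), side="right")),
                                  N_STATES - 1)
        if not node.child_nodes():
            tips[node.taxon.label] = state[id(node)] + 1
    return TipStates(states=tips, root_state=root_state, rng_seed=rng_seed, **provenance)


def simulate_retained(
    tree: dendropy.Tree,
    q: QMatrix | np.ndarray,
    n_keep: int = 10,
    max_attempts: int = 200,
    rng_seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    root_state: int = 1,
    tree_id: str = "",
) -> list[TipStates]:
    """Simulate up to ``max_attempts`` datasets and keep the first
    ``n_keep`` in which all four states appear at the tips.

    Returns fewer than ``n_keep`` datasets (with a logged warning) when
    the attempt budget is exhausted — a reported condition, not an
    error, mirroring that more data must be simulated than used.
    """
    if n_keep > max_attempts:
        raise ValueError("n_keep must not exceed max_attempts")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    label = q.label if isinstance(q, QMatrix) else ""
    probs = branch_probabilities(tree, q)

    kept: list[TipStates] = []
    for attempt in range(max_attempts):
        sim = simulate_tip_states(
            tree,
            q,
            root_state=root_state,
            rng=rng,
            _branch_probs=probs,
            tree_id=tree_id,
            matrix_label=label,
            replicate_index=len(kept),
        )
        if sim.all_states_present():
            kept.append(sim)
            if len(kept) == n_keep:
                break
    if len(kept) < n_keep:
        logger.warning(
            "retained only %d/%d simulations after %d attempts (tree=%s, matrix=%s)",
            len(kept), n_keep, max_attempts, tree_id, label,
        )
    return kept
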