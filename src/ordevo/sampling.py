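"""Random taxon removal for the missing-data sensitivity analysis.

Half of the tips (by default) are removed uniformly at random — blind to
character state — together with their data.  Degree-2 nodes created by
the removal are spliced out with branch lengths summed, so the pruned
tree keeps the original root height and stays ultrametric.  A pruned
dataset is usable only if all four states survive among the remaining
tips; :func:`retain_if_all_states` applies that rule.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np

from .simulate import ALL_STATES, TipStates
from .trees import tip_labels

__all__ = ["prune_random_taxa", "prune_to_labels", "retain_if_all_states"]


def prune_random_taxa(
    tree: dendropy.Tree,
    chars: TipStates,
    fraction: float = 0.5,
    rng_seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[dendropy.Tree, TipStates]:
    """Remove ``floor(fraction * n_taxa)`` random tips and their data.

    Tips are sampled uniformly without replacement, independent of
    state.  Returns a new (tree, TipStates) pair; inputs are untouched.
    Deterministic given the seed.
    """
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    labels = tip_labels(tree)
    missing = set(labels) - set(chars.states)
    if missing or set(chars.states) - set(labels):
        raise ValueError("tip states do not match the tree's taxa")
    n = len(labels)
    n_remove = math.floor(fraction * n)
    if n - n_remove < 2:
        raise ValueError(f"pruning {n_remove} of {n} tips would leave < 2 tips")
    if rng is None:
        rng = np.random.default_rng(rng_seed)
    removed = {labels[i] for i in rng.choice(n, size=n_remove, replace=False)}
    keep = [lab for lab in labels if lab not in removed]
    pruned = prune_to_labels(tree, keep)
    return pruned, chars.subset(keep)


def prune_to_labels(tree: dendropy.Tree, keep: list[str]) -> dendropy.Tree:
    """Copy of ``tree`` restricted to the tips in ``keep``.

    Unifurcations are suppressed by summing branch lengths, except at
    the root, which is retained (possibly with a single child) so that
    root-to-tip depths are unchanged.
    """
    keep_set = set(keep)
    pruned = dendropy.Tree(tree)
    pruned.is_rooted = True
    for leaf in list(pruned.leaf_node_iter()):
        if leaf.taxon.label not in keep_set:
            leaf.parent_node.remove_child(leaf)
    # children-first cleanup: drop emptied internals, splice unifurcations
    for node in list(pruned.postorder_node_iter()):
        parent = node.parent_node
        children = node.child_nodes()
        if not children and node.taxon is None:
            if parent is not None:
                parent.remove_child(node)
        elif len(children) == 1 and parent is not None:
            child = children[0]
            child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
            node.remove_child(child)
            parent.add_child(child)
            parent.remove_child(node)
    return pruned


def retain_if_all_states(chars: TipStates) -> bool:
    """True iff the (pruned) tip states still include all of {1,2,3,4}."""
    return chars.state_set == ALL_STATES
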