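"""Random ultrametric coalescent trees and Newick input/output.

Trees are :class:`dendropy.Tree` objects: rooted, binary, with branch
lengths in coalescent units (one unit = the expected pairwise coalescence
time for a sample of two).  The Kingman coalescent is simulated directly:
starting from ``n`` lineages, the waiting time until the next merger while
``k`` lineages persist is exponential with rate ``k(k-1)/2``, and the pair
that merges is chosen uniformly at random.  The resulting genealogy is
ultrametric by construction, with expected root age ``2(1 - 1/n)``.

Tip labels default to ``t1 .. tN``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np

__all__ = [
    "generate_coalescent_tree",
    "write_newick",
    "read_newick",
    "tip_labels",
    "tree_depth",
    "node_depths",
    "is_ultrametric",
    "validate_tree",
    "NewickParseError",
]

#: relative tolerance used by the ultrametricity check
ULTRAMETRIC_RTOL = 1e-9


class NewickParseError(ValueError):
    """Raised when a Newick string or file cannot be parsed."""


def generate_coalescent_tree(
    n_taxa: int,
    rng_seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    label_template: str = "t{index}",
) -> dendropy.Tree:
    """Simulate a Kingman coalescent genealogy for ``n_taxa`` samples.

    Parameters
    ----------
    n_taxa
        Number of tips; must be at least 2.
    rng_seed
        Seed for a fresh :func:`numpy.random.default_rng` stream.  The
        returned tree is a deterministic function of the seed.
    rng
        Alternatively, an existing generator (takes precedence over
        ``rng_seed``).
    label_template
        Format string for tip labels; receives ``index`` starting at 1.

    Returns
    -------
    dendropy.Tree
        Rooted, binary, ultrametric tree with branch lengths in
        coalescent units.
    """
    if n_taxa < 2:
        raise ValueError(f"n_taxa must be >= 2, got {n_taxa}")
    if rng is None:
        rng = np.random.default_rng(rng_seed)

    namespace = dendropy.TaxonNamespace()
    lineages: list[dendropy.Node] = []
    ages: dict[int, float] = {}
    for i in range(n_taxa):
        taxon = namespace.new_taxon(label=label_template.format(index=i + 1))
        node = dendropy.Node(taxon=taxon)
        ages[id(node)] = 0.0
        lineages.append(node)

    t = 0.0
    k = n_taxa
    while k > 1:
        rate = k * (k - 1) / 2.0
        t += rng.exponential(1.0 / rate)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        ages[id(parent)] = t
        for child in (lineages[i], lineages[j]):
            parent.add_child(child)
            child.edge.length = t - ages[id(child)]
        # replace the two merged lineages by their parent (order-stable)
        lineages = [nd for idx, nd in enumerate(lineages) if idx not in (i, j)]
        lineages.append(parent)
        k -= 1

    tree = dendropy.Tree(taxon_namespace=namespace)
    tree.seed_node = lineages[0]
    tree.is_rooted = True
    return tree


def write_newick(tree: dendropy.Tree, destination) -> None:
    """Write ``tree`` to ``destination`` (path or file object) as Newick.

    Branch lengths are written with 17 significant digits so that a
    write/read round trip preserves them to double precision.
    """
    kwargs = dict(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".17g",
    )
    if hasattr(destination, "write"):
        tree.write(file=destination, **kwargs)
    else:
        tree.write(path=str(destination), **kwargs)


def read_newick(source) -> dendropy.Tree:
    """Read one Newick tree from a path, file object, or literal string.

    Raises
    ------
    NewickParseError
        If the input is not well-formed Newick; the message carries the
        parser's position information.
    """
    try:
        if hasattr(source, "read"):
            tree = dendropy.Tree.get(file=source, schema="newick")
        elif isinstance(source, (str, bytes)) and not Path(str(source)).exists():
            tree = dendropy.Tree.get(data=source, schema="newick")
        else:
            tree = dendropy.Tree.get(path=str(source), schema="newick")
    except Exception as exc:  # dendropy raises several DataError subclasses
        raise NewickParseError(f"malformed Newick input: {exc}") from exc
    tree.is_rooted = True
    return tree


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in (stable) leaf-iteration order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def node_depths(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Root-to-node path length for every node (root depth 0)."""
    depths: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            length = node.edge.length or 0.0
            depths[node] = depths[node.parent_node] + length
    return depths


def tree_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length."""
    depths = node_depths(tree)
    return max(depths[leaf] for leaf in tree.leaf_node_iter())


def is_ultrametric(tree: dendropy.Tree, rtol: float = ULTRAMETRIC_RTOL) -> bool:
    """True iff all root-to-tip path lengths agree within relative ``rtol``."""
    depths = node_depths(tree)
    tip_d = [depths[leaf] for leaf in tree.leaf_node_iter()]
    hi = max(tip_d)
    lo = min(tip_d)
    return hi - lo <= rtol * max(hi, 1e-300)


def validate_tree(tree: dendropy.Tree, *, require_binary: bool = True) -> None:
    """Check the structural invariants of a simulated tree.

    Raises :class:`ValueError` on the first violation: non-unique tip
    labels, missing/negative/non-finite branch lengths, internal nodes of
    the wrong degree, or a non-ultrametric depth profile.
    """
    labels = tip_labels(tree)
    if len(labels) != len(set(labels)):
        raise ValueError("tip labels are not unique")
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            length = node.edge.length
            if length is None or not math.isfinite(length) or length < 0:
                raise ValueError(f"invalid branch length {length!r}")
        n_children = len(node.child_nodes())
        if n_children == 0:
            if node.taxon is None:
                raise ValueError("leaf node without a taxon")
        elif require_binary and n_children != 2 and node.parent_node is not None:
            raise ValueError(f"internal node with {n_children} children")
    if require_binary and len(tree.seed_node.child_nodes()) not in (1, 2):
        raise ValueError("root must have one or two children")
    if not is_ultrametric(tree):
        raise ValueError("tree is not ultrametric")


def internal_node_count(tree: dendropy.Tree) -> int:
    """Number of internal (non-leaf) nodes."""
    return sum(1 for nd in tree.preorder_node_iter() if nd.child_nodes())


def coalescent_intervals(tree: dendropy.Tree) -> dict[int, float]:
    """Duration during which exactly ``k`` lineages existed, per ``k``.

    Computed from internal-node ages; assumes the tree is ultrametric
    with distinct coalescence times (true almost surely for simulated
    trees).
    """
    depths = node_depths(tree)
    depth = tree_depth(tree)
    internal_ages = sorted(
        depth - depths[nd] for nd in tree.preorder_node_iter() if nd.child_nodes()
    )
    n = len(internal_ages) + 1
    intervals: dict[int, float] = {}
    prev = 0.0
    for idx, age in enumerate(internal_ages):
        k = n - idx
        intervals[k] = age - prev
        prev = age
    return intervals


def write_tree_manifest(rows: Iterable[dict], destination) -> None:
    """Write a per-tree manifest TSV (tree_id, n_taxa, seed, depth)."""
    import pandas as pd

    pd.DataFrame(list(rows)).to_csv(destination, sep="\t", index=False)
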