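"""Catalog of 4-state instantaneous rate matrices (Q matrices).

The study simulates a four-state trait along a putative trajectory
``1 -> 2 -> 3 -> 4``.  *Ordered* matrices forbid "skip" transitions
(1->3, 1->4, 2->4 and, symmetrically, 3->1, 4->1, 4->2): those cells are
zero.  *Unordered* matrices allow every transition.  *Non-reversible*
matrices additionally forbid all backward transitions (for ordered
models, j->i with j>i; for unordered models the matrix is upper
triangular), which makes state 4 absorbing.

Allowed cells hold small integers (1-3) that encode relative, not
absolute, rates.  Four rate-pattern classes are crossed with the
ordered/unordered and reversible/non-reversible axes to give the
16-matrix generating catalog:

``equal_rates``
    every allowed transition at rate 1;
``all_rates_different``
    distinct small-integer rates on the allowed cells;
``symmetric_pairs``
    forward and reverse rates equal within each state pair (the
    non-reversible slot of this class uses all allowed rates = 2, a
    rate-2 equal-rates matrix, so all catalog entries stay distinct);
``high_intermediate_exit``
    transitions out of the intermediate states 2 and 3 at rate 3, all
    other allowed transitions at rate 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "QMatrix",
    "PATTERN_CLASSES",
    "build_q_matrix",
    "validate_q",
    "q_violations",
    "generating_catalog",
    "catalog_to_json",
]

N_STATES = 4

PATTERN_CLASSES = (
    "equal_rates",
    "all_rates_different",
    "symmetric_pairs",
    "high_intermediate_exit",
)

# 0-based (row, col) cells, states 1..4 -> indices 0..3
_ORDERED_FORWARD = ((0, 1), (1, 2), (2, 3))
_ORDERED_REVERSE = ((1, 0), (2, 1), (3, 2))
_SKIP_FORWARD = ((0, 2), (0, 3), (1, 3))
_UPPER_TRIANGLE = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
_ALL_OFFDIAG = tuple((i, j) for i in range(4) for j in range(4) if i != j)


@dataclass(frozen=True)
class QMatrix:
    """A 4x4 instantaneous rate matrix with generating-model metadata."""

    rates: np.ndarray
    ordered: bool
    reversible: bool
    pattern_class: str
    label: str

    def __post_init__(self):
        object.__setattr__(self, "rates", np.asarray(self.rates, dtype=float))
        self.rates.setflags(write=False)

    def rate(self, i: int, j: int) -> float:
        """Rate of the ``i -> j`` transition, states numbered 1..4."""
        return float(self.rates[i - 1, j - 1])


def _allowed_cells(ordered: bool, reversible: bool) -> tuple[tuple[int, int], ...]:
    if ordered:
        return _ORDERED_FORWARD + (_ORDERED_REVERSE if reversible else ())
    return _ALL_OFFDIAG if reversible else _UPPER_TRIANGLE


def _assignments(ordered: bool, reversible: bool, pattern_class: str) -> dict:
    cells = _allowed_cells(ordered, reversible)
    if pattern_class == "equal_rates":
        return {c: 1 for c in cells}
    if pattern_class == "all_rates_different":
        if ordered:
            rates = dict(zip(_ORDERED_FORWARD, (1, 2, 3)))
            if reversible:
                rates.update(zip(_ORDERED_REVERSE, (2, 3, 1)))
            return rates
        # unordered: cycle 1,2,3 over the allowed cells in row-major order
        return {c: (k % 3) + 1 for k, c in enumerate(cells)}
    if pattern_class == "symmetric_pairs":
        if not reversible:
            # no reverse cells exist; rate-2 equal-rates keeps the slot distinct
            return {c: 2 for c in cells}
        if ordered:
            pair_rates = {(0, 1): 1, (1, 2): 2, (2, 3): 3}
        else:
            pair_rates = {
                (0, 1): 1, (0, 2): 2, (0, 3): 3,
                (1, 2): 1, (1, 3): 2, (2, 3): 3,
            }
        rates = {}
        for (i, j), r in pair_rates.items():
            rates[(i, j)] = r
            rates[(j, i)] = r
        return rates
    if pattern_class == "high_intermediate_exit":
        # intermediate states 2 and 3 are indices 1 and 2
        return {c: (3 if c[0] in (1, 2) else 1) for c in cells}
    raise ValueError(
        f"unknown pattern_class {pattern_class!r}; expected one of {PATTERN_CLASSES}"
    )


def build_q_matrix(ordered: bool, reversible: bool, pattern_class: str) -> QMatrix:
    """Construct one catalog Q matrix.

    The off-diagonal cells allowed by the ``ordered``/``reversible``
    structure receive the integer rates of ``pattern_class``; every
    diagonal cell is the negated sum of its row's off-diagonal entries,
    so rows sum to zero.  Pure function: identical output on every call.
    """
    q = np.zeros((N_STATES, N_STATES))
    for (i, j), r in _assignments(ordered, reversible, pattern_class).items():
        q[i, j] = r
    np.fill_diagonal(q, -q.sum(axis=1))
    label = "{}_{}_{}".format(
        "ordered" if ordered else "unordered",
        "rev" if reversible else "nonrev",
        pattern_class,
    )
    return QMatrix(q, ordered, reversible, pattern_class, label)


def q_violations(q: QMatrix, atol: float = 1e-12) -> list[str]:
    """List of invariant violations (empty when the matrix is valid)."""
    problems: list[str] = []
    rates = np.asarray(q.rates, dtype=float)
    if rates.shape != (N_STATES, N_STATES):
        return [f"shape {rates.shape} != (4, 4)"]
    for i in range(N_STATES):
        for j in range(N_STATES):
            if i != j and rates[i, j] < 0:
                problems.append(f"negative off-diagonal rate at cell ({i + 1},{j + 1})")
        row_sum = rates[i].sum()
        if abs(row_sum) > atol:
            problems.append(f"row {i + 1} sums to {row_sum:g}, expected 0")
    if q.ordered:
        for i, j in _SKIP_FORWARD:
            if rates[i, j] != 0:
                problems.append(f"ordered matrix has nonzero skip cell ({i + 1},{j + 1})")
        if not q.reversible:
            for i, j in _ORDERED_REVERSE + ((2, 0), (3, 0), (3, 1)):
                if rates[i, j] != 0:
                    problems.append(
                        f"non-reversible ordered matrix has nonzero backward cell "
                        f"({i + 1},{j + 1})"
                    )
    if not q.reversible and np.any(rates[N_STATES - 1] != 0):
        problems.append("non-reversible matrix must have absorbing state 4 (zero row)")
    return problems


def validate_q(q: QMatrix, atol: float = 1e-12) -> bool:
    """True iff ``q`` satisfies all structural invariants."""
    return not q_violations(q, atol=atol)


def generating_catalog() -> list[QMatrix]:
    """The 16 generating matrices: {ordered, unordered} x {reversible,
    non-reversible} x the four rate-pattern classes.  Labels and order
    are stable across runs."""
    catalog = [
        build_q_matrix(ordered, reversible, pattern)
        for ordered in (True, False)
        for reversible in (True, False)
        for pattern in PATTERN_CLASSES
    ]
    for q in catalog:
        assert validate_q(q), q.label
    return catalog


def catalog_to_json(catalog: Iterable[QMatrix] | None = None, indent: int = 2) -> str:
    """Serialize the catalog (label, flags, 4x4 rate array) as JSON."""
    catalog = generating_catalog() if catalog is None else list(catalog)
    payload = [
        {
            "label": q.label,
            "ordered": q.ordered,
            "reversible": q.reversible,
            "pattern_class": q.pattern_class,
            "rates": np.asarray(q.rates).tolist(),
        }
        for q in catalog
    ]
    return json.dumps(payload, indent=indent)
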