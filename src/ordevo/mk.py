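"""Maximum-likelihood inference of all 12 transition rates (ARD model).

Given a tree and tip states, the likelihood of the 4-state
all-rates-different (ARD) Markov model is computed with the Felsenstein
pruning algorithm — tip partials are indicator vectors, internal-node
partials combine the children through each branch's ``P(t) = expm(Qt)``,
and the root sums over states under a flat prior (1/4 per state, the
conventional default; configurable).

:func:`fit_ard_model` maximizes that likelihood over the 12 non-negative
rates with box-constrained L-BFGS-B (bounds ``[0, rate_max]``), restarted
from several jittered log-uniform initial points.  Boundary zeros are
meaningful: a rate estimated at exactly 0 is evidence for a forbidden
transition, which the strictest downstream classification threshold
relies on.

Rates are keyed ``A``..``L`` after the row-major off-diagonal layout of
the estimated-rate table: A:1→2, B:1→3, C:1→4, D:2→1, E:2→3, F:2→4,
G:3→1, H:3→2, I:3→4, J:4→1, K:4→2, L:4→3.  B, C and F are the forward
"skip" cells that an ordered model forbids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize

from ._pruning import ard_loglik
from .qmatrices import N_STATES, QMatrix
from .simulate import ALL_STATES, TipStates

__all__ = [
    "RATE_KEYS",
    "RATE_CELLS",
    "RateEstimates",
    "FitSettings",
    "log_likelihood",
    "fit_ard_model",
    "rates_from_q",
]

#: rate labels in row-major off-diagonal order of the 4x4 matrix
RATE_KEYS = "ABCDEFGHIJKL"

#: 1-based (from_state, to_state) cell for each rate key
RATE_CELLS = {
    "A": (1, 2), "B": (1, 3), "C": (1, 4),
    "D": (2, 1), "E": (2, 3), "F": (2, 4),
    "G": (3, 1), "H": (3, 2), "I": (3, 4),
    "J": (4, 1), "K": (4, 2), "L": (4, 3),
}


@dataclass
class RateEstimates:
    """Twelve estimated transition rates with fit diagnostics."""

    rates: np.ndarray  # (12,) in A..L order, events per unit branch length
    log_likelihood: float
    converged: bool
    n_restarts_used: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape != (12,):
            raise ValueError("expected 12 rates (A..L)")
        if np.any(~np.isfinite(self.rates)) or np.any(self.rates < 0):
            raise ValueError("rates must be finite and >= 0")

    def __getitem__(self, key: str) -> float:
        return float(self.rates[RATE_KEYS.index(key)])

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(RATE_KEYS, self.rates)}


@dataclass(frozen=True)
class FitSettings:
    """Optimizer settings for :func:`fit_ard_model`.

    ``n_restarts`` jittered starts with initial rates drawn log-uniform
    on ``[init_low, init_high]``; rates box-constrained to
    ``[0, rate_max]``; L-BFGS-B stopping at relative function change
    ``ftol`` or projected-gradient norm ``gtol``, at most ``maxfun``
    evaluations per restart.
    """

    n_restarts: int = 5
    rate_max: float = 100.0
    init_low: float = 0.01
    init_high: float = 10.0
    maxfun: int = 2000
    ftol: float = 1e-8
    gtol: float = 1e-8
    seed: int | None = None


def _encode(tree: dendropy.Tree, chars: TipStates):
    """Flatten the tree + data into the arrays the numba kernel expects."""
    nodes = list(tree.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n_nodes = len(nodes)
    tip_state = np.full(n_nodes, -1, dtype=np.int64)
    internal: list[int] = []
    child_ptr = np.zeros(n_nodes + 1, dtype=np.int64)
    child_idx: list[int] = []
    child_blen: list[float] = []
    for i, nd in enumerate(nodes):
        children = nd.child_nodes()
        if children:
            internal.append(i)
            for c in children:
                child_idx.append(index[id(c)])
                length = c.edge.length
                if length is None or length < 0 or not np.isfinite(length):
                    raise ValueError(f"invalid branch length {length!r}")
                child_blen.append(float(length))
        else:
            label = nd.taxon.label
            if label not in chars.states:
                raise ValueError(f"no state for taxon {label!r}")
            s = chars.states[label]
            if s not in ALL_STATES:
                raise ValueError(f"state {s!r} outside 1..4 for taxon {label!r}")
            tip_state[i] = s - 1
        child_ptr[i + 1] = len(child_idx)
    if set(chars.states) - {nd.taxon.label for nd in nodes if not nd.child_nodes()}:
        raise ValueError("tip states include taxa absent from the tree")
    return (
        np.asarray(internal, dtype=np.int64),
        child_ptr,
        np.asarray(child_idx, dtype=np.int64),
        np.asarray(child_blen, dtype=float),
        tip_state,
        n_nodes,
    )


def _as_rate_vector(rates) -> np.ndarray:
    if isinstance(rates, RateEstimates):
        vec = rates.rates
    elif isinstance(rates, dict):
        vec = np.array([rates[k] for k in RATE_KEYS], dtype=float)
    else:
        vec = np.asarray(rates, dtype=float)
    if vec.shape != (12,):
        raise ValueError("expected 12 rates in A..L order")
    if np.any(vec < 0) or np.any(~np.isfinite(vec)):
        raise ValueError("rates must be finite and >= 0")
    return vec


def rates_from_q(q: QMatrix | np.ndarray) -> np.ndarray:
    """The 12 off-diagonal rates of ``q`` in A..L order."""
    m = q.rates if isinstance(q, QMatrix) else np.asarray(q, dtype=float)
    return np.array([m[i, j] for i in range(N_STATES) for j in range(N_STATES) if i != j])


def log_likelihood(
    tree: dendropy.Tree,
    chars: TipStates,
    rates,
    root_prior: np.ndarray | None = None,
) -> float:
    """Pruning-algorithm log-likelihood of ``chars`` on ``tree``.

    ``rates`` may be a length-12 vector in A..L order, a dict keyed by
    rate letter, a :class:`RateEstimates`, or (via
    :func:`rates_from_q`) the off-diagonals of a generating Q matrix.
    """
    vec = _as_rate_vector(rates)
    prior = (np.full(N_STATES, 0.25) if root_prior is None
             else np.asarray(root_prior, dtype=float))
    enc = _encode(tree, chars)
    return float(ard_loglik(vec, *enc, prior))


def fit_ard_model(
    tree: dendropy.Tree,
    chars: TipStates,
    settings: FitSettings | None = None,
    root_prior: np.ndarray | None = None,
    **provenance,
) -> RateEstimates:
    """Maximize the ARD likelihood over the 12 non-negative rates.

    The best optimum across restarts is returned (ties broken by first
    occurrence, so results are deterministic given the settings seed).
    ``converged`` is False when no restart converged — such records are
    flagged for downstream exclusion rather than raising, since sparse
    datasets can defeat the optimizer.
    """
    if settings is None:
        settings = FitSettings()
    if len(set(chars.states.values())) < 2:
        raise ValueError("tip data must contain at least 2 distinct states")
    prior = (np.full(N_STATES, 0.25) if root_prior is None
             else np.asarray(root_prior, dtype=float))
    enc = _encode(tree, chars)

    def negll(x):
        return -ard_loglik(x, *enc, prior)

    rng = np.random.default_rng(settings.seed)
    bounds = [(0.0, settings.rate_max)] * 12
    best = None
    best_ok = False
    for _ in range(settings.n_restarts):
        x0 = np.exp(rng.uniform(np.log(settings.init_low),
                                np.log(settings.init_high), size=12))
        res = minimize(
            negll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxfun": settings.maxfun,
                     "ftol": settings.ftol, "gtol": settings.gtol},
        )
        ok = bool(res.success) and np.isfinite(res.fun)
        # prefer converged restarts; among equals keep the strictly best
        # (first-occurrence tie-break keeps results deterministic)
        if (best is None or (ok and not best_ok)
                or (ok == best_ok and res.fun < best.fun)):
            best, best_ok = res, ok

    assert best is not None
    return RateEstimates(
        rates=np.clip(best.x, 0.0, settings.rate_max),
        log_likelihood=float(-best.fun),
        converged=best_ok,
        n_restarts_used=settings.n_restarts,
        provenance=dict(provenance),
    )
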