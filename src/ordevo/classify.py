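"""Ordered/unordered classification of fitted rate matrices and summaries.

Classification looks only at the forward rates: the three "skip" cells
B (1→3), C (1→4), F (2→4), which an ordered model forbids, judged
against the forward "trajectory" cells A (1→2), E (2→3), I (3→4).
Three thresholds of decreasing stringency:

``strict``
    B, C and F all at zero.  ML estimates sit exactly on the box
    constraint when a rate is inferred to be zero, but a small
    tolerance ``zero_tol`` (default 1e-5) absorbs optimizer round-off;
    it is configurable because the headline proportions are sensitive
    to it (see :func:`sweep_zero_tol`).
``absolute_0.1``
    B, C and F all below 0.1.
``relative_magnitude``
    B, C and F each at least one order of magnitude below the mean of
    A, E and I.

Accuracy is the proportion of ordered-generated datasets classified
ordered; type-I error is the proportion of unordered-generated datasets
classified ordered.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .mk import RATE_KEYS, RateEstimates

__all__ = [
    "THRESHOLDS",
    "DEFAULT_ZERO_TOL",
    "classify_ordered",
    "classify_records",
    "summarize",
    "rate_cell_distributions",
    "sweep_zero_tol",
]

THRESHOLDS = ("strict", "absolute_0.1", "relative_magnitude")
DEFAULT_ZERO_TOL = 1e-5

_SKIP = ("B", "C", "F")
_TRAJECTORY = ("A", "E", "I")


def _get(est, key: str) -> float:
    if isinstance(est, RateEstimates):
        return est[key]
    if isinstance(est, Mapping) or isinstance(est, pd.Series):
        return float(est[key])
    raise TypeError(f"cannot read rate {key!r} from {type(est).__name__}")


def classify_ordered(est, threshold_id: str, zero_tol: float = DEFAULT_ZERO_TOL) -> bool:
    """Apply one threshold rule to a converged fit.

    ``est`` is a :class:`~ordevo.mk.RateEstimates` or any mapping with
    keys A..L (and, if present, ``converged``).  Refuses non-converged
    estimates: the caller must exclude them.
    """
    converged = est.converged if isinstance(est, RateEstimates) else est.get("converged", True)
    if not converged:
        raise ValueError("refusing to classify a non-converged estimate")
    skip = np.array([_get(est, k) for k in _SKIP])
    if threshold_id == "strict":
        return bool(np.all(skip <= zero_tol))
    if threshold_id == "absolute_0.1":
        return bool(np.all(skip < 0.1))
    if threshold_id == "relative_magnitude":
        cutoff = np.mean([_get(est, k) for k in _TRAJECTORY]) / 10.0
        return bool(np.all(skip < cutoff))
    raise ValueError(f"unknown threshold {threshold_id!r}; expected one of {THRESHOLDS}")


_PROVENANCE_COLS = ("tree_size", "tree_id", "matrix_label", "replicate", "regime",
                    "generating_ordered")


def classify_records(estimates: pd.DataFrame,
                     zero_tol: float = DEFAULT_ZERO_TOL) -> pd.DataFrame:
    """Three classification records (one per threshold) per converged fit.

    ``estimates`` is the long results table with columns A..L,
    ``converged`` and the provenance keys; non-converged rows are
    dropped here (they are counted upstream in the run manifest).
    """
    usable = estimates[estimates["converged"]].reset_index(drop=True)
    records = []
    for _, row in usable.iterrows():
        for threshold in THRESHOLDS:
            rec = {k: row[k] for k in _PROVENANCE_COLS if k in row.index}
            rec["threshold"] = threshold
            rec["inferred_ordered"] = classify_ordered(row, threshold, zero_tol)
            records.append(rec)
    columns = [c for c in _PROVENANCE_COLS if c in usable.columns]
    columns += ["threshold", "inferred_ordered"]
    return pd.DataFrame(records, columns=columns)


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Pool classification records into accuracy / type-I proportions.

    One row per (tree_size, threshold, regime): ``n_ordered`` and
    ``accuracy`` (P(called ordered | generated ordered)); ``n_unordered``
    and ``type1_error`` (P(called ordered | generated unordered)).
    Empty cells report NaN with n = 0, never 0/0.
    """
    rows = []
    for (size, threshold, regime), group in records.groupby(
        ["tree_size", "threshold", "regime"], sort=True
    ):
        ordered_gen = group[group["generating_ordered"]]
        unordered_gen = group[~group["generating_ordered"]]
        rows.append({
            "tree_size": size,
            "threshold": threshold,
            "regime": regime,
            "n_ordered": len(ordered_gen),
            "accuracy": (ordered_gen["inferred_ordered"].mean()
                         if len(ordered_gen) else np.nan),
            "n_unordered": len(unordered_gen),
            "type1_error": (unordered_gen["inferred_ordered"].mean()
                            if len(unordered_gen) else np.nan),
        })
    return pd.DataFrame(rows)


def rate_cell_distributions(estimates: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary of each estimated rate cell per generating
    matrix (the per-cell box-plot panel).  Converged fits only."""
    usable = estimates[estimates["converged"]]
    rows = []
    for label, group in usable.groupby("matrix_label", sort=True):
        for cell in RATE_KEYS:
            values = group[cell].to_numpy(dtype=float)
            q = np.percentile(values, [0, 25, 50, 75, 100])
            rows.append({
                "matrix_label": label, "cell": cell, "n": len(values),
                "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
            })
    return pd.DataFrame(rows)


def sweep_zero_tol(estimates: pd.DataFrame,
                   tolerances: Iterable[float] = (1e-8, 1e-7, 1e-6, 1e-5,
                                                  1e-4, 1e-3)) -> pd.DataFrame:
    """Strict-threshold summary at several zero tolerances.

    The strict rule's proportions depend on what "estimated at zero"
    means numerically; this sweep exposes that sensitivity.
    """
    frames = []
    for tol in tolerances:
        recs = classify_records(estimates, zero_tol=tol)
        summ = summarize(recs[recs["threshold"] == "strict"])
        summ.insert(0, "zero_tol", tol)
        frames.append(summ)
    return pd.concat(frames, ignore_index=True)
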