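"""Threshold classification rules and summary tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ordevo as ov
from ordevo.classify import THRESHOLDS, classify_records, sweep_zero_tol
from ordevo.mk import RATE_KEYS


def _est(**rates):
    values = {k: 0.0 for k in RATE_KEYS}
    values.update(rates)
    return ov.RateEstimates(rates=np.array([values[k] for k in RATE_KEYS]),
                            log_likelihood=-1.0, converged=True)


def test_exact_zero_skip_rates_are_ordered_under_all_thresholds():
    est = _est(A=2.0, E=0.5, I=1.0)
    for threshold in THRESHOLDS:
        assert ov.classify_ordered(est, threshold)


def test_small_positive_skip_rates_split_the_thresholds():
    est = _est(B=0.05, C=0.01, F=0.09, A=1.0, E=1.0, I=1.0)
    assert not ov.classify_ordered(est, "strict")
    assert ov.classify_ordered(est, "absolute_0.1")
    assert ov.classify_ordered(est, "relative_magnitude")  # each < 0.1


def test_thresholds_are_not_nested():
    # relative cutoff mean(A,E,I)/10 = 0.03; F = 0.09 fails it
    est = _est(B=0.05, C=0.01, F=0.09, A=0.3, E=0.3, I=0.3)
    assert ov.classify_ordered(est, "absolute_0.1")
    assert not ov.classify_ordered(est, "relative_magnitude")


def test_unknown_threshold_and_nonconverged_are_refused():
    est = _est(A=1.0)
    with pytest.raises(ValueError, match="threshold"):
        ov.classify_ordered(est, "lenient")
    bad = ov.RateEstimates(rates=np.zeros(12), log_likelihood=-1.0, converged=False)
    with pytest.raises(ValueError, match="non-converged"):
        ov.classify_ordered(bad, "strict")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 10.0), min_size=12, max_size=12))
def test_strict_implies_absolute_when_tolerance_below_cutoff(rates):
    est = ov.RateEstimates(rates=np.array(rates), log_likelihood=0.0, converged=True)
    if ov.classify_ordered(est, "strict", zero_tol=1e-5):
        assert ov.classify_ordered(est, "absolute_0.1")


def _records(n_ordered, n_ordered_called, n_unordered=0, n_unordered_called=0):
    rows = []
    for i in range(n_ordered):
        rows.append({"tree_size": 15, "threshold": "strict", "regime": "full",
                     "generating_ordered": True,
                     "inferred_ordered": i < n_ordered_called})
    for i in range(n_unordered):
        rows.append({"tree_size": 15, "threshold": "strict", "regime": "full",
                     "generating_ordered": False,
                     "inferred_ordered": i < n_unordered_called})
    return pd.DataFrame(rows)


def test_summarize_computes_conditional_proportions():
    summary = ov.summarize(_records(10, 6, 5, 1))
    row = summary.iloc[0]
    assert row["n_ordered"] == 10 and row["accuracy"] == pytest.approx(0.6)
    assert row["n_unordered"] == 5 and row["type1_error"] == pytest.approx(0.2)
    assert 0 <= row["accuracy"] <= 1


def test_summarize_reports_empty_cells_as_missing():
    summary = ov.summarize(_records(10, 6))
    row = summary.iloc[0]
    assert row["n_unordered"] == 0
    assert np.isnan(row["type1_error"])


def test_classify_records_excludes_nonconverged_fits():
    base = {k: 0.0 for k in RATE_KEYS}
    estimates = pd.DataFrame([
        {"tree_size": 15, "tree_id": "x", "matrix_label": "m", "replicate": 0,
         "generating_ordered": True, "regime": "full", **base,
         "converged": True},
        {"tree_size": 15, "tree_id": "x", "matrix_label": "m", "replicate": 1,
         "generating_ordered": True, "regime": "full", **base,
         "converged": False},
    ])
    records = classify_records(estimates)
    assert len(records) == len(THRESHOLDS)
    assert set(records["threshold"]) == set(THRESHOLDS)


def test_rate_cell_distributions_five_number_summary():
    rows = []
    for rep, c_val in enumerate([0.0, 0.1, 0.2, 0.3]):
        rates = {k: 0.0 for k in RATE_KEYS}
        rates["C"] = c_val
        rows.append({"matrix_label": "m", "replicate": rep, "converged": True,
                     **rates})
    df = pd.DataFrame(rows)
    dist = ov.rate_cell_distributions(df)
    c_row = dist[dist["cell"] == "C"].iloc[0]
    assert c_row["median"] == pytest.approx(0.15)
    assert c_row["min"] == 0.0 and c_row["max"] == pytest.approx(0.3)
    a_row = dist[dist["cell"] == "A"].iloc[0]
    assert a_row["min"] == a_row["max"] == 0.0
    pd.testing.assert_frame_equal(dist, ov.rate_cell_distributions(df))


def test_sweep_zero_tol_is_monotone_in_tolerance():
    rng = np.random.default_rng(0)
    rows = []
    for rep in range(40):
        rates = {k: float(rng.uniform(0, 2)) for k in RATE_KEYS}
        for k in ("B", "C", "F"):
            rates[k] = float(rng.choice([0.0, 1e-7, 1e-4, 0.5]))
        rows.append({"tree_size": 15, "tree_id": "x", "matrix_label": "m",
                     "replicate": rep, "generating_ordered": True,
                     "regime": "full", "converged": True, **rates})
    sweep = sweep_zero_tol(pd.DataFrame(rows))
    acc = sweep.sort_values("zero_tol")["accuracy"].to_numpy()
    assert np.all(np.diff(acc) >= 0)
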