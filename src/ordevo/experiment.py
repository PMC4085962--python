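"""Orchestration of the full simulation experiment.

For each tree size and each generating model class the pipeline runs
tree simulation → character simulation (with the all-four-states
retention rule) → optional 50% taxon pruning → 12-rate ML inference →
threshold classification, and pools the results into accuracy and
type-I-error summaries.

The full design is 20 trees × 8 matrices × 10 retained replicates per
ordering per tree size (= 1600 expected datasets, fewer retained in
practice), with the pruned regime paired to the full regime — the same
simulated dataset is refit after removing half the taxa, so sampling
effects are estimated within-dataset.  ``n_trees_per_size`` and
``n_keep`` scale the design down for desk runs.

Seeding: every stage derives its stream from the master seed through
``numpy.random.SeedSequence`` spawn keys indexed by design-cell
coordinates, so any single simulation is re-runnable in isolation and
results are independent of execution order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from .mk import RATE_KEYS, FitSettings, fit_ard_model
from .qmatrices import generating_catalog
from .sampling import prune_random_taxa, retain_if_all_states
from .simulate import simulate_retained
from .trees import generate_coalescent_tree, tree_depth, write_newick

__all__ = ["ExperimentConfig", "ExperimentResult", "run_experiment",
           "paired_accuracy_drop"]

logger = logging.getLogger(__name__)

_STAGE_TREE, _STAGE_CHARS, _STAGE_PRUNE, _STAGE_FIT = 0, 1, 2, 3


@dataclass
class ExperimentConfig:
    """Design and numerical settings for one experiment run.

    Defaults reproduce the full study design (20 trees per size, 10
    retained simulations of each of the 8 matrices per ordering, 50%
    pruning everywhere except the 15-taxon group).
    """

    taxon_sizes: tuple[int, ...] = (15, 50, 100, 1000)
    n_trees_per_size: int = 20
    n_keep: int = 10
    max_attempts: int = 200
    orderings: tuple[str, ...] = ("ordered", "unordered")
    prune_fraction: float = 0.5
    prune_exempt_sizes: tuple[int, ...] = (15,)
    run_pruned_regime: bool = True
    root_state: int = 1
    zero_tol: float = _classify.DEFAULT_ZERO_TOL
    fit: FitSettings = field(default_factory=FitSettings)
    master_seed: int = 0
    output_root: str | None = None
    write_trees: bool = False

    def __post_init__(self):
        if self.n_keep > self.max_attempts:
            raise ValueError("n_keep must not exceed max_attempts")
        valid = {"ordered", "unordered"}
        if not set(self.orderings) <= valid or not self.orderings:
            raise ValueError(f"orderings must be a non-empty subset of {valid}")

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        payload = json.loads(Path(path).read_text())
        if "fit" in payload:
            payload["fit"] = FitSettings(**payload["fit"])
        for key in ("taxon_sizes", "orderings", "prune_exempt_sizes"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class ExperimentResult:
    """All tables produced by one run, plus the reproducibility manifest."""

    estimates: pd.DataFrame
    records: pd.DataFrame
    summary: pd.DataFrame
    manifest: dict
    config: ExperimentConfig

    def save(self, output_root) -> None:
        root = Path(output_root)
        root.mkdir(parents=True, exist_ok=True)
        self.estimates.to_csv(root / "estimates.csv", index=False)
        self.records.to_csv(root / "records.csv", index=False)
        self.summary.to_csv(root / "summary.csv", index=False)
        manifest = dict(self.manifest)
        manifest["config"] = asdict(self.config)
        (root / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=key))


def _seed_int(master_seed: int, *key: int) -> int:
    return int(np.random.SeedSequence(master_seed, spawn_key=key)
               .generate_state(1, dtype=np.uint32)[0]) % (2**31)


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run every design cell and pool the results.

    Partial failures (retention shortfalls, pruned datasets losing a
    state, non-converged fits) are logged and counted in the manifest,
    never silently skipped.
    """
    if config.output_root is not None:
        root = Path(config.output_root)
        root.mkdir(parents=True, exist_ok=True)
        if not root.is_dir():
            raise OSError(f"unwritable output root {root}")

    catalog = generating_catalog()
    rows: list[dict] = []
    tree_manifest: list[dict] = []
    counters = {
        "attempted_datasets": 0,
        "retained_datasets": 0,
        "retention_shortfall": 0,
        "pruned_missing_state": 0,
        "nonconverged_full": 0,
        "nonconverged_pruned": 0,
    }

    for size in config.taxon_sizes:
        for ordering in config.orderings:
            ordered_gen = ordering == "ordered"
            matrices = [m for m in catalog if m.ordered == ordered_gen]
            for tree_idx in range(config.n_trees_per_size):
                tree_key = (size, int(ordered_gen), tree_idx)
                tree = generate_coalescent_tree(
                    size, rng=_rng(config.master_seed, _STAGE_TREE, *tree_key))
                tree_id = f"n{size}_{ordering}_{tree_idx:03d}"
                tree_manifest.append({
                    "tree_id": tree_id, "n_taxa": size,
                    "depth": tree_depth(tree),
                })
                if config.output_root and config.write_trees:
                    tdir = Path(config.output_root) / "trees"
                    tdir.mkdir(exist_ok=True)
                    write_newick(tree, tdir / f"{tree_id}.nwk")
                prune_here = (config.run_pruned_regime
                              and size not in config.prune_exempt_sizes)
                for m_idx, matrix in enumerate(matrices):
                    sims = simulate_retained(
                        tree, matrix,
                        n_keep=config.n_keep,
                        max_attempts=config.max_attempts,
                        rng=_rng(config.master_seed, _STAGE_CHARS, *tree_key, m_idx),
                        root_state=config.root_state,
                        tree_id=tree_id,
                    )
                    counters["attempted_datasets"] += config.n_keep
                    counters["retained_datasets"] += len(sims)
                    counters["retention_shortfall"] += config.n_keep - len(sims)
                    for rep, chars in enumerate(sims):
                        cell_key = tree_key + (m_idx, rep)
                        prov = {
                            "tree_size": size, "tree_id": tree_id,
                            "matrix_label": matrix.label, "replicate": rep,
                            "generating_ordered": ordered_gen,
                        }
                        fit_seed = _seed_int(config.master_seed, _STAGE_FIT,
                                             *cell_key, 0)
                        est = fit_ard_model(
                            tree, chars,
                            settings=FitSettings(
                                **{**asdict(config.fit), "seed": fit_seed}),
                        )
                        if not est.converged:
                            counters["nonconverged_full"] += 1
                        rows.append({**prov, "regime": "full",
                                     **est.as_dict(),
                                     "logLik": est.log_likelihood,
                                     "converged": est.converged,
                                     "n_restarts": est.n_restarts_used})
                        if not prune_here:
                            continue
                        ptree, pchars = prune_random_taxa(
                            tree, chars, config.prune_fraction,
                            rng=_rng(config.master_seed, _STAGE_PRUNE, *cell_key),
                        )
                        if not retain_if_all_states(pchars):
                            counters["pruned_missing_state"] += 1
                            continue
                        pfit_seed = _seed_int(config.master_seed, _STAGE_FIT,
                                              *cell_key, 1)
                        pest = fit_ard_model(
                            ptree, pchars,
                            settings=FitSettings(
                                **{**asdict(config.fit), "seed": pfit_seed}),
                        )
                        if not pest.converged:
                            counters["nonconverged_pruned"] += 1
                        rows.append({**prov, "regime": "pruned",
                                     **pest.as_dict(),
                                     "logLik": pest.log_likelihood,
                                     "converged": pest.converged,
                                     "n_restarts": pest.n_restarts_used})

    columns = ["tree_size", "tree_id", "matrix_label", "replicate",
               "generating_ordered", "regime", *RATE_KEYS,
               "logLik", "converged", "n_restarts"]
    estimates = pd.DataFrame(rows, columns=columns)
    records = _classify.classify_records(estimates, zero_tol=config.zero_tol)
    summary = _classify.summarize(records)
    n_regimes = estimates["regime"].nunique() if len(estimates) else 0
    manifest = {
        "master_seed": config.master_seed,
        "counters": counters,
        "trees": tree_manifest,
        "n_estimates": len(estimates),
        "n_records": len(records),
        "n_regimes": n_regimes,
    }
    # every converged fit yields exactly one record per threshold
    expected = int(estimates["converged"].sum()) * len(_classify.THRESHOLDS)
    if len(records) != expected:
        raise RuntimeError(
            f"record bookkeeping mismatch: {len(records)} != {expected}")
    logger.info("run complete: %s", counters)

    result = ExperimentResult(estimates, records, summary, manifest, config)
    if config.output_root is not None:
        result.save(config.output_root)
    return result


def paired_accuracy_drop(summary: pd.DataFrame) -> pd.Series:
    """Per-size accuracy loss from 50% taxon removal, in percentage
    points, averaged over the three thresholds.

    ``summary`` must contain paired ``full`` and ``pruned`` rows from
    the same run; sizes lacking either regime are omitted.
    """
    full = summary[summary["regime"] == "full"].set_index(["tree_size", "threshold"])
    pruned = summary[summary["regime"] == "pruned"].set_index(["tree_size", "threshold"])
    common = full.index.intersection(pruned.index)
    if len(common) == 0:
        raise ValueError("summaries share no (tree_size, threshold) cells")
    diff = (full.loc[common, "accuracy"] - pruned.loc[common, "accuracy"]) * 100.0
    return diff.groupby(level="tree_size").mean()
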