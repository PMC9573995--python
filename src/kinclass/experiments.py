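"""Result-generating experiments: robustness curves, grids, baselines.

This module drives the package end to end: simulate balanced pair datasets on
a grid of genotyping error rates (GERs), extract the 17 relatedness features,
run per-GER forward selection and cross-GER consensus to fix one final feature
set per task, and measure accuracies against the single-feature K1 baselines.
Two further studies probe robustness: a train-GER x test-GER accuracy grid
(does matching the training error rate to the test error rate help?) and a
marker-deletion study (how little of the SNP panel suffices?).

The classical KING decision rules are included as baselines: kinship
thresholds at powers of two for degree assignment, and the IBS0 cutoff for
separating parent-child from full siblings within the 1st degree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, extract_features
from .hierarchy import RandomForestBackend, SVMBackend, task_xy
from .io import RunConfig, write_seeds, write_table
from .selection import SelectionTrace, choose_final_set, consensus_rank, cv_accuracy, forward_select
from .simulate import TYPES_BY_DEGREE, PairDataset, build_pair_dataset

logger = logging.getLogger("kinclass")

# KING kinship bin edges: 2**-1.5, 2**-2.5, 2**-3.5, 2**-4.5
_K1_EDGES = (2 ** -1.5, 2 ** -2.5, 2 ** -3.5, 2 ** -4.5)

#: per-GER selected-set size cap when counting (the degree task plateaus at 7)
DEGREE_SET_CAP = 7

#: the robust degree feature set identified by cross-error consensus selection
FINAL_DEGREE_FEATURES = ("K1", "j4", "j7", "K0", "IBS0", "j6", "j8")

TASK_TYPES = {
    "degree": None,  # all pairs
    "deg1": list(TYPES_BY_DEGREE[1]),
    "deg2": list(TYPES_BY_DEGREE[2]),
    "deg3": list(TYPES_BY_DEGREE[3]),
}


def k1_threshold_degree(k1, map_duplicate_to_first: bool = True):
    """Degree call from K1 alone via the KING power-of-two kinship bins.

    Bins are right-closed: K1 in (2**-2.5, 2**-1.5] is 1st degree, down to
    K1 <= 2**-4.5 for unrelated.  K1 above 2**-1.5 indicates a duplicate or
    monozygotic twin; this study has no such class, so it is mapped to 1st
    degree for 4-class scoring (configurable).
    """
    k1 = np.asarray(k1, dtype=float)
    out = np.zeros(k1.shape, dtype=int)
    out[k1 > _K1_EDGES[3]] = 3
    out[k1 > _K1_EDGES[2]] = 2
    out[k1 > _K1_EDGES[1]] = 1
    dup = k1 > _K1_EDGES[0]
    out[dup] = 1 if map_duplicate_to_first else -1
    if dup.any():
        logger.info("%d pairs above the duplicate threshold 2**-1.5", int(dup.sum()))
    return out if out.ndim else int(out)


def k1_ibs0_first_degree_rule(k1, ibs0, tau_ibs0: float = 0.005):
    """Classic 1st-degree disambiguation: parent-child iff IBS0 < tau.

    Parent-child pairs share an allele at every locus, so opposite homozygotes
    arise only from genotyping error; full siblings show IBS0 well above zero.
    """
    ibs0 = np.asarray(ibs0, dtype=float)
    out = np.where(ibs0 < tau_ibs0, "parent-child", "full-sibling")
    return out if out.ndim else str(out)


# ---------------------------------------------------------------------------
# Shared plumbing
# ---------------------------------------------------------------------------


def family_index(table: pd.DataFrame) -> np.ndarray:
    """Family index of each pair row, recovered from the pair_id suffix."""
    return table["pair_id"].str.rsplit("-", n=1).str[-1].astype(int).to_numpy()


def selection_backend(config: RunConfig) -> RandomForestBackend:
    """The lighter forest used inside the greedy selection wrapper."""
    return RandomForestBackend(n_estimators=config.selection_trees)


def final_backend(config: RunConfig):
    if config.backend == "rf":
        return RandomForestBackend(n_estimators=config.rf_trees)
    if config.backend == "svm":
        return SVMBackend(C=config.svm_c)
    raise ValueError(f"unknown backend {config.backend!r}")


def features_by_ger(
    base: PairDataset, gers, seed: int, pair_types: list[str] | None = None
) -> dict[float, pd.DataFrame]:
    """Feature tables for an error-free dataset corrupted at each GER.

    The error-free genotypes are simulated once; each GER level receives an
    independent error stream derived from ``seed``.
    """
    if base.ger != 0.0:
        raise ValueError("base dataset must be error-free")
    if pair_types is not None:
        base = base.subset(pair_types)
    tables = {}
    for i, ger in enumerate(gers):
        ds = base if ger == 0.0 else base.with_error(ger, seed=seed + i)
        tables[float(ger)] = extract_features(ds)
    return tables


def select_and_rank(
    tables_by_ger: dict[float, pd.DataFrame],
    task: str,
    config: RunConfig,
    seed: int,
    max_steps: int | None = None,
) -> tuple[list[SelectionTrace], "pd.DataFrame"]:
    """Per-GER forward selection for one task on the selection subsample."""
    backend = selection_backend(config)
    traces = []
    for ger, table in sorted(tables_by_ger.items()):
        fam = family_index(table)
        sub = table[fam < config.selection_families]
        X, y = task_xy(sub, task)
        trace = forward_select(
            X, y, backend, k_folds=config.selection_folds,
            max_steps=max_steps or config.max_steps, seed=seed,
        )
        trace.ger = ger
        traces.append(trace)
    curves = pd.concat(
        [t.to_frame().assign(ger=t.ger, task=task) for t in traces], ignore_index=True
    )
    return traces, curves


def consensus_final_set(
    traces: list[SelectionTrace],
    tables_by_ger: dict[float, pd.DataFrame],
    task: str,
    config: RunConfig,
    seed: int,
    set_cap: int | None = None,
    final_k: int | None = None,
):
    """Consensus ranking across GERs and the final feature set for one task.

    ``set_cap`` caps each GER's counted prefix; ``final_k`` forces the final
    set size instead of picking the mean-accuracy-maximizing prefix.
    """
    sizes = None
    if set_cap is not None:
        sizes = [len(t.best_prefix(cap=set_cap)) for t in traces]
    ranking = consensus_rank(traces, set_sizes=sizes)
    if final_k is not None:
        return ranking, ranking.ranking[:final_k], None
    X_by, y_by = {}, {}
    for ger, table in tables_by_ger.items():
        fam = family_index(table)
        sub = table[fam < config.selection_families]
        X_by[ger], y_by[ger] = task_xy(sub, task)
    final, curve = choose_final_set(
        ranking, X_by, y_by, selection_backend(config),
        k_folds=config.selection_folds, seed=seed,
    )
    return ranking, final, curve


# ---------------------------------------------------------------------------
# Train-GER x test-GER grid
# ---------------------------------------------------------------------------


@dataclass
class ExperimentGrid:
    """Accuracy matrix over training and test GERs for one task."""

    task: str
    train_gers: tuple[float, ...]
    test_gers: tuple[float, ...]
    accuracy: np.ndarray  # (replicates, train, test)
    seeds: list[int]

    def __post_init__(self) -> None:
        r, t, u = self.accuracy.shape
        if t != len(self.train_gers) or u != len(self.test_gers):
            raise ValueError("accuracy matrix shape does not match GER lists")
        if np.any((self.accuracy < 0) | (self.accuracy > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean(self) -> np.ndarray:
        return self.accuracy.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, gt in enumerate(self.train_gers):
            for j, ge in enumerate(self.test_gers):
                rows.append(
                    {
                        "task": self.task,
                        "ger_train": gt,
                        "ger_test": ge,
                        "accuracy": self.mean[i, j],
                        "sd": self.accuracy[:, i, j].std(ddof=1) if len(self.seeds) > 1 else 0.0,
                    }
                )
        return pd.DataFrame(rows)


def ger_grid_experiment(
    tasks,
    train_gers,
    test_gers,
    config: RunConfig,
    feature_sets: dict[str, list[str]],
    n_families: int | None = None,
) -> dict[str, ExperimentGrid]:
    """Train at each GER, test at each GER, on independent simulated datasets.

    Per replicate, one error-free training cohort and one independent test
    cohort are simulated; each GER level corrupts the respective cohort with a
    fresh error stream.  One corrupted test set per test GER is shared across
    the training GERs of the same replicate.
    """
    n_fam = n_families or config.n_families
    backend = final_backend(config)
    reps = config.grid_replicates
    rep_seeds = [config.stage_seed("grid", r) for r in range(reps)]
    acc = {task: np.zeros((reps, len(train_gers), len(test_gers))) for task in tasks}
    for r, rseed in enumerate(rep_seeds):
        train_base = build_pair_dataset(n_fam, 0.0, config.n_loci, seed=rseed)
        test_base = build_pair_dataset(n_fam, 0.0, config.n_loci, seed=rseed + 1)
        for task in tasks:
            types = TASK_TYPES[task]
            train_tabs = features_by_ger(train_base, train_gers, seed=rseed + 2, pair_types=types)
            test_tabs = features_by_ger(test_base, test_gers, seed=rseed + 3, pair_types=types)
            feats = feature_sets[task]
            for i, gt in enumerate(train_gers):
                X, y = task_xy(train_tabs[float(gt)], task)
                model = backend.with_seed(rseed).make()
                model.fit(X[feats].to_numpy(), y)
                for j, ge in enumerate(test_gers):
                    Xt, yt = task_xy(test_tabs[float(ge)], task)
                    acc[task][r, i, j] = np.mean(model.predict(Xt[feats].to_numpy()) == yt)
    return {
        task: ExperimentGrid(
            task=task,
            train_gers=tuple(train_gers),
            test_gers=tuple(test_gers),
            accuracy=acc[task],
            seeds=rep_seeds,
        )
        for task in tasks
    }


# ---------------------------------------------------------------------------
# Missing-data study
# ---------------------------------------------------------------------------


def missing_data_experiment(
    config: RunConfig,
    degree_features: list[str],
    deletion_rates=None,
    gers=None,
    n_runs: int | None = None,
    base: PairDataset | None = None,
) -> pd.DataFrame:
    """Mean degree-task accuracy over random SNP deletions.

    For every (GER, deletion rate, run) the error-free cohort is corrupted,
    a random locus subset is deleted, features are re-extracted and the
    degree task is cross-validated with both the final feature set and the
    K1-only baseline.  Returns mean and SD over runs.
    """
    rates = tuple(deletion_rates if deletion_rates is not None else config.deletion_rates)
    gers = tuple(gers if gers is not None else (0.0, 0.1))
    n_runs = n_runs or config.missing_runs
    backend = final_backend(config)
    if base is None:
        base = build_pair_dataset(
            config.n_families, 0.0, config.n_loci, seed=config.stage_seed("missing-sim")
        )
    rows = []
    for ger in gers:
        ds_ger = base if ger == 0.0 else base.with_error(ger, seed=config.stage_seed("missing-err"))
        for rate in rates:
            accs = {"final": [], "K1": []}
            for run in range(n_runs):
                dseed = config.stage_seed("missing-del", run)
                ds = ds_ger if rate == 0.0 else ds_ger.delete_snps(rate, seed=dseed + run)
                table = extract_features(ds)
                X, y = task_xy(table, "degree")
                accs["final"].append(
                    cv_accuracy(X, y, degree_features, backend, config.k_folds, seed=dseed)
                )
                accs["K1"].append(
                    cv_accuracy(X, y, ["K1"], backend, config.k_folds, seed=dseed)
                )
                if rate == 0.0:
                    break  # no randomness to average over
            for name, vals in accs.items():
                rows.append(
                    {
                        "ger": ger,
                        "deletion_rate": rate,
                        "feature_set": name,
                        "accuracy": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                        "n_runs": len(vals),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full replication
# ---------------------------------------------------------------------------


def run_replication(config: RunConfig, out_dir=None, run_grid: bool = True, run_missing: bool = True) -> dict:
    """End-to-end replication: simulate, select, classify, grid, missing data.

    Writes the report directory (selection traces, consensus rankings, final
    accuracies per GER, grid and missing-data tables, resolved config and
    seeds) and returns the in-memory results.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {
        "master": config.seed,
        "simulate": config.stage_seed("simulate"),
        "error": config.stage_seed("error"),
        "select": config.stage_seed("select"),
        "cv": config.stage_seed("cv"),
    }
    logger.info("simulating %d families x %d loci", config.n_families, config.n_loci)
    base = build_pair_dataset(
        config.n_families, 0.0, config.n_loci, seed=seeds["simulate"]
    )
    tables = features_by_ger(base, config.gers, seed=seeds["error"])

    traces_all, rankings, final_sets = {}, {}, {}
    curve_frames, trace_frames = [], []
    for task in TASK_TYPES:
        traces, curves = select_and_rank(tables, task, config, seeds["select"])
        traces_all[task] = traces
        trace_frames.append(curves)
        cap = DEGREE_SET_CAP if task == "degree" else None
        ranking, final, curve = consensus_final_set(
            traces, tables, task, config, seeds["select"], set_cap=cap
        )
        rankings[task] = ranking
        final_sets[task] = final
        if curve is not None:
            curve_frames.append(curve.assign(task=task))
        logger.info("task %s final feature set: %s", task, final)

    backend = final_backend(config)
    acc_rows = []
    for task in TASK_TYPES:
        for ger, table in sorted(tables.items()):
            X, y = task_xy(table, task)
            for name, feats in (("final", final_sets[task]), ("K1", ["K1"])):
                acc_rows.append(
                    {
                        "task": task,
                        "ger": ger,
                        "feature_set": name,
                        "n_features": len(feats),
                        "accuracy": cv_accuracy(
                            X, y, feats, backend, config.k_folds, seed=seeds["cv"]
                        ),
                    }
                )
    accuracy_by_ger = pd.DataFrame(acc_rows)

    results: dict = {
        "final_sets": final_sets,
        "rankings": rankings,
        "accuracy_by_ger": accuracy_by_ger,
    }

    traces_dir = out / "selection_traces"
    traces_dir.mkdir(exist_ok=True)
    for frame in trace_frames:
        task = frame["task"].iloc[0]
        write_table(frame, traces_dir / f"trace_{task}.csv")
    write_table(
        pd.concat(
            [rankings[t].to_frame().assign(task=t) for t in rankings], ignore_index=True
        ),
        out / "consensus_ranking.csv",
    )
    write_table(accuracy_by_ger, out / "accuracy_by_ger.csv")
    if curve_frames:
        write_table(pd.concat(curve_frames, ignore_index=True), out / "consensus_curves.csv")

    if run_grid:
        grids = ger_grid_experiment(
            ("deg1", "deg2", "deg3"),
            config.gers,
            config.gers,
            config,
            final_sets,
            n_families=min(config.n_families, config.selection_families * 2),
        )
        results["grids"] = grids
        for task, grid in grids.items():
            write_table(grid.to_frame(), out / f"grid_{task}.csv")
    if run_missing:
        missing = missing_data_experiment(config, final_sets["degree"], base=base)
        results["missing_data"] = missing
        write_table(missing, out / "missing_data.csv")

    config.to_yaml(out / "config_resolved.yaml")
    write_seeds(seeds, out / "seeds.json")
    return results
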