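"""End-to-end experiment skeleton tying the modules together.

``train_source_models`` fits every (source, classifier) pair on the
balanced incomplete-data pools; ``run_experiment`` evaluates the full
ensemble grid on the common complete-data test set; ``recovery_harness``
repeats the whole comparison (ensembles + CDL/IDL feature selection) over
seeds and tabulates accuracies and support-recovery Jaccard indices.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import classifiers as clf
from . import ensembles as ens
from .cohort import MultiSourceCohort, Partition, split_train_test
from .featsel import complete_dataset_learning, incomplete_dataset_learning
from .simulate import GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["train_source_models", "source_frames", "run_experiment", "recovery_harness", "jaccard"]


def source_frames(cohort: MultiSourceCohort, ids: Sequence[str], source: str) -> pd.DataFrame:
    """Design matrix of one source for the given subjects (rows = subjects)."""
    idx = {s.id: s for s in cohort.subjects}
    rows = [idx[i].source_data[source] for i in ids]
    return pd.DataFrame(
        np.asarray(rows, dtype=float), index=list(ids), columns=list(cohort.spec.feature_names[source])
    )


def train_source_models(
    cohort: MultiSourceCohort,
    partition: Partition,
    kinds: Sequence[str] = ("lr", "rf"),
    seed: int = 0,
    **fit_kwargs,
) -> dict[tuple[str, str], clf.TrainedModel]:
    """Fit one model per (source, classifier kind) on that source's balanced
    incomplete-data pool.  Sources with an empty pool or a single class are
    skipped with a log entry (their ensemble pool is simply smaller)."""
    labels = cohort.labels
    models: dict[tuple[str, str], clf.TrainedModel] = {}
    for src in cohort.spec.names:
        ids = partition.train_by_source.get(src, [])
        labs = {i: labels[i] for i in ids}
        if not ids or len(set(labs.values())) < 2:
            logger.warning("skipping source %r: unusable training pool (n=%d)", src, len(ids))
            continue
        balanced = clf.balance_classes(ids, labs, seed)
        X = source_frames(cohort, balanced, src)
        y = np.array([labels[i] for i in balanced])
        for kind in kinds:
            m = clf.fit_classifier(kind, X.to_numpy(dtype=float), y, seed=seed, **fit_kwargs)
            m.source, m.kind = src, kind if isinstance(kind, str) else getattr(kind, "__name__", "plugin")
            m.feature_names = list(X.columns)
            models[(src, m.kind)] = m
    return models


def run_experiment(
    cohort: MultiSourceCohort,
    partition: Partition | None = None,
    kinds: Sequence[str] = ("lr", "rf"),
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Train all source models and evaluate the full ensemble grid on the
    complete-data test set."""
    partition = partition or split_train_test(cohort)
    if not partition.test_ids:
        raise ValueError("no complete-data subjects: nothing to test against")
    models = train_source_models(cohort, partition, kinds, seed, **fit_kwargs)
    test_X = {src: source_frames(cohort, partition.test_ids, src) for src in cohort.spec.names}
    labels = cohort.labels
    return ens.run_ensemble_grid(models, test_X, labels)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard index of two index sets; 1.0 if both are empty."""
    sa, sb = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def recovery_harness(
    config: GeneratorConfig,
    n_seeds: int = 50,
    n_lambda: int = 4,
    rf_trees: int = 100,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Run ensembles, CDL and IDL end-to-end on fresh cohorts.

    One row per seed: the best individual-source test accuracy, the combined
    (all classifiers x all sources) ensemble accuracies under both fusion
    rules, the CDL/IDL downstream CV accuracies, and the Jaccard overlap of
    each method's selected support with the planted informative features.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    rows = []
    for s in range(n_seeds):
        cfg = replace(config, seed=base_seed + s)
        cohort, truth = generate_cohort(cfg)
        partition = split_train_test(cohort)
        if not partition.test_ids:
            logger.warning("seed %d: no complete subjects, skipping", cfg.seed)
            continue
        grid = run_experiment(
            cohort, partition, kinds=("lr", "rf"), seed=cfg.seed, n_estimators=rf_trees
        )
        indiv = grid[grid["scope"] == "individual"]["accuracy"].max()
        comb = grid[grid["scope"] == "combined"].set_index("fusion_rule")["accuracy"]
        truth_cols = truth.informative_columns(cohort.spec)
        cdl_w, cdl_m = complete_dataset_learning(
            cohort, partition, estimator="sg_lasso", n_lambda=n_lambda, seed=cfg.seed
        )
        idl_s, idl_m = incomplete_dataset_learning(
            cohort, partition, n_lambda=n_lambda, seed=cfg.seed
        )
        rows.append(
            {
                "seed": cfg.seed,
                "best_individual_acc": float(indiv),
                "combined_majority_acc": float(comb.get("majority", np.nan)),
                "combined_mean_prob_acc": float(comb.get("mean_prob", np.nan)),
                "cdl_cv_acc": cdl_m["cv_accuracy"],
                "idl_cv_acc": idl_m["cv_accuracy"],
                "cdl_jaccard": jaccard(cdl_w.support, truth_cols),
                "idl_jaccard": jaccard(idl_s.final_columns, truth_cols),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise RuntimeError("no seed produced a testable cohort")
    return df
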