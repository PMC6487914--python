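"""Classifier-, source-, and combined-level ensemble fusion.

Two fusion rules operate on a pool of base responses for one subject:

* majority voting — return 1 iff the number of positive hard responses is
  at least half the pool size (a tie therefore returns 1);
* mean probability — return 1 iff the average soft response is >= 0.5
  (again, the boundary returns 1).

A *classifier ensemble* pools the B classifiers of one source.  A *source
ensemble* pools the responses of one classifier kind across sources.  The
*combined ensemble* pools all (classifier x source) base responses
directly — never the outputs of the classifier ensembles — which keeps the
maximum response variability in the pool.  When a source lacks a classifier
kind the pool is simply smaller; the threshold is always half the actual
pool size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classifiers import THRESHOLD, TrainedModel, evaluate

__all__ = [
    "ResponseSet",
    "majority_vote",
    "mean_probability",
    "classifier_ensemble",
    "source_ensemble",
    "combined_ensemble",
    "collect_responses",
    "run_ensemble_grid",
]


@dataclass
class ResponseSet:
    """Long-format table of base responses.

    Columns: subject_id, source, classifier, soft.  Hard responses are
    re-derived from the soft ones at 0.5 so the two can never disagree.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"subject_id", "source", "classifier", "soft"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"response table needs columns {sorted(req)}")
        soft = self.table["soft"].to_numpy(dtype=float)
        if ((soft < 0) | (soft > 1)).any():
            raise ValueError("soft responses must lie in [0, 1]")
        if self.table.duplicated(["subject_id", "source", "classifier"]).any():
            raise ValueError("duplicate (subject, source, classifier) responses")
        self.table = self.table.assign(hard=(soft >= THRESHOLD).astype(int))

    def subset(self, sources: Iterable[str] | None = None, classifiers: Iterable[str] | None = None) -> pd.DataFrame:
        t = self.table
        if sources is not None:
            t = t[t["source"].isin(list(sources))]
        if classifiers is not None:
            t = t[t["classifier"].isin(list(classifiers))]
        return t


def majority_vote(responses: Sequence[int]) -> int:
    """1 iff positive votes reach half the pool (ties break positive)."""
    r = np.asarray(responses)
    if r.size == 0:
        raise ValueError("empty response pool")
    if not np.isin(r, (0, 1)).all():
        raise ValueError("hard responses must be 0 or 1")
    return int(r.sum() >= r.size / 2)


def mean_probability(softs: Sequence[float]) -> int:
    """1 iff the mean soft response is at least 0.5."""
    p = np.asarray(softs, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability pool")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    return int(p.mean() >= THRESHOLD)


def _fuse_groups(t: pd.DataFrame, method: str) -> pd.Series:
    if t.empty:
        raise ValueError("empty response pool")
    if method == "majority":
        return t.groupby("subject_id")["hard"].apply(lambda v: majority_vote(v.to_numpy()))
    if method == "mean_prob":
        return t.groupby("subject_id")["soft"].apply(lambda v: mean_probability(v.to_numpy()))
    raise ValueError(f"unknown fusion method {method!r}")


def classifier_ensemble(rs: ResponseSet, source: str, method: str = "majority") -> pd.Series:
    """Fuse the B classifier responses of one source, per subject."""
    return _fuse_groups(rs.subset(sources=[source]), method)


def source_ensemble(rs: ResponseSet, classifiers: Iterable[str], method: str = "majority") -> pd.Series:
    """Pool all (classifier x source) responses of the selected classifier
    kinds across every source, per subject, and threshold at half the pool."""
    return _fuse_groups(rs.subset(classifiers=list(classifiers)), method)


def combined_ensemble(rs: ResponseSet, method: str = "majority") -> pd.Series:
    """Source ensemble over every classifier kind present."""
    return _fuse_groups(rs.table, method)


def collect_responses(
    models: dict[tuple[str, str], TrainedModel],
    test_X: dict[str, pd.DataFrame],
) -> ResponseSet:
    """Evaluate every (source, classifier) model on the common test set.

    ``models`` is keyed by (source, classifier kind); ``test_X[source]`` is
    the test design matrix of that source, indexed by subject id.
    """
    rows = []
    for (src, kind), model in models.items():
        X = test_X[src]
        soft = model.predict_soft(X.to_numpy(dtype=float))
        for sid, p in zip(X.index, soft):
            rows.append({"subject_id": sid, "source": src, "classifier": kind, "soft": float(p)})
    return ResponseSet(pd.DataFrame(rows))


def run_ensemble_grid(
    models: dict[tuple[str, str], TrainedModel],
    test_X: dict[str, pd.DataFrame],
    test_labels: dict[str, int],
    methods: Sequence[str] = ("majority", "mean_prob"),
) -> pd.DataFrame:
    """Evaluate every individual model, classifier ensemble, single-classifier
    source ensemble, and the combined ensemble on the same test set.

    Returns one row per (model, fusion rule, scope) with accuracy and F1.
    """
    rs = collect_responses(models, test_X)
    sources = sorted({s for s, _ in models})
    kinds = sorted({k for _, k in models})
    rows = []

    def _score(pred: pd.Series, model_id: str, rule: str, scope: str) -> None:
        ids = list(pred.index)
        y = np.array([test_labels[i] for i in ids])
        m = evaluate(pred.to_numpy(), pred.to_numpy(), y)
        rows.append(
            {
                "model_id": model_id,
                "fusion_rule": rule,
                "scope": scope,
                "accuracy": m.accuracy,
                "f1": m.f1,
                "n_test": len(ids),
            }
        )

    for (src, kind) in sorted(models):
        t = rs.subset(sources=[src], classifiers=[kind]).set_index("subject_id")
        _score(t["hard"], f"{src}:{kind}", "none", "individual")
    for src in sources:
        n_kinds = rs.subset(sources=[src])["classifier"].nunique()
        if n_kinds < 2:
            continue
        for method in methods:
            _score(classifier_ensemble(rs, src, method), f"{src}:all", method, "classifier")
    for kind in kinds:
        for method in methods:
            _score(source_ensemble(rs, [kind], method), f"all:{kind}", method, "source")
    for method in methods:
        _score(combined_ensemble(rs, method), "all:all", method, "combined")
    return pd.DataFrame(rows)
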