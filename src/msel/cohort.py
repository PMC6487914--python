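"""Multi-source cohort data model with source-wise missingness.

A *source* is one modality a subject can contribute (e.g. a smartphone
tapping, walking, voice or memory test).  Each subject's contribution
pattern is a binary vector ``I[1..S]``; its decimal value is the subject's
*domain*.  Splitting a cohort into the ``2**S`` domains is called *dataset
deconstruction*.  Subjects who contributed every source (domain
``2**S - 1``) form the common test set; every other subject trains the
individual source models of exactly the sources it contributed, so no
subject with at least one source is ever discarded (100% retention).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SourceSpec",
    "Subject",
    "MultiSourceCohort",
    "Partition",
    "smartphone_pd_spec",
    "assign_domain",
    "source_vector",
    "deconstruct",
    "eligible_sources",
    "split_train_test",
    "complete_design_matrix",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_partition_manifest",
]


@dataclass(frozen=True)
class SourceSpec:
    """Ordered description of the sources a cohort may contain.

    Parameters
    ----------
    names
        Source identifiers in concatenation order (the order used when
        per-source blocks are stacked into one design matrix).
    feature_names
        Ordered feature labels per source; ``len(feature_names[s])`` is the
        source's feature count ``p_i``.
    bit_order
        Source -> bit position (1-based).  Bit ``i`` carries weight
        ``2**(i-1)`` in the domain index.  Configurable because the bit
        convention is a property of the cohort, not of the method.
    """

    names: tuple[str, ...]
    feature_names: Mapping[str, tuple[str, ...]]
    bit_order: Mapping[str, int]

    def __post_init__(self) -> None:
        if len(self.names) < 1:
            raise ValueError("at least one source required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate source names")
        if set(self.feature_names) != set(self.names):
            raise ValueError("feature_names keys must match source names")
        for s, feats in self.feature_names.items():
            if len(set(feats)) != len(feats):
                raise ValueError(f"duplicate feature names within source {s!r}")
        if sorted(self.bit_order.values()) != list(range(1, len(self.names) + 1)):
            raise ValueError("bit_order must be a bijection onto 1..S")
        if set(self.bit_order) != set(self.names):
            raise ValueError("bit_order keys must match source names")

    @property
    def n_sources(self) -> int:
        return len(self.names)

    @property
    def feature_counts(self) -> dict[str, int]:
        return {s: len(self.feature_names[s]) for s in self.names}

    @property
    def n_features_total(self) -> int:
        return sum(len(self.feature_names[s]) for s in self.names)

    @property
    def complete_domain(self) -> int:
        return 2 ** self.n_sources - 1

    def bit_weight(self, source: str) -> int:
        return 2 ** (self.bit_order[source] - 1)

    def to_json(self) -> dict:
        return {
            "names": list(self.names),
            "feature_names": {s: list(f) for s, f in self.feature_names.items()},
            "bit_order": dict(self.bit_order),
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "SourceSpec":
        return cls(
            names=tuple(obj["names"]),
            feature_names={s: tuple(f) for s, f in obj["feature_names"].items()},
            bit_order=dict(obj["bit_order"]),
        )


def smartphone_pd_spec(feature_counts: Mapping[str, int] | None = None) -> SourceSpec:
    """The four-source smartphone-test layout used throughout.

    Bits: memory->1, voice->2, walking->3, tapping->4, so the single-source
    domains are 1 (memory), 2 (voice), 4 (walking) and 8 (tapping) and the
    complete domain is 15.  Concatenation order is tapping, walking, voice,
    memory.  Default feature counts are 97/180/326/3.
    """
    counts = dict(feature_counts or {"tapping": 97, "walking": 180, "voice": 326, "memory": 3})
    names = ("tapping", "walking", "voice", "memory")
    return SourceSpec(
        names=names,
        feature_names={s: tuple(f"{s}_f{i}" for i in range(counts[s])) for s in names},
        bit_order={"memory": 1, "voice": 2, "walking": 3, "tapping": 4},
    )


@dataclass
class Subject:
    """One participant: binary label (1 = case/PD, 0 = control/HC) and the
    feature vectors of the sources actually contributed."""

    id: str
    label: int
    source_data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        self.source_data = {s: np.asarray(v, dtype=float) for s, v in self.source_data.items()}


@dataclass
class MultiSourceCohort:
    """A set of subjects plus the :class:`SourceSpec` they conform to."""

    spec: SourceSpec
    subjects: list[Subject]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        for sub in self.subjects:
            for src, vec in sub.source_data.items():
                if src not in self.spec.names:
                    raise ValueError(f"subject {sub.id}: unknown source {src!r}")
                p_i = len(self.spec.feature_names[src])
                if vec.shape != (p_i,):
                    raise ValueError(
                        f"subject {sub.id}: source {src!r} has {vec.shape} values, expected ({p_i},)"
                    )

    def __len__(self) -> int:
        return len(self.subjects)

    def subject(self, sid: str) -> Subject:
        return self._index()[sid]

    def _index(self) -> dict[str, Subject]:
        return {s.id: s for s in self.subjects}

    @property
    def labels(self) -> dict[str, int]:
        return {s.id: s.label for s in self.subjects}

    def domain_of(self, sub: Subject) -> int:
        return assign_domain(source_vector(sub, self.spec), self.spec)

    @property
    def n_complete(self) -> int:
        full = self.spec.complete_domain
        return sum(1 for s in self.subjects if self.domain_of(s) == full)

    @property
    def n_incomplete(self) -> int:
        return len(self.subjects) - self.n_complete


@dataclass
class Partition:
    """Train/test split under the deconstruction rule.

    ``test_ids`` are exactly the complete-data subjects; ``train_by_source``
    maps each source to the incomplete-data subjects contributing it.
    """

    train_by_source: dict[str, list[str]]
    test_ids: list[str]

    @property
    def train_ids(self) -> set[str]:
        out: set[str] = set()
        for ids in self.train_by_source.values():
            out.update(ids)
        return out


def source_vector(sub: Subject, spec: SourceSpec) -> np.ndarray:
    """Binary contribution vector ``I[1..S]`` in bit order."""
    vec = np.zeros(spec.n_sources, dtype=int)
    for src in sub.source_data:
        vec[spec.bit_order[src] - 1] = 1
    return vec


def assign_domain(v: Sequence[int] | np.ndarray, spec: SourceSpec) -> int:
    """Decimal domain index of a binary source vector: sum of I[i] * 2**(i-1)."""
    v = np.asarray(v, dtype=int)
    if v.shape != (spec.n_sources,):
        raise ValueError(f"source vector length {v.shape} != S={spec.n_sources}")
    if not np.isin(v, (0, 1)).all():
        raise ValueError("source vector entries must be 0 or 1")
    return int((v * (2 ** np.arange(spec.n_sources))).sum())


def deconstruct(cohort: MultiSourceCohort) -> dict[int, list[str]]:
    """Split a cohort into its 2**S complete domains.

    Every domain key is present (possibly with an empty list); the lists are
    disjoint and jointly exhaustive.
    """
    if not cohort.subjects:
        raise ValueError("cannot deconstruct an empty cohort")
    out: dict[int, list[str]] = {d: [] for d in range(2 ** cohort.spec.n_sources)}
    for sub in cohort.subjects:
        out[cohort.domain_of(sub)].append(sub.id)
    return out


def eligible_sources(sub: Subject, spec: SourceSpec | None = None) -> list[str]:
    """Sources whose individual source model this subject may help train."""
    if spec is not None:
        return [s for s in spec.names if s in sub.source_data]
    return list(sub.source_data)


def split_train_test(cohort: MultiSourceCohort) -> Partition:
    """Reserve complete-data subjects as the common test set; every other
    subject joins the training pool of each source it contributed."""
    full = cohort.spec.complete_domain
    test_ids: list[str] = []
    train_by_source: dict[str, list[str]] = {s: [] for s in cohort.spec.names}
    for sub in cohort.subjects:
        if cohort.domain_of(sub) == full:
            test_ids.append(sub.id)
        else:
            for src in eligible_sources(sub, cohort.spec):
                train_by_source[src].append(sub.id)
    if not test_ids:
        logger.warning("no complete-data subjects: test set is empty")
    return Partition(train_by_source=train_by_source, test_ids=test_ids)


def complete_design_matrix(
    cohort: MultiSourceCohort, partition: Partition
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Concatenated design matrix of the complete-data subjects.

    Returns ``(X, y, groups)`` with subjects as rows and the per-source
    feature blocks stacked in spec order, so X has ``p = sum(p_i)`` columns.
    ``groups[j]`` is the 0-based source index of column ``j``.  (The
    mathematical convention for this matrix is features-by-subjects,
    ``p x N_c``; ``X.T`` gives that orientation.)
    """
    if not partition.test_ids:
        raise ValueError("partition has no complete-data subjects")
    idx = cohort._index()
    cols: list[str] = []
    groups: list[int] = []
    for gi, src in enumerate(cohort.spec.names):
        for f in cohort.spec.feature_names[src]:
            cols.append(f"{src}::{f}")
            groups.append(gi)
    rows = []
    y = []
    for sid in partition.test_ids:
        sub = idx[sid]
        parts = []
        for src in cohort.spec.names:
            if src not in sub.source_data:
                raise ValueError(f"subject {sid} marked complete but lacks source {src!r}")
            vec = sub.source_data[src]
            if np.isnan(vec).any():
                raise ValueError(f"subject {sid}: NaN inside complete source {src!r}")
            parts.append(vec)
        rows.append(np.concatenate(parts))
        y.append(sub.label)
    X = pd.DataFrame(np.asarray(rows), index=list(partition.test_ids), columns=cols)
    return X, pd.Series(y, index=X.index, name="label"), np.asarray(groups)


# ---------------------------------------------------------------------------
# I/O: one CSV per source (subject_id, label, feature columns) + JSON spec.


def read_cohort_csv(
    paths: Mapping[str, str | Path], spec: SourceSpec, drop_empty: bool = True
) -> MultiSourceCohort:
    """Load a cohort from per-source CSV files.

    Each CSV has columns ``subject_id, label`` then the source's features in
    spec order.  A subject may appear in any subset of the files but at most
    once per file (repeated instances are rejected).  Subjects appearing in
    no file at all simply do not exist; subjects with conflicting labels
    raise.
    """
    subjects: dict[str, Subject] = {}
    for src in spec.names:
        if src not in paths:
            continue
        df = pd.read_csv(paths[src], dtype={"subject_id": str})
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise ValueError(f"source {src!r}: repeated instance for subject {dup!r}")
        feat_cols = list(spec.feature_names[src])
        missing = [c for c in feat_cols if c not in df.columns]
        if missing:
            raise ValueError(f"source {src!r}: missing feature columns {missing[:3]}...")
        for _, row in df.iterrows():
            sid, label = str(row["subject_id"]), int(row["label"])
            vec = row[feat_cols].to_numpy(dtype=float)
            if sid in subjects:
                if subjects[sid].label != label:
                    raise ValueError(f"subject {sid!r}: conflicting labels across sources")
                subjects[sid].source_data[src] = vec
            else:
                subjects[sid] = Subject(id=sid, label=label, source_data={src: vec})
    subs = list(subjects.values())
    n_empty = sum(1 for s in subs if not s.source_data)
    if drop_empty and n_empty:
        logger.info("dropping %d subjects with zero sources", n_empty)
        subs = [s for s in subs if s.source_data]
    return MultiSourceCohort(spec=spec, subjects=subs)


def write_cohort_csv(cohort: MultiSourceCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write one CSV per source plus ``source_spec.json``; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for src in cohort.spec.names:
        rows = []
        for sub in cohort.subjects:
            if src in sub.source_data:
                rows.append([sub.id, sub.label, *sub.source_data[src]])
        df = pd.DataFrame(rows, columns=["subject_id", "label", *cohort.spec.feature_names[src]])
        p = out_dir / f"{src}.csv"
        df.to_csv(p, index=False)
        paths[src] = p
    with open(out_dir / "source_spec.json", "w") as fh:
        json.dump(cohort.spec.to_json(), fh, indent=1)
    return paths


def write_partition_manifest(
    cohort: MultiSourceCohort, partition: Partition, path: str | Path
) -> None:
    """JSON manifest: per-subject domain and train/test role per source."""
    domains = {sub.id: cohort.domain_of(sub) for sub in cohort.subjects}
    roles: dict[str, dict] = {}
    test = set(partition.test_ids)
    for sub in cohort.subjects:
        roles[sub.id] = {
            "domain": domains[sub.id],
            "role": "test" if sub.id in test else "train",
            "train_sources": [] if sub.id in test else eligible_sources(sub, cohort.spec),
        }
    with open(path, "w") as fh:
        json.dump(
            {
                "n_subjects": len(cohort),
                "n_complete": len(partition.test_ids),
                "n_incomplete": len(cohort) - len(partition.test_ids),
                "subjects": roles,
            },
            fh,
            indent=1,
        )
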