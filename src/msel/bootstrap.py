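"""Bootstrap feature-confidence curves as a function of sample size.

For a given feature and class pool, draw ``nSamp`` subjects with
replacement, compute statistics (mean, sd) of the resampled feature values,
and repeat ``n_boot`` times.  Sweeping ``nSamp`` over a size grid shows at
what cohort size a feature's class-conditional statistics stabilise — the
basis for arguing that selection on a large incomplete-data pool is more
trustworthy than on a small complete-data pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import MultiSourceCohort, Partition

logger = logging.getLogger(__name__)

__all__ = ["BootstrapCurve", "bootstrap_sample", "bootstrap_statistics", "sweep_sample_sizes"]

DEFAULT_N_BOOT = 10_000

_STATS = {
    "mean": lambda a: float(np.mean(a)),
    "sd": lambda a: float(np.std(a, ddof=1)) if a.size > 1 else 0.0,
}


@dataclass
class BootstrapCurve:
    """Per (feature, class) stabilisation curve.

    ``points`` has one row per sample size with the mean over replicates of
    each bootstrap statistic (mean of replicate means, mean of replicate
    sds) and the dispersion of the replicate means.
    """

    feature: str
    class_label: int
    n_boot: int
    points: pd.DataFrame  # columns: size, mean_of_means, mean_of_sds, sd_of_means


def bootstrap_sample(values: np.ndarray, n_samp: int, seed: int | np.random.Generator) -> np.ndarray:
    """``n_samp`` draws with replacement from the pool; deterministic given seed."""
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("empty pool")
    if n_samp < 1:
        raise ValueError("n_samp must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(values, size=n_samp, replace=True)


def bootstrap_statistics(
    values: np.ndarray,
    n_samp: int,
    n_boot: int,
    statistics: tuple[str, ...] = ("mean", "sd"),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Replicate table: one row per bootstrap replicate, one column per
    statistic.  The sd of a size-1 resample is reported as 0 (flagged)."""
    unknown = set(statistics) - set(_STATS)
    if unknown:
        raise ValueError(f"unknown statistics {sorted(unknown)}")
    if n_samp == 1 and "sd" in statistics:
        logger.info("sd of size-1 resamples is reported as 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for b in range(n_boot):
        s = bootstrap_sample(values, n_samp, rng)
        rows.append({"replicate": b, **{st: _STATS[st](s) for st in statistics}})
    return pd.DataFrame(rows)


def sweep_sample_sizes(
    cohort: MultiSourceCohort,
    partition: Partition,
    source: str,
    features: list[str],
    sizes: list[int] | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> list[BootstrapCurve]:
    """One stabilisation curve per (feature, class).

    Pools are the incomplete-data contributors of ``source``, split by
    class, so the curves describe exactly the subjects available to the
    large-cohort (IDL-style) selection.  Sizes exceeding a class pool are
    skipped with a log entry.  Default size grid: 12 log-spaced points from
    10 up to the smaller class pool.
    """
    idx = {s.id: s for s in cohort.subjects}
    ids = partition.train_by_source.get(source, [])
    if not ids:
        raise ValueError(f"no incomplete-data contributors for source {source!r}")
    feat_idx = {f: i for i, f in enumerate(cohort.spec.feature_names[source])}
    for f in features:
        if f not in feat_idx:
            raise KeyError(f"feature {f!r} not in source {source!r}")
    pools: dict[int, np.ndarray] = {}
    for lab in (0, 1):
        sel = [i for i in ids if idx[i].label == lab]
        pools[lab] = np.asarray([idx[i].source_data[source] for i in sel], dtype=float)
    if sizes is None:
        top = max(min(len(pools[0]), len(pools[1])), 10)
        sizes = sorted({int(round(s)) for s in np.logspace(1, np.log10(top), 12)})
    curves: list[BootstrapCurve] = []
    rng = np.random.default_rng(seed)
    for f in features:
        j = feat_idx[f]
        for lab in (0, 1):
            pool = pools[lab][:, j]
            pts = []
            for size in sizes:
                if size > pool.size:
                    logger.info("skipping size %d > pool %d (feature %r, class %d)", size, pool.size, f, lab)
                    continue
                rep = bootstrap_statistics(pool, size, n_boot, ("mean", "sd"), rng)
                pts.append(
                    {
                        "size": size,
                        "mean_of_means": float(rep["mean"].mean()),
                        "mean_of_sds": float(rep["sd"].mean()),
                        "sd_of_means": float(rep["mean"].std(ddof=1)) if n_boot > 1 else 0.0,
                    }
                )
            curves.append(
                BootstrapCurve(feature=f, class_label=lab, n_boot=n_boot, points=pd.DataFrame(pts))
            )
    return curves


def curves_to_frame(curves: list[BootstrapCurve]) -> pd.DataFrame:
    """Long-format CSV-ready table of a curve set."""
    frames = []
    for c in curves:
        d = c.points.copy()
        d.insert(0, "feature", c.feature)
        d.insert(1, "class", c.class_label)
        frames.append(d)
    return pd.concat(frames, ignore_index=True)
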