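"""Correlation stage: Pearson correlations of divergence measures with
selection strength, and of measures with each other.

Coefficients are computed across regions within each (treatment, generation,
iteration) cell, averaged over iterations with equal weight, and optionally
further averaged within treatment levels (e.g. all treatments with
migration = 0.002).  Cells with fewer than three complete pairs or zero
variance in either variable are dropped as missing and counted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "pairwise_correlation",
    "iteration_correlations",
    "level_average",
]

log = logging.getLogger("divergesim")

DEFAULT_GROUP_KEYS = ("treatment", "generation")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pairwise-complete Pearson r; NaN for <3 pairs or zero variance."""
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0.0 or np.std(y) == 0.0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def iteration_correlations(
    records: pd.DataFrame,
    x: str,
    y: str,
    group_keys=DEFAULT_GROUP_KEYS,
) -> pd.DataFrame:
    """Per-(group x iteration) Pearson r of ``x`` vs ``y`` across regions."""
    keys = list(group_keys) + ["iteration"]
    rows = []
    n_missing = 0
    for key_vals, sub in records.groupby(keys, sort=True):
        r = _pearson(sub[x].to_numpy(float), sub[y].to_numpy(float))
        if np.isnan(r):
            n_missing += 1
        rows.append(dict(zip(keys, key_vals)) | {
            "r": r,
            "n_regions": int(sub["region_id"].nunique()),
        })
    if n_missing:
        log.info("correlation %s~%s: %d group x iteration cells missing "
                 "(zero variance or <3 complete pairs)", x, y, n_missing)
    return pd.DataFrame(rows)


def pairwise_correlation(
    records: pd.DataFrame,
    x: str,
    y: str,
    group_keys=DEFAULT_GROUP_KEYS,
) -> pd.DataFrame:
    """Iteration-averaged correlation table.

    Returns one row per group with columns ``mean_r`` (equal-weight mean over
    iterations, missing cells excluded), ``n_iterations`` and ``n_regions``.
    """
    per_iter = iteration_correlations(records, x, y, group_keys)
    out = (
        per_iter.groupby(list(group_keys), sort=True)
        .agg(mean_r=("r", "mean"),
             n_iterations=("r", lambda s: int(s.notna().sum())),
             n_regions=("n_regions", "max"))
        .reset_index()
    )
    out.insert(0, "x", x)
    out.insert(1, "y", y)
    return out


def level_average(
    corr_table: pd.DataFrame,
    records: pd.DataFrame,
    level: str,
    group_keys=("generation",),
) -> pd.DataFrame:
    """Average treatment-level coefficients within levels of one demographic
    factor (``founders``, ``dp_fraction`` or ``migration``).

    ``corr_table`` must be grouped by treatment; the treatment -> factor-level
    mapping is taken from ``records``.
    """
    mapping = records[["treatment", level]].drop_duplicates()
    merged = corr_table.merge(mapping, on="treatment", validate="many_to_one")
    keys = [level] + list(group_keys)
    return (
        merged.groupby(keys, sort=True)
        .agg(mean_r=("mean_r", "mean"), n_treatments=("treatment", "nunique"))
        .reset_index()
    )
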