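"""Quantile outlier calling, spike-in false-positive/false-negative
permutations, combined-measure outlier sets and cross-treatment overlap.

The spike-in permutation estimates how often a 95%-quantile outlier scan run
on an (almost entirely) neutral pool flags truly neutral regions: a pool of
neutral records (all iterations of all regions for one treatment x
generation) has 5% of its rows replaced by records of the same regions drawn
from the divergent-selection regime, outliers are called per measure, and

* FPR = fraction of outliers that are neutral records,
* FNR = fraction of the spiked divergent records not recovered,

averaged over permutations.  Combined-measure outlier sets are intersections
of single-measure sets; for single measures FPR = FNR because the outlier set
and the spike are the same size.

"Convergence" between treatments is measured as the proportional overlap of
outlier *region* sets from the same permutation replicate, averaged over
permutations, and summarized as a symmetric treatment x treatment matrix
ordered by average-linkage hierarchical clustering.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "MEASURES",
    "MEASURE_COMBOS",
    "quantile_outliers",
    "spike_in_permutation",
    "PermutationResult",
    "overlap_matrix",
    "cluster_order",
    "quantile_cutoffs",
]

log = logging.getLogger("divergesim")

MEASURES = ("fst", "dxy", "delta_pi")
MEASURE_COMBOS: tuple[tuple[str, ...], ...] = tuple(
    combo
    for size in (1, 2, 3)
    for combo in itertools.combinations(MEASURES, size)
)


def combo_label(combo: tuple[str, ...]) -> str:
    return "&".join(combo)


def quantile_outliers(values: pd.Series, q: float = 0.95) -> set:
    """Ids (index labels) with value strictly above the empirical q-quantile.

    Missing values are excluded before the quantile is computed (linear /
    type-7 interpolation); ties at or below the cut-off are not outliers, so
    the set never exceeds ``(1-q)`` of the data.
    """
    clean = values.dropna()
    if clean.empty:
        raise ValueError("all values missing; cannot call outliers")
    cut = float(np.quantile(clean.to_numpy(float), q))
    return set(clean.index[clean.to_numpy(float) > cut])


@dataclass
class PermutationResult:
    """Averaged spike-in results for one treatment x generation pool."""

    treatment: str
    generation: int
    n_perm: int
    summary: pd.DataFrame  # rows: measure combo; cols: outlier_n, fpr, fnr
    outlier_regions: dict[str, list[set]]  # combo label -> per-perm region ids


def spike_in_permutation(
    neutral_pool: pd.DataFrame,
    phenodiv_pool: pd.DataFrame,
    n_perm: int = 100,
    seed: int | np.random.SeedSequence = 0,
    q: float = 0.95,
    measures: tuple[str, ...] = MEASURES,
) -> PermutationResult:
    """Estimate FPR/FNR of quantile outlier scans on a spiked neutral pool.

    ``neutral_pool``: all iterations x regions of one treatment x generation
    under the neutral regime.  ``phenodiv_pool``: the divergent-selection pool
    for the same treatment x generation, with at least one iteration per
    region.  Per permutation, one random neutral record per region is spiked
    out for one random divergent iteration of that region.
    """
    for name, pool in (("neutral", neutral_pool), ("pheno_div", phenodiv_pool)):
        missing = [c for c in ("region_id", "iteration", *measures)
                   if c not in pool.columns]
        if missing:
            raise ValueError(f"{name} pool lacks columns {missing}")
    regions = np.sort(neutral_pool["region_id"].unique())
    if set(phenodiv_pool["region_id"].unique()) < set(regions):
        raise ValueError("pheno_div pool must cover every region of the "
                         "neutral pool")
    n_spike = len(regions)
    if n_spike >= len(neutral_pool):
        raise ValueError("neutral pool smaller than the spike size")

    rng = np.random.default_rng(seed)
    neutral = neutral_pool.reset_index(drop=True)
    pd_groups = {rid: sub.reset_index(drop=True)
                 for rid, sub in phenodiv_pool.groupby("region_id")}

    labels = [combo_label(c) for c in MEASURE_COMBOS if set(c) <= set(measures)]
    combos = [c for c in MEASURE_COMBOS if set(c) <= set(measures)]
    acc = {lab: {"outlier_n": [], "fpr": [], "fnr": []} for lab in labels}
    outlier_regions: dict[str, list[set]] = {lab: [] for lab in labels}

    for _ in range(n_perm):
        drop = rng.choice(len(neutral), n_spike, replace=False)
        kept = neutral.drop(index=drop)
        spiked_rows = []
        for rid in regions:
            grp = pd_groups[rid]
            spiked_rows.append(grp.iloc[rng.integers(0, len(grp))])
        spiked = pd.DataFrame(spiked_rows)
        pool = pd.concat([kept, spiked], ignore_index=True)
        is_neutral = np.zeros(len(pool), dtype=bool)
        is_neutral[: len(kept)] = True
        region_of = pool["region_id"].to_numpy()

        single_sets = {
            m: quantile_outliers(pool[m], q) for m in measures
        }
        spiked_ids = set(range(len(kept), len(pool)))
        for combo, lab in zip(combos, labels):
            ids = set.intersection(*(single_sets[m] for m in combo))
            n_out = len(ids)
            if n_out == 0:
                fpr = 0.0
            else:
                fpr = sum(1 for i in ids if is_neutral[i]) / n_out
            fnr = len(spiked_ids - ids) / n_spike
            acc[lab]["outlier_n"].append(n_out)
            acc[lab]["fpr"].append(fpr)
            acc[lab]["fnr"].append(fnr)
            outlier_regions[lab].append({int(region_of[i]) for i in ids})

    summary = pd.DataFrame([
        {
            "measures": lab,
            "outlier_n": float(np.mean(acc[lab]["outlier_n"])),
            "fpr": float(np.mean(acc[lab]["fpr"])),
            "fnr": float(np.mean(acc[lab]["fnr"])),
        }
        for lab in labels
    ])
    treatment = str(neutral_pool["treatment"].iloc[0]) if "treatment" in neutral_pool else ""
    generation = int(neutral_pool["generation"].iloc[0]) if "generation" in neutral_pool else -1
    return PermutationResult(
        treatment=treatment,
        generation=generation,
        n_perm=n_perm,
        summary=summary,
        outlier_regions=outlier_regions,
    )


# ---------------------------------------------------------------------------
# cross-treatment overlap
# ---------------------------------------------------------------------------

def _pair_overlap(a: set, b: set, denominator: str) -> float:
    if not a and not b:
        return float("nan")
    inter = len(a & b)
    if denominator == "jaccard":
        return inter / len(a | b)
    return inter / ((len(a) + len(b)) / 2.0)


def overlap_matrix(
    per_treatment_sets: dict[str, list[set]],
    denominator: str = "mean",
) -> pd.DataFrame:
    """Mean proportional overlap of outlier region sets between treatments.

    ``per_treatment_sets`` maps treatment label to the per-permutation region
    sets of one measure combination; permutation replicates must align across
    treatments.  Overlap is ``|A & B| / mean(|A|, |B|)`` (or Jaccard) within
    each permutation, averaged over permutations; a pair with both sets empty
    in every permutation is missing.
    """
    labels = list(per_treatment_sets)
    n_perm = {len(v) for v in per_treatment_sets.values()}
    if len(n_perm) != 1:
        raise ValueError("treatments have differing permutation counts")
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            vals = [
                _pair_overlap(sa, sb, denominator)
                for sa, sb in zip(per_treatment_sets[a], per_treatment_sets[b])
            ]
            v = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")
            mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def cluster_order(matrix: pd.DataFrame):
    """Average-linkage clustering on distance ``1 - overlap``.

    Returns ``(ordered_labels, linkage_matrix)``; missing entries are imputed
    with the column mean (with a warning), leaf order is deterministic with
    ties broken by input index.
    """
    m = matrix.to_numpy(float).copy()
    if np.isnan(m).any():
        log.warning("overlap matrix has missing entries; imputing column means")
        offdiag = np.where(np.eye(len(m), dtype=bool), np.nan, m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_means = np.nanmean(offdiag, axis=0)
        col_means = np.nan_to_num(col_means, nan=0.0)
        ii, jj = np.where(np.isnan(m))
        m[ii, jj] = col_means[jj]
    d = 1.0 - (m + m.T) / 2.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    # deterministic tie-break: an index-ordered perturbation far below any
    # real overlap difference, so equal-distance merges follow input order
    n = len(d)
    idx = np.arange(n, dtype=float)
    tie = 1e-9 * (idx[:, None] + idx[None, :]) / (2 * n)
    d = d + tie
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    order = _index_ordered_leaves(z, n)
    return [matrix.index[i] for i in order], z


def _index_ordered_leaves(z: np.ndarray, n: int) -> list[int]:
    """Dendrogram leaf order with, at every internal node, the subtree
    containing the smallest original index traversed first."""
    children = {n + i: (int(a), int(b)) for i, (a, b, _, _) in enumerate(z)}
    min_leaf: dict[int, int] = {}

    def leaves(node: int) -> list[int]:
        if node < n:
            min_leaf[node] = node
            return [node]
        a, b = children[node]
        la, lb = leaves(a), leaves(b)
        if min_leaf[b] < min_leaf[a]:
            la, lb = lb, la
        min_leaf[node] = min(min_leaf[a], min_leaf[b])
        return la + lb

    return leaves(2 * n - 2)


def quantile_cutoffs(
    records: pd.DataFrame,
    q: float = 0.95,
    measures: tuple[str, ...] = MEASURES,
    group_keys=("treatment", "generation", "regime"),
) -> pd.DataFrame:
    """Upper-quantile cut-offs of pooled iteration x region values per group,
    the per-regime thresholds a distribution comparison would plot."""
    rows = []
    for key_vals, sub in records.groupby(list(group_keys), sort=True):
        row = dict(zip(group_keys, key_vals))
        for m in measures:
            clean = sub[m].dropna()
            row[m] = float(np.quantile(clean, q)) if len(clean) else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
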