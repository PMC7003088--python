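"""Stage glue: assemble the standard output tables from a records table.

Each function here is a thin orchestration layer over one analysis module,
producing the tidy TSV-shaped frames the command-line interface writes and
the replication script reports.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import correlations, lmm, outliers

__all__ = [
    "summary_table",
    "correlation_tables",
    "spikein_tables",
    "overlap_tables",
    "lmm_table",
    "final_generation",
]

MEASURES = outliers.MEASURES


def final_generation(records: pd.DataFrame) -> int:
    return int(records["generation"].max())


def summary_table(records: pd.DataFrame) -> pd.DataFrame:
    """Mean of each measure per treatment x regime x generation (the
    trajectory panels), averaged over regions and iterations."""
    keys = ["treatment", "founders", "dp_fraction", "migration",
            "regime", "generation"]
    return (
        records.groupby(keys, sort=True)[list(MEASURES) + ["pi_ap", "pi_dp"]]
        .mean()
        .reset_index()
    )


def correlation_tables(records: pd.DataFrame) -> pd.DataFrame:
    """Iteration-averaged Pearson correlations per treatment x generation:
    each measure against selection strength S and against each other."""
    pairs = [(m, "S") for m in MEASURES]
    pairs += [("fst", "dxy"), ("fst", "delta_pi"), ("dxy", "delta_pi")]
    tables = [
        correlations.pairwise_correlation(records, x, y)
        for x, y in pairs
    ]
    return pd.concat(tables, ignore_index=True)


def spikein_tables(
    records: pd.DataFrame,
    generations: list[int] | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Spike-in FPR/FNR per treatment x generation x measure(-combination).

    Returns the flat rates table and the per-(treatment, generation)
    :class:`~divergesim.outliers.PermutationResult` objects (whose retained
    outlier sets feed the overlap stage).
    """
    neutral = records[records["regime"] == "neutral"]
    phenodiv = records[records["regime"] == "pheno_div"]
    if neutral.empty or phenodiv.empty:
        raise ValueError("spike-in needs both neutral and pheno_div records")
    if generations is None:
        generations = [final_generation(records)]
    treatments = sorted(records["treatment"].unique())
    rows = []
    results: dict[tuple[str, int], outliers.PermutationResult] = {}
    for gen in generations:
        for t_idx, trt in enumerate(treatments):
            np_pool = neutral[(neutral["treatment"] == trt)
                              & (neutral["generation"] == gen)]
            pd_pool = phenodiv[(phenodiv["treatment"] == trt)
                               & (phenodiv["generation"] == gen)]
            if np_pool.empty or pd_pool.empty:
                continue
            ss = np.random.SeedSequence(seed, spawn_key=(4, t_idx, gen))
            res = outliers.spike_in_permutation(
                np_pool, pd_pool, n_perm=n_perm, seed=ss
            )
            results[(trt, gen)] = res
            meta = np_pool.iloc[0]
            for _, r in res.summary.iterrows():
                rows.append({
                    "generation": gen,
                    "treatment": trt,
                    "founders": meta.get("founders"),
                    "dp_fraction": meta.get("dp_fraction"),
                    "migration": meta.get("migration"),
                    **r.to_dict(),
                })
    return pd.DataFrame(rows), results


def overlap_tables(
    spikein_results: dict,
    generation: int,
    combos: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Cross-treatment outlier-overlap matrix per measure combination, rows
    and columns ordered by hierarchical clustering."""
    labels = sorted({t for (t, g) in spikein_results if g == generation})
    if not labels:
        raise ValueError(f"no spike-in results at generation {generation}")
    any_res = spikein_results[(labels[0], generation)]
    if combos is None:
        combos = list(any_res.outlier_regions)
    out = {}
    for combo in combos:
        sets = {t: spikein_results[(t, generation)].outlier_regions[combo]
                for t in labels}
        mat = outliers.overlap_matrix(sets)
        if len(labels) > 2:
            order, _ = outliers.cluster_order(mat)
            mat = mat.loc[order, order]
        out[combo] = mat
    return out


def lmm_table(
    records_with_features: pd.DataFrame,
    generation: int | None = None,
    measures: tuple[str, ...] = MEASURES,
    migration_levels: tuple[float, ...] | None = None,
    predictors: tuple[str, ...] = lmm.DEFAULT_PREDICTORS,
) -> pd.DataFrame:
    """Mixed-model coefficient/variance table per measure x migration stratum
    at the final sampling generation (divergent-selection records)."""
    data = records_with_features[records_with_features["regime"] == "pheno_div"]
    if generation is None:
        generation = final_generation(data)
    data = data[data["generation"] == generation]
    if migration_levels is None:
        migration_levels = tuple(sorted(data["migration"].unique()))
    results = []
    for measure in measures:
        for m in migration_levels:
            results.append(
                lmm.fit_feature_model(data, measure, migration=m,
                                      predictors=predictors)
            )
    return lmm.results_table(results)
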