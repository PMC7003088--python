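"""Mixed-model stage: variance in each divergence measure explained by gene
features, with region (gene) identity and demographic treatment as crossed
random intercepts.

The model, fit by REML per measure and per migration stratum on the final
sampling generation, is

    measure ~ S + gene_length + exon_n + selection_target + pheno_gen
              + (1 | region_id) + (1 | treatment)

with predictors z-scored by default.  Variance explained is partitioned as
marginal (fixed effects only) and conditional (fixed + random) R^2:
``var(X beta)`` over, respectively plus, the random-intercept variances and
the residual variance.  Censored ``pheno_gen`` records (runs that never
reached the phenotypic optimum) are excluded, with counts logged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

__all__ = ["FeatureModelResult", "fit_feature_model", "DEFAULT_PREDICTORS"]

log = logging.getLogger("divergesim")

DEFAULT_PREDICTORS = ("S", "gene_length", "exon_n", "selection_target", "pheno_gen")


@dataclass
class FeatureModelResult:
    measure: str
    migration: float | None
    coefficients: pd.DataFrame   # term, estimate, se, df, t, p
    var_fixed_pct: float         # marginal R^2, percent
    var_total_pct: float         # conditional R^2, percent
    n_obs: int
    n_censored_dropped: int
    dropped_random_terms: tuple[str, ...] = ()


def _zscore(s: pd.Series) -> pd.Series:
    sd = s.std(ddof=0)
    if sd == 0:
        return s - s.mean()
    return (s - s.mean()) / sd


def fit_feature_model(
    records: pd.DataFrame,
    measure: str,
    migration: float | None = None,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    standardize: bool = True,
    random_terms: tuple[str, ...] = ("region_id", "treatment"),
) -> FeatureModelResult:
    """REML mixed-model fit of one measure on gene features.

    ``records`` must already be restricted to the final sampling generation
    and carry the region features (see ``runner.merge_region_features``);
    ``migration`` selects a stratum (None = use all rows).
    """
    data = records.copy()
    if migration is not None:
        data = data[data["migration"] == migration]
    n_censored = 0
    if "pheno_censored" in data.columns and "pheno_gen" in predictors:
        n_censored = int(data["pheno_censored"].sum())
        if n_censored:
            log.info("%s (m=%s): dropping %d censored pheno_gen records",
                     measure, migration, n_censored)
        data = data[~data["pheno_censored"]]
    cols = [measure, *predictors, *random_terms]
    data = data.dropna(subset=cols).reset_index(drop=True)
    if len(data) < len(predictors) + 3:
        raise ValueError("too few complete records to fit the model")

    constant = tuple(p for p in predictors
                     if data[p].astype(float).std(ddof=0) == 0.0)
    if constant:
        log.info("%s (m=%s): dropping zero-variance predictors %s",
                 measure, migration, constant)
        predictors = tuple(p for p in predictors if p not in constant)
    if standardize:
        for p in predictors:
            data[p] = _zscore(data[p].astype(float))

    usable_random = tuple(
        t for t in random_terms if data[t].nunique() > 1
    )
    dropped = tuple(t for t in random_terms if t not in usable_random)

    fit, usable_random, dropped = _fit_with_fallback(
        data, measure, predictors, usable_random, dropped
    )

    fe_names = ["Intercept", *predictors]
    beta = fit.params[fe_names]
    x = np.column_stack([np.ones(len(data))] +
                        [data[p].to_numpy(float) for p in predictors])
    var_fixed = float(np.var(x @ beta.to_numpy(), ddof=0))
    var_random = float(np.sum(fit.vcomp)) if len(usable_random) else 0.0
    var_resid = float(fit.scale)
    total = var_fixed + var_random + var_resid
    df_resid = len(data) - len(fe_names)
    coefs = pd.DataFrame({
        "term": fe_names,
        "estimate": fit.params[fe_names].to_numpy(),
        "se": fit.bse[fe_names].to_numpy(),
        "df": df_resid,
        "t": fit.tvalues[fe_names].to_numpy(),
        "p": fit.pvalues[fe_names].to_numpy(),
    })
    return FeatureModelResult(
        measure=measure,
        migration=migration,
        coefficients=coefs,
        var_fixed_pct=100.0 * var_fixed / total,
        var_total_pct=100.0 * (var_fixed + var_random) / total,
        n_obs=len(data),
        n_censored_dropped=n_censored,
        dropped_random_terms=dropped,
    )


def _fit_with_fallback(data, measure, predictors, usable_random, dropped):
    """Fit; on singular/non-converged fits drop random terms one by one."""
    formula = f"{measure} ~ " + " + ".join(predictors)
    data = data.assign(_one=1)
    while True:
        vc = {t: f"0 + C({t})" for t in usable_random}
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if usable_random:
                    model = smf.mixedlm(formula, data, groups="_one", vc_formula=vc)
                    fit = model.fit(reml=True)
                else:
                    fit = smf.ols(formula, data).fit()
                    fit.vcomp = np.array([])
                    fit.scale = float(fit.mse_resid)
            if not usable_random or np.all(np.isfinite(fit.params)):
                return fit, usable_random, dropped
        except Exception as err:  # singular fit: retry without a random term
            if not usable_random:
                raise
            log.warning("%s: singular mixed fit (%s); dropping random term %r",
                        measure, err, usable_random[-1])
        dropped = dropped + (usable_random[-1],)
        usable_random = usable_random[:-1]


def results_table(results: list[FeatureModelResult]) -> pd.DataFrame:
    """Flatten fitted models into one tidy table (one row per coefficient)."""
    rows = []
    for res in results:
        for _, c in res.coefficients.iterrows():
            rows.append({
                "measure": res.measure,
                "migration": res.migration,
                "var_fixed_pct": res.var_fixed_pct,
                "var_total_pct": res.var_total_pct,
                "n_obs": res.n_obs,
                **c.to_dict(),
            })
    return pd.DataFrame(rows)
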