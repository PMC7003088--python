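"""Experiment orchestration: the factorial of regions x treatments x regimes
x iterations, with hierarchical seeding, burn-in sharing and checkpointing.

Seeds are derived with ``numpy.random.SeedSequence(master_seed, spawn_key=...)``
so every cell's stream is reproducible and independent of execution order.
Within a (region, iteration) group the two phenotype regimes (divergent and
null) share one stabilizing burn-in and the neutral regime has its own
neutral burn-in, so all treatments of a group diverge from a common ancestral
population.

Output is one tidy table (pandas DataFrame / TSV): one row per region x
treatment x regime x iteration x sampling generation, carrying the windowed
divergence statistics, the sweep-timing proxy ``pheno_gen``, and the region
features used by the mixed-model stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import SimParams, TreatmentSpec, full_grid, run_burn_in, run_simulation
from .regions import ArchParams, RegionArchitecture, sample_region

__all__ = [
    "ExperimentPlan",
    "full_plan",
    "desk_plan",
    "run_experiment",
    "merge_region_features",
]

log = logging.getLogger("divergesim")

REGIMES = ("pheno_div", "pheno_null", "neutral")

# spawn-key kinds for hierarchical seed derivation
_KIND_COHORT, _KIND_BURN_STAB, _KIND_BURN_NEUTRAL, _KIND_RUN = 0, 1, 2, 3


@dataclass
class ExperimentPlan:
    """A fully specified experiment: parameters, grid, cohort settings."""

    params: SimParams
    treatments: list[TreatmentSpec]
    regimes: tuple[str, ...] = REGIMES
    n_regions: int = 100
    region_length: int = 25_000
    iterations: int = 20
    master_seed: int = 0
    arch_params: ArchParams | None = None

    def __post_init__(self) -> None:
        labels = [t.label for t in self.treatments]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate treatments in plan")

    def cohort(self) -> list[RegionArchitecture]:
        ss = np.random.SeedSequence(self.master_seed, spawn_key=(_KIND_COHORT,))
        arch = self.arch_params or ArchParams().scaled_to(self.region_length)
        children = ss.spawn(self.n_regions)
        return [
            sample_region(child, region_id=i, length=self.region_length,
                          arch_params=arch)
            for i, child in enumerate(children)
        ]

    def expected_rows(self) -> int:
        from .engine import sampling_generations

        return (
            self.n_regions * len(self.treatments) * len(self.regimes)
            * self.iterations * len(sampling_generations(self.params.run_gens))
        )


def full_plan(master_seed: int = 0, regimes: tuple[str, ...] = REGIMES) -> ExperimentPlan:
    """The full-scale profile: 100 regions x 16 treatments x 20 iterations,
    N = 1000, 25 kb regions, 10,000 + 10,000 generations."""
    params = SimParams()
    return ExperimentPlan(
        params=params,
        treatments=full_grid(params.ap_n),
        regimes=regimes,
        n_regions=100,
        region_length=25_000,
        iterations=20,
        master_seed=master_seed,
    )


def desk_plan(
    master_seed: int = 0,
    regimes: tuple[str, ...] = REGIMES,
    n_regions: int = 16,
    iterations: int = 5,
    ap_n: int = 100,
    region_length: int = 2_500,
    gens: int = 1_000,
) -> ExperimentPlan:
    """Scaled-down desk profile for development, tests and quick replication.

    N = 100 with the 10x mutation/recombination scaling (mu = 4.89e-5,
    r = 1e-5) matches the full profile's theta per site (4*N*mu = 0.0196),
    and migration (m = 0.02) is scaled by the same factor to preserve
    4*N*m; a run is two orders of magnitude cheaper.  Selection stays on its
    absolute scale, mirroring how the full profile's own mutation-rate
    scalings are treated as populations of larger effective size with
    unchanged fitness functions.  The treatment grid keeps both
    prolonged-bottleneck extremes and both migration levels (no founding
    bottleneck), the factors with first-order effects at full scale.
    """
    params = SimParams(
        ap_n=ap_n, mu=4.89e-5, r=1e-5,
        burn_in_gens=gens, run_gens=gens,
    )
    treatments = [
        TreatmentSpec(ap_n, dp_fraction, m)
        for dp_fraction in (0.1, 1.0)
        for m in (0.0, 0.02)
    ]
    return ExperimentPlan(
        params=params,
        treatments=treatments,
        regimes=regimes,
        n_regions=n_regions,
        region_length=region_length,
        iterations=iterations,
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# execution
# ---------------------------------------------------------------------------

def _cell_key(region_id: int, t_label: str, regime: str, iteration: int) -> str:
    return f"{region_id}|{t_label}|{regime}|{iteration}"


def _group_rows(
    plan: ExperimentPlan,
    region: RegionArchitecture,
    iteration: int,
    done: set[str],
) -> list[dict]:
    """Run all (treatment, regime) cells of one (region, iteration) group,
    sharing burn-ins, skipping completed cells."""
    params = plan.params
    needed = {
        (t, rg)
        for t in plan.treatments
        for rg in plan.regimes
        if _cell_key(region.region_id, t.label, rg, iteration) not in done
    }
    if not needed:
        return []

    burns: dict[int, object] = {}

    def burn_for(regime: str):
        kind = _KIND_BURN_NEUTRAL if regime == "neutral" else _KIND_BURN_STAB
        if kind not in burns:
            ss = np.random.SeedSequence(
                plan.master_seed, spawn_key=(kind, region.region_id, iteration)
            )
            burns[kind] = run_burn_in(region, params.with_regime(
                "neutral" if kind == _KIND_BURN_NEUTRAL else "pheno_null"), ss)
        return burns[kind]

    rows: list[dict] = []
    for t_idx, treatment in enumerate(plan.treatments):
        for rg_idx, regime in enumerate(plan.regimes):
            if (treatment, regime) not in needed:
                continue
            run_ss = np.random.SeedSequence(
                plan.master_seed,
                spawn_key=(_KIND_RUN, region.region_id, t_idx, rg_idx, iteration),
            )
            result = run_simulation(
                region, treatment, params.with_regime(regime), run_ss,
                burn_in_state=burn_for(regime).copy(),
            )
            if result.zero_fitness_warnings:
                log.warning(
                    "region %d %s %s iter %d: %d zero-fitness generations "
                    "fell back to uniform parent choice",
                    region.region_id, treatment.label, regime, iteration,
                    result.zero_fitness_warnings,
                )
            for rec in result.records:
                rows.append({
                    "region_id": region.region_id,
                    "treatment": treatment.label,
                    "founders": treatment.founders,
                    "dp_fraction": treatment.dp_fraction,
                    "migration": treatment.migration,
                    "regime": regime,
                    "iteration": iteration,
                    **rec,
                })
    return rows


_SORT_KEYS = ["region_id", "treatment", "regime", "iteration", "generation"]


def run_experiment(
    plan: ExperimentPlan,
    out_dir: str | Path | None = None,
    threads: int = 1,
    resume: bool = False,
) -> pd.DataFrame:
    """Run every cell of the plan and return the tidy records table.

    With ``out_dir``, completed cells are checkpointed (``manifest.txt`` +
    ``records.tsv``) and skipped on resume; a manifest that does not match the
    records file is refused.
    """
    cohort = plan.cohort()
    done: set[str] = set()
    prior = pd.DataFrame()
    manifest_path = records_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest_path = out_dir / "manifest.txt"
        records_path = out_dir / "records.tsv"
        meta_path = out_dir / "metadata.json"
        if resume and manifest_path.exists():
            done = set(manifest_path.read_text().split())
            if not records_path.exists():
                raise RuntimeError(
                    f"checkpoint at {out_dir} has a manifest but no records "
                    "table; remove the directory and restart cleanly"
                )
            prior = pd.read_csv(records_path, sep="\t")
            have = {
                _cell_key(r, t, rg, it)
                for r, t, rg, it in prior[
                    ["region_id", "treatment", "regime", "iteration"]
                ].drop_duplicates().itertuples(index=False)
            }
            if not done <= have:
                raise RuntimeError(
                    f"checkpoint at {out_dir} is corrupt (manifest lists cells "
                    "missing from records.tsv); remove it and restart cleanly"
                )
        elif manifest_path.exists() and not resume:
            raise RuntimeError(
                f"{out_dir} already contains a checkpoint; pass resume=True "
                "or choose a fresh directory"
            )
        meta_path.write_text(json.dumps({
            "master_seed": plan.master_seed,
            "iterations": plan.iterations,
            "n_regions": plan.n_regions,
            "region_length": plan.region_length,
            "treatments": [t.label for t in plan.treatments],
            "regimes": list(plan.regimes),
            "params": {k: getattr(plan.params, k)
                       for k in plan.params.__dataclass_fields__},
        }, indent=2))

    groups = [(region, it) for region in cohort for it in range(plan.iterations)]

    def run_group(args):
        region, it = args
        return _group_rows(plan, region, it, done)

    if threads > 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=threads)(delayed(run_group)(g) for g in groups)
    else:
        chunks = [run_group(g) for g in groups]

    new_rows = [row for chunk in chunks for row in chunk]
    table = pd.DataFrame(new_rows)
    if not prior.empty:
        table = pd.concat([prior, table], ignore_index=True)
    if not table.empty:
        table = table.sort_values(_SORT_KEYS, kind="mergesort").reset_index(drop=True)

    if out_dir is not None and not table.empty:
        table.to_csv(records_path, sep="\t", index=False)
        keys = sorted({
            _cell_key(r, t, rg, it)
            for r, t, rg, it in table[
                ["region_id", "treatment", "regime", "iteration"]
            ].drop_duplicates().itertuples(index=False)
        })
        manifest_path.write_text("\n".join(keys) + "\n")
    return table


def merge_region_features(records: pd.DataFrame,
                          cohort: list[RegionArchitecture]) -> pd.DataFrame:
    """Attach per-region gene features (S, exon count, gene length, coding
    fraction) to a records table, keyed on ``region_id``."""
    feats = pd.DataFrame([
        {
            "region_id": r.region_id,
            "S": r.S,
            "S_sigma": r.S_sigma,
            "exon_n": r.exon_n,
            "gene_length": r.gene_length,
            "selection_target": r.selection_target,
        }
        for r in cohort
    ])
    return records.merge(feats, on="region_id", how="left", validate="many_to_one")
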