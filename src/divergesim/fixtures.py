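"""Miniature synthetic stand-ins for every analysis stage's input.

These generators produce records tables with the exact shape of simulator
output (region x treatment x regime x iteration x generation rows) but with
values drawn from known distributions, so the correlation, outlier,
permutation, overlap and mixed-model stages can be tested against analytic
ground truth in milliseconds.  They share the TSV contracts of the production
stages; they do not emulate linkage structure within regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DivergenceFixtureSpec",
    "make_divergence_fixture",
    "make_spikein_pools",
    "make_block_overlap_sets",
    "random_haplotype_pair",
]

MEASURES = ("fst", "dxy", "delta_pi")


@dataclass(frozen=True)
class DivergenceFixtureSpec:
    """Distributional knobs for a synthetic records table.

    ``injected_r`` sets the exact population Pearson correlation between each
    measure and the per-region selection strength S ~ Uniform(-1, 1);
    ``location``/``scale`` shift and scale each measure per treatment.
    """

    n_regions: int = 100
    n_iterations: int = 20
    treatments: tuple[str, ...] = ("T0",)
    generations: tuple[int, ...] = (10_000,)
    regime: str = "pheno_div"
    seed: int = 0
    injected_r: dict = field(default_factory=dict)       # measure -> r
    location: dict = field(default_factory=dict)         # measure or (measure, treatment) -> mu
    scale: dict = field(default_factory=dict)

    def loc(self, measure: str, treatment: str) -> float:
        return self.location.get((measure, treatment),
                                 self.location.get(measure, 0.0))

    def scl(self, measure: str, treatment: str) -> float:
        return self.scale.get((measure, treatment), self.scale.get(measure, 1.0))


def make_divergence_fixture(spec: DivergenceFixtureSpec) -> pd.DataFrame:
    """Records table with known measure~S correlations.

    Each measure is ``loc + scale * (r * S/sd(S) + sqrt(1-r^2) * eps)`` with
    eps ~ N(0,1) independent per record, which has population correlation
    exactly ``r`` with S.  Returns the standard records schema plus an ``S``
    column and demographic factor columns parsed from nothing (set to 0).
    """
    rng = np.random.default_rng(spec.seed)
    for m, r in spec.injected_r.items():
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"injected_r[{m!r}] out of [-1, 1]")
        if m not in MEASURES:
            raise ValueError(f"unknown measure {m!r}")
    S = rng.uniform(-1.0, 1.0, spec.n_regions)
    s_std = (S - S.mean()) / S.std(ddof=0)
    rows = []
    for trt in spec.treatments:
        for gen in spec.generations:
            for it in range(spec.n_iterations):
                vals = {}
                for m in MEASURES:
                    r = float(spec.injected_r.get(m, 0.0))
                    eps = rng.standard_normal(spec.n_regions)
                    base = r * s_std + np.sqrt(1.0 - r * r) * eps
                    vals[m] = spec.loc(m, trt) + spec.scl(m, trt) * base
                for i in range(spec.n_regions):
                    rows.append({
                        "region_id": i,
                        "treatment": trt,
                        "founders": 0,
                        "dp_fraction": 0.0,
                        "migration": 0.0,
                        "regime": spec.regime,
                        "iteration": it,
                        "generation": gen,
                        "fst": vals["fst"][i],
                        "dxy": vals["dxy"][i],
                        "delta_pi": vals["delta_pi"][i],
                        "pi_ap": np.nan,
                        "pi_dp": np.nan,
                        "pheno_gen": gen,
                        "pheno_censored": False,
                        "S": S[i],
                    })
    return pd.DataFrame(rows)


def make_spikein_pools(
    n_regions: int = 100,
    n_iterations: int = 20,
    shift: float = 0.0,
    seed: int = 0,
    treatment: str = "T0",
    generation: int = 10_000,
    measure_corr: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Neutral and divergent pools for the spike-in permutation.

    Neutral values are standard normal per measure; divergent values are
    shifted by ``shift`` standard deviations on every measure (0 makes the
    pools exchangeable, large values perfectly separable).  ``measure_corr``
    optionally correlates the three measures within a record.
    """
    rng = np.random.default_rng(seed)

    def pool(n_iter: int, loc: float, regime: str) -> pd.DataFrame:
        n = n_regions * n_iter
        if measure_corr:
            shared = rng.standard_normal(n)
            draws = {
                m: np.sqrt(measure_corr) * shared
                + np.sqrt(1 - measure_corr) * rng.standard_normal(n)
                for m in MEASURES
            }
        else:
            draws = {m: rng.standard_normal(n) for m in MEASURES}
        return pd.DataFrame({
            "region_id": np.tile(np.arange(n_regions), n_iter),
            "iteration": np.repeat(np.arange(n_iter), n_regions),
            "treatment": treatment,
            "generation": generation,
            "regime": regime,
            **{m: loc + draws[m] for m in MEASURES},
        })

    return pool(n_iterations, 0.0, "neutral"), pool(n_iterations, shift, "pheno_div")


def make_block_overlap_sets(
    blocks: tuple[tuple[str, ...], ...],
    n_perm: int = 50,
    n_regions: int = 2000,
    set_size: int = 100,
    within_block_overlap: float = 0.9,
    seed: int = 0,
) -> dict[str, list[set]]:
    """Per-treatment outlier region sets with block structure.

    Treatments within a block draw ``within_block_overlap`` of each set from
    a shared per-permutation core; the rest (and everything, across blocks)
    is independent, giving high within-block and near-chance between-block
    overlap for testing the overlap matrix and its clustering.
    """
    rng = np.random.default_rng(seed)
    n_core = int(round(within_block_overlap * set_size))
    out: dict[str, list[set]] = {t: [] for block in blocks for t in block}
    for _ in range(n_perm):
        for block in blocks:
            core = set(rng.choice(n_regions, n_core, replace=False).tolist())
            for t in block:
                extra = set()
                while len(extra) < set_size - n_core:
                    extra = set(
                        rng.choice(n_regions, set_size - n_core, replace=False).tolist()
                    ) - core
                out[t].append(core | extra)
    return out


def random_haplotype_pair(
    rng: np.random.Generator,
    n_ap: int = 10,
    n_dp: int = 8,
    n_sites: int = 30,
    maf_alpha: float = 0.5,
):
    """Small random 0/1 haplotype matrices for brute-force statistic oracles."""
    p_ap = rng.beta(maf_alpha, maf_alpha, n_sites)
    p_dp = rng.beta(maf_alpha, maf_alpha, n_sites)
    ap = (rng.random((n_ap, n_sites)) < p_ap).astype(np.uint8)
    dp = (rng.random((n_dp, n_sites)) < p_dp).astype(np.uint8)
    return ap, dp
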