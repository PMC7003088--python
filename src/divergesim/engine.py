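"""Diploid two-deme Wright-Fisher forward simulator.

The model: a single ancestral population of ``AP_N`` diploid hermaphrodites
evolves for a burn-in period under Gaussian stabilizing selection around a
phenotypic optimum of 0 (or neutrally, in the neutral regime).  It then splits
into an ancestral-phenotype population AP (all ``AP_N`` individuals) and a
diverged-phenotype population DP founded by ``BN`` individuals sampled without
replacement; from the next generation DP is held at ``dp_fraction * AP_N``.
AP keeps the ancestral optimum; DP's optimum moves to 10 (divergent regime)
or stays at 0 (null regime), with fitness-function SD ``S_sigma = 10**-S``
set per region.  Symmetric migration moves offspring parentage across demes
at rate ``m``.

Phenotypes are the dosage-additive sum of effect sizes of exonic
non-synonymous mutations (effects ~ Normal(0, mu_sigma); synonymous and
non-coding mutations are neutral).  Fitness combines Gaussian stabilizing
selection with a density-dependent cost of phenotypic similarity
(competition): ``w = w_sel / (1 + C/N)`` by default.

Haplotypes are rows of a 0/1 matrix over currently segregating sites; sites
fixed in all demes are folded into per-deme phenotype offsets, and (without
migration) sites privately fixed in one deme and lost in the other move to a
per-deme substitution ledger so that D_XY and F_ST are purge-invariant.

Generation order: fitness -> parent choice (with migration) -> recombination
-> mutation -> fixation purge.  Parent sampling works in log-fitness space
shifted by the per-deme maximum, which is mathematically identical to
sampling proportional to raw fitness but immune to underflow when a deme is
far from a steep optimum.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, replace

import numpy as np

from . import stats as _stats
from .regions import RegionArchitecture

__all__ = [
    "SimParams",
    "TreatmentSpec",
    "SimResult",
    "phenotype",
    "selection_fitness",
    "competition_penalty",
    "total_fitness",
    "sampling_generations",
    "run_burn_in",
    "split_populations",
    "step_generation",
    "run_simulation",
    "CLS_NONCODING",
    "CLS_SYN",
    "CLS_NONSYN",
]

CLS_NONCODING, CLS_SYN, CLS_NONSYN = 0, 1, 2

# sampling points as fractions of the divergence period; at the full
# 10,000-generation profile these are generations 100, 500, 1000, 2000 ... 10000
SAMPLING_FRACTIONS = (
    0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
)
WINDOW = 20  # generations averaged before each sampling point
_PURGE_INTERVAL = 25  # generations between hygiene purges of inert columns


@dataclass(frozen=True)
class SimParams:
    """Simulation parameters (defaults are the full-scale profile).

    ``mu`` and ``r`` are per-bp per-generation rates; alternates scale both
    100-fold up or down to vary theta = 4*N*mu.  ``c_dist`` truncates the
    competition kernel at 3 * ``c_sigma``.
    """

    ap_opt: float = 0.0
    ap_s_sigma: float = 1.0
    ap_n: int = 1000
    dp_div_opt: float = 10.0
    mu: float = 4.89e-6
    mu_sigma: float = 1.0
    r: float = 1.0e-6
    c_max: float = 1.0
    c_sigma: float = 0.4
    c_dist: float = 1.2
    burn_in_gens: int = 10_000
    run_gens: int = 10_000
    nonsyn_fraction: float = 0.7
    regime: str = "pheno_div"  # pheno_div | pheno_null | neutral
    fitness_combination: str = "density"  # density | multiplicative
    purge_private_fixed: bool = True
    selection_scale: float = 1.0  # multiplies log fitness (2Ns rescaling)

    def __post_init__(self) -> None:
        if self.regime not in ("pheno_div", "pheno_null", "neutral"):
            raise ValueError(f"unknown regime {self.regime!r}")
        for name in ("mu", "r", "c_max", "c_sigma", "c_dist", "mu_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def dp_opt(self) -> float:
        return self.dp_div_opt if self.regime == "pheno_div" else self.ap_opt

    @property
    def neutral(self) -> bool:
        return self.regime == "neutral"

    def with_regime(self, regime: str) -> "SimParams":
        return replace(self, regime=regime)


@dataclass(frozen=True)
class TreatmentSpec:
    """One cell of the factorial demography grid.

    ``founders``: individuals sampled from the burn-in population to found DP
    (founding bottleneck).  ``dp_fraction``: DP's long-term size as a fraction
    of ``ap_n`` (prolonged bottleneck).  ``migration``: symmetric per-offspring
    probability of cross-deme parentage.
    """

    founders: int
    dp_fraction: float
    migration: float

    def dp_n(self, ap_n: int) -> int:
        n = int(round(self.dp_fraction * ap_n))
        if n < 1:
            raise ValueError("dp_fraction too small for this ap_n")
        return n

    @property
    def label(self) -> str:
        return f"BN{self.founders}_DP{self.dp_fraction:g}_M{self.migration:g}"


def full_grid(ap_n: int = 1000) -> list[TreatmentSpec]:
    """The 16-treatment factorial: {0.1,1.0} founders x 4 DP sizes x 2 m."""
    grid = []
    for bn_frac in (0.1, 1.0):
        for dp_fraction in (0.01, 0.1, 0.5, 1.0):
            for m in (0.0, 0.002):
                grid.append(
                    TreatmentSpec(int(round(bn_frac * ap_n)), dp_fraction, m)
                )
    return grid


# ---------------------------------------------------------------------------
# pure fitness-model operations
# ---------------------------------------------------------------------------

def phenotype(hap_a: np.ndarray, hap_b: np.ndarray, effects: np.ndarray,
              offset: float = 0.0) -> float:
    """Additive phenotype of a diploid genome: dosage-weighted sum of effects
    plus the contribution of fixed (purged) mutations."""
    dosage = np.asarray(hap_a, dtype=np.float64) + np.asarray(hap_b, dtype=np.float64)
    return float(dosage @ np.asarray(effects, dtype=np.float64) + offset)


def selection_fitness(z, optimum: float, s_sigma: float):
    """Gaussian fitness, rescaled so the optimum has fitness exactly 1."""
    if s_sigma <= 0:
        raise ValueError("s_sigma must be > 0")
    z = np.asarray(z, dtype=np.float64)
    out = np.exp(-((z - optimum) ** 2) / (2.0 * s_sigma**2))
    return float(out) if out.ndim == 0 else out


def competition_penalty(z, c_max: float = 1.0, c_sigma: float = 0.4,
                        c_dist: float = 1.2) -> np.ndarray:
    """Summed fitness cost of phenotypic proximity to other individuals.

    Reciprocal by construction: each pair within ``c_dist`` contributes
    ``c_max * exp(-d^2 / (2 c_sigma^2))`` to both members.
    """
    z = np.atleast_1d(np.asarray(z, dtype=np.float64))
    d = np.abs(z[:, None] - z[None, :])
    k = c_max * np.exp(-(d**2) / (2.0 * c_sigma**2))
    k[d > c_dist] = 0.0
    np.fill_diagonal(k, 0.0)
    return k.sum(axis=1)

def total_fitness(z, optimum: float, s_sigma: float, params: SimParams) -> np.ndarray:
    """Per-individual fitness combining selection and competition."""
    z = np.atleast_1d(np.asarray(z, dtype=np.float64))
    n = len(z)
    w = selection_fitness(z, optimum, s_sigma)
    if params.c_max > 0 and n > 1:
        c = competition_penalty(z, params.c_max, params.c_sigma, params.c_dist)
        if params.fitness_combination == "density":
            w = w / (1.0 + c / n)
        else:
            w = w * np.exp(-c / n)
    return np.atleast_1d(w)


# ---------------------------------------------------------------------------
# population state
# ---------------------------------------------------------------------------

class PopulationState:
    """One or two demes sharing a segregating-site registry.

    ``G[i]`` is a ``(2*size_i, capacity)`` uint8 matrix; only the first
    ``ncols`` columns are live.  ``pheno_offset[i]`` accumulates ``2*effect``
    for every mutation fixed in deme ``i`` (including the burn-in ancestor);
    ``fixed_private[i]`` counts substitutions private to deme ``i`` that were
    purged from the matrices (only populated without migration).
    """

    def __init__(self, sizes: list[int], length: int, capacity: int = 256):
        self.length = length
        self.sizes = list(sizes)
        self.G = [np.zeros((2 * n, capacity), dtype=np.uint8) for n in sizes]
        self.pos = np.zeros(capacity, dtype=np.int64)
        self.eff = np.zeros(capacity, dtype=np.float64)
        self.cls = np.zeros(capacity, dtype=np.int8)
        self.origin = np.zeros(capacity, dtype=np.int64)
        self.ncols = 0
        self.pheno_offset = [0.0 for _ in sizes]
        self.fixed_private = [0 for _ in sizes]
        self.generation = 0
        self.zero_fitness_warnings = 0
        self.migrant_offspring = 0

    # -- bookkeeping ------------------------------------------------------
    @property
    def capacity(self) -> int:
        return self.pos.shape[0]

    def copy(self) -> "PopulationState":
        return _copy.deepcopy(self)

    def _grow(self, needed: int) -> None:
        new_cap = max(2 * self.capacity, needed)
        for name in ("pos", "eff", "cls", "origin"):
            old = getattr(self, name)
            grown = np.zeros(new_cap, dtype=old.dtype)
            grown[: self.ncols] = old[: self.ncols]
            setattr(self, name, grown)
        for i, g in enumerate(self.G):
            grown = np.zeros((g.shape[0], new_cap), dtype=np.uint8)
            grown[:, : self.ncols] = g[:, : self.ncols]
            self.G[i] = grown

    def append_mutations(self, pos, eff, cls) -> np.ndarray:
        n_new = len(pos)
        if self.ncols + n_new > self.capacity:
            self._grow(self.ncols + n_new)
        cols = np.arange(self.ncols, self.ncols + n_new)
        self.pos[cols] = pos
        self.eff[cols] = eff
        self.cls[cols] = cls
        self.origin[cols] = self.generation
        for g in self.G:
            g[:, cols] = 0
        self.ncols += n_new
        return cols

    def compact(self, keep: np.ndarray) -> None:
        idx = np.flatnonzero(keep)
        k = len(idx)
        for name in ("pos", "eff", "cls", "origin"):
            arr = getattr(self, name)
            arr[:k] = arr[: self.ncols][idx]
        for g in self.G:
            g[:, :k] = g[:, : self.ncols][:, idx]
        self.ncols = k

    def counts(self) -> list[np.ndarray]:
        return [g[:, : self.ncols].sum(axis=0, dtype=np.int64) for g in self.G]

    def phenotypes(self, i: int) -> np.ndarray:
        g = self.G[i][:, : self.ncols]
        dosage = (g[0::2] + g[1::2]).astype(np.float64)
        return dosage @ self.eff[: self.ncols] + self.pheno_offset[i]

    # -- statistics -------------------------------------------------------
    def divergence_stats(self, counts: list[np.ndarray] | None = None) -> dict:
        """Instantaneous pi_AP, pi_DP, F_ST, D_XY, delta-pi for a two-deme state."""
        if len(self.sizes) != 2:
            raise ValueError("divergence statistics require two demes")
        if counts is None:
            counts = self.counts()
        c_ap, c_dp = counts
        n_ap, n_dp = 2 * self.sizes[0], 2 * self.sizes[1]
        pi_ap = _stats.pi_from_counts(c_ap, n_ap, self.length)
        pi_dp = _stats.pi_from_counts(c_dp, n_dp, self.length)
        return {
            "pi_ap": pi_ap,
            "pi_dp": pi_dp,
            "fst": _stats.fst_from_counts(
                c_ap, n_ap, c_dp, n_dp, self.fixed_private[0], self.fixed_private[1]
            ),
            "dxy": _stats.dxy_from_counts(
                c_ap, n_ap, c_dp, n_dp, self.length,
                self.fixed_private[0], self.fixed_private[1],
            ),
            "delta_pi": _stats.delta_pi(pi_ap, pi_dp),
        }


# ---------------------------------------------------------------------------
# generation step
# ---------------------------------------------------------------------------

def _parent_cdf(z: np.ndarray, optimum: float, s_sigma: float,
                params: SimParams) -> np.ndarray | None:
    """Cumulative parenting weights; None means uniform (neutral/degenerate).

    Selection is evaluated in log space and shifted by the deme maximum before
    exponentiation, which leaves the sampling distribution unchanged while
    avoiding underflow far from steep optima.  ``params.selection_scale``
    multiplies the combined log fitness, the standard rescaling that keeps
    2Ns invariant when a scaled-down profile shrinks N.
    """
    n = len(z)
    logw = -((z - optimum) ** 2) / (2.0 * s_sigma**2)
    if params.c_max > 0 and n > 1:
        c = competition_penalty(z, params.c_max, params.c_sigma, params.c_dist)
        if params.fitness_combination == "density":
            logw = logw - np.log1p(c / n)
        else:
            logw = logw - c / n
    if params.selection_scale != 1.0:
        logw = logw * params.selection_scale
    w = np.exp(logw - logw.max())
    cdf = np.cumsum(w)
    if not np.isfinite(cdf[-1]) or cdf[-1] <= 0.0:
        return None
    return cdf


def _draw_parents(cdf: np.ndarray | None, n_parents: int, n_draws: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Fitness-proportional parent indices (inverse-CDF sampling)."""
    if cdf is None:
        return rng.integers(0, n_parents, n_draws)
    u = rng.random(n_draws) * cdf[-1]
    return np.searchsorted(cdf, u, side="right").clip(0, n_parents - 1)


def _gametes(state: PopulationState, src: int, parent_idx: np.ndarray,
             rng: np.random.Generator, r: float) -> np.ndarray:
    """One recombinant gamete per parent index: crossover count ~ Poisson(r*L),
    breakpoints uniform, starting haplotype random."""
    g_src = state.G[src]
    ncols, L = state.ncols, state.length
    n = len(parent_idx)
    start = rng.integers(0, 2, n)
    k = rng.poisson(r * L, n) if r > 0 else np.zeros(n, dtype=np.int64)
    out = g_src[:, :ncols][2 * parent_idx + start]
    for i in np.flatnonzero(k > 0):
        p = parent_idx[i]
        bp = np.sort(rng.integers(1, L, k[i]))
        seg = np.searchsorted(bp, state.pos[:ncols], side="right")
        hap = (start[i] + seg) % 2
        out[i] = np.where(hap == 0, g_src[2 * p][:ncols], g_src[2 * p + 1][:ncols])
    return out


def step_generation(
    state: PopulationState,
    params: SimParams,
    region: RegionArchitecture,
    rng: np.random.Generator,
    migration: float = 0.0,
    next_sizes: list[int] | None = None,
    exon_mask: np.ndarray | None = None,
    phenotypes: list[np.ndarray] | None = None,
    need_counts: bool = True,
) -> list[np.ndarray] | None:
    """Advance the state by one Wright-Fisher generation in place.

    With ``need_counts`` (default) the fixation purge runs and the per-deme
    derived-allele counts of the offspring generation are returned for use by
    windowed statistics; otherwise the purge is deferred (fixed and lost
    columns are statistically inert) and run only periodically for hygiene.
    ``phenotypes`` optionally passes pre-computed parent phenotypes (one
    array per deme) to avoid recomputation.
    """
    n_pops = len(state.sizes)
    sizes_next = list(next_sizes) if next_sizes is not None else list(state.sizes)
    if exon_mask is None:
        exon_mask = region.exon_mask()

    # fitness of the parental generation
    probs: list[np.ndarray | None] = []
    if params.neutral:
        probs = [None] * n_pops
    else:
        optima = [params.ap_opt] + ([params.dp_opt] if n_pops == 2 else [])
        sigmas = [params.ap_s_sigma] + ([region.S_sigma] if n_pops == 2 else [])
        for i in range(n_pops):
            z = phenotypes[i] if phenotypes is not None else state.phenotypes(i)
            p = _parent_cdf(z, optima[i], sigmas[i], params)
            if p is None and len(z) > 1:
                state.zero_fitness_warnings += 1
            probs.append(p)

    # parent choice + recombination
    new_G = []
    for i in range(n_pops):
        n_off = sizes_next[i]
        g_new = np.zeros((2 * n_off, state.capacity), dtype=np.uint8)
        if n_pops == 2 and migration > 0.0:
            mig = rng.random(n_off) < migration
        else:
            mig = np.zeros(n_off, dtype=bool)
        for is_mig in (False, True):
            slots = np.flatnonzero(mig == is_mig)
            if len(slots) == 0:
                continue
            src = (1 - i) if is_mig else i
            n_src = state.sizes[src]
            for half in (0, 1):
                parents = _draw_parents(probs[src], n_src, len(slots), rng)
                g_new[2 * slots + half, : state.ncols] = _gametes(
                    state, src, parents, rng, params.r
                )
            if is_mig:
                state.migrant_offspring += len(slots)
        new_G.append(g_new)

    state.G = new_G
    state.sizes = sizes_next
    state.generation += 1

    # new mutations: one registry column each, carried by a single gamete
    for i in range(n_pops):
        n_gametes = 2 * state.sizes[i]
        n_new = rng.poisson(params.mu * state.length * n_gametes)
        if n_new == 0:
            continue
        rows = rng.integers(0, n_gametes, n_new)
        pos_new = rng.integers(0, state.length, n_new)
        in_exon = exon_mask[pos_new]
        is_nonsyn = in_exon & (rng.random(n_new) < params.nonsyn_fraction)
        cls_new = np.where(
            is_nonsyn, CLS_NONSYN, np.where(in_exon, CLS_SYN, CLS_NONCODING)
        ).astype(np.int8)
        eff_new = np.zeros(n_new)
        if not params.neutral and is_nonsyn.any():
            idx = np.flatnonzero(is_nonsyn)
            eff_new[idx] = rng.normal(0.0, params.mu_sigma, len(idx))
        cols = state.append_mutations(pos_new, eff_new, cls_new)
        state.G[i][rows, cols] = 1

    if need_counts or state.generation % _PURGE_INTERVAL == 0:
        return _purge_fixed(state, params, migration)
    return None


def _purge_fixed(state: PopulationState, params: SimParams,
                 migration: float) -> list[np.ndarray]:
    """Drop globally lost/fixed columns; record substitutions.  Returns the
    post-purge per-deme derived-allele counts."""
    counts = state.counts()
    eff = state.eff[: state.ncols]
    if len(state.sizes) == 1:
        c = counts[0]
        n_hap = 2 * state.sizes[0]
        fixed = c == n_hap
        drop = (c == 0) | fixed
        if fixed.any():
            state.pheno_offset[0] += 2.0 * eff[fixed].sum()
    else:
        c_a, c_b = counts
        na, nb = 2 * state.sizes[0], 2 * state.sizes[1]
        fixed_all = (c_a == na) & (c_b == nb)
        drop = ((c_a == 0) & (c_b == 0)) | fixed_all
        if fixed_all.any():
            shared = 2.0 * eff[fixed_all].sum()
            state.pheno_offset[0] += shared
            state.pheno_offset[1] += shared
        if migration == 0.0 and params.purge_private_fixed:
            priv_a = (c_a == na) & (c_b == 0)
            priv_b = (c_b == nb) & (c_a == 0)
            if priv_a.any():
                state.fixed_private[0] += int(priv_a.sum())
                state.pheno_offset[0] += 2.0 * eff[priv_a].sum()
                drop |= priv_a
            if priv_b.any():
                state.fixed_private[1] += int(priv_b.sum())
                state.pheno_offset[1] += 2.0 * eff[priv_b].sum()
                drop |= priv_b
    if drop.any():
        keep = ~drop
        state.compact(keep)
        counts = [c[keep] for c in counts]
    return counts


# ---------------------------------------------------------------------------
# run-level operations
# ---------------------------------------------------------------------------

def _rng_from(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def run_burn_in(region: RegionArchitecture, params: SimParams,
                seed) -> PopulationState:
    """Evolve a single population of ``ap_n`` toward the ancestral optimum
    for ``burn_in_gens`` generations (neutrally in the neutral regime)."""
    rng = _rng_from(seed)
    state = PopulationState([params.ap_n], region.length)
    exon_mask = region.exon_mask()
    for _ in range(params.burn_in_gens - 1):
        step_generation(state, params, region, rng, exon_mask=exon_mask,
                        need_counts=False)
    step_generation(state, params, region, rng, exon_mask=exon_mask)
    return state


def split_populations(burn_in_state: PopulationState, treatment: TreatmentSpec,
                      seed, params: SimParams | None = None) -> PopulationState:
    """Found AP (all burn-in individuals) and DP (``founders`` individuals
    sampled without replacement) from a burn-in state."""
    n_burn = burn_in_state.sizes[0]
    if treatment.founders > n_burn:
        raise ValueError(
            f"founders={treatment.founders} exceeds burn-in size {n_burn}"
        )
    rng = _rng_from(seed)
    chosen = np.sort(rng.choice(n_burn, treatment.founders, replace=False))
    rows = np.empty(2 * len(chosen), dtype=np.int64)
    rows[0::2] = 2 * chosen
    rows[1::2] = 2 * chosen + 1

    pair = PopulationState([n_burn, treatment.founders], burn_in_state.length,
                           capacity=burn_in_state.capacity)
    pair.pos = burn_in_state.pos.copy()
    pair.eff = burn_in_state.eff.copy()
    pair.cls = burn_in_state.cls.copy()
    pair.origin = burn_in_state.origin.copy()
    pair.ncols = burn_in_state.ncols
    pair.G[0] = burn_in_state.G[0].copy()
    pair.G[1] = burn_in_state.G[0][rows].copy()
    pair.pheno_offset = [burn_in_state.pheno_offset[0]] * 2
    pair.generation = 0
    return pair


@dataclass
class SimResult:
    """Output of one region x treatment x regime run."""

    records: list[dict]          # one dict per sampling generation
    pheno_gen: int
    pheno_censored: bool
    zero_fitness_warnings: int
    migrant_offspring: int
    final_state: PopulationState | None = None


def sampling_generations(run_gens: int) -> list[int]:
    gens = sorted({max(1, int(round(f * run_gens))) for f in SAMPLING_FRACTIONS})
    return gens


def run_simulation(
    region: RegionArchitecture,
    treatment: TreatmentSpec,
    params: SimParams,
    seed,
    burn_in_state: PopulationState | None = None,
    keep_final_state: bool = False,
) -> SimResult:
    """Burn-in (unless supplied), split, divergence period with windowed
    statistics at the standard sampling generations."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    burn_ss, split_ss, run_ss = ss.spawn(3)
    if burn_in_state is None:
        burn_in_state = run_burn_in(region, params, burn_ss)
    state = split_populations(burn_in_state, treatment, split_ss, params)
    rng = _rng_from(run_ss)
    exon_mask = region.exon_mask()

    sample_gens = sampling_generations(params.run_gens)
    in_window = np.zeros(params.run_gens + 1, dtype=bool)
    for g in sample_gens:
        in_window[max(1, g - WINDOW + 1): g + 1] = True
    is_sample = np.zeros(params.run_gens + 1, dtype=bool)
    is_sample[sample_gens] = True

    dp_n = treatment.dp_n(params.ap_n)
    pheno_target = params.dp_opt - 1.0
    pheno_gen, censored = -1, True
    window_vals: dict[str, list[float]] = {k: [] for k in
                                           ("fst", "dxy", "delta_pi", "pi_ap", "pi_dp")}
    records: list[dict] = []

    for g in range(1, params.run_gens + 1):
        next_sizes = [params.ap_n, dp_n] if g == 1 else None
        if params.neutral:
            z_list = None
        else:
            z_list = [state.phenotypes(0), state.phenotypes(1)]
            if censored and float(np.median(z_list[1])) >= pheno_target:
                pheno_gen, censored = state.generation, False
        counts = step_generation(
            state, params, region, rng,
            migration=treatment.migration, next_sizes=next_sizes,
            exon_mask=exon_mask, phenotypes=z_list,
            need_counts=in_window[g],
        )
        if in_window[g]:
            st = state.divergence_stats(counts)
            for k, v in st.items():
                window_vals[k].append(v)
        if is_sample[g]:
            rec = {"generation": g}
            for k, vals in window_vals.items():
                rec[k] = _stats.window_average(vals)
                window_vals[k] = []
            records.append(rec)

    # final-generation phenotype check (loop checks parents, not last offspring)
    if censored and not params.neutral:
        if float(np.median(state.phenotypes(1))) >= pheno_target:
            pheno_gen, censored = state.generation, False
    if censored:
        pheno_gen = params.run_gens
    for rec in records:
        rec["pheno_gen"] = pheno_gen
        rec["pheno_censored"] = censored
    return SimResult(
        records=records,
        pheno_gen=pheno_gen,
        pheno_censored=censored,
        zero_fitness_warnings=state.zero_fitness_warnings,
        migrant_offspring=state.migrant_offspring,
        final_state=state if keep_final_state else None,
    )
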