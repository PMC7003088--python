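"""Region-wide divergence statistics: pi, F_ST, D_XY and delta-pi.

All statistics are single values per 25 kb region computed over every site,
monomorphic and polymorphic, mirroring window-based genome scans in which each
region plays the role of one window.

Two call surfaces are provided:

* matrix functions (:func:`pi`, :func:`fst`, :func:`dxy`) taking 0/1 haplotype
  matrices (rows = haplotypes, columns = segregating sites), used by tests and
  post-hoc analysis of exported genotypes;
* frequency kernels (``*_from_counts``) used by the simulation engine, which
  tracks derived-allele counts directly.

Both reduce to the same per-site definitions:

* ``pi``: mean pairwise difference per site; per site the unbiased expected
  heterozygosity ``2 p (1-p) n/(n-1)``, summed over sites and divided by the
  region length ``L``.
* ``F_ST = 1 - H_S/H_T`` with ``H_S`` the unweighted mean of the two
  within-population expected heterozygosities summed across sites and ``H_T``
  the expected heterozygosity of the pooled sample, as a ratio of sums over
  the region.  Undefined (NaN) when ``H_T = 0``.
* ``D_XY``: mean per-site difference over all between-population haplotype
  pairs, including substitutions privately fixed in either population since
  the split.
* ``delta_pi = log10(pi_AP / pi_DP)``: positive when the diverged population
  has lost diversity; NaN when either pi is zero.

Populations can privately fix mutations that are then dropped from the
segregating matrices; such substitutions are passed as ``fixed_ap`` /
``fixed_dp`` site counts so that D_XY and F_ST are invariant to the purge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DivergenceRecord",
    "pi",
    "fst",
    "dxy",
    "delta_pi",
    "window_average",
    "pi_from_counts",
    "fst_from_counts",
    "dxy_from_counts",
]


@dataclass(frozen=True)
class DivergenceRecord:
    """One row of the tidy results table.

    Statistics are 20-generation window averages at a sampling generation;
    ``pheno_gen`` is the first generation the diverged population's median
    phenotype came within one unit of its optimum (``pheno_censored`` marks
    runs that never reached it).
    """

    region_id: int
    treatment: str
    regime: str
    iteration: int
    generation: int
    fst: float
    dxy: float
    delta_pi: float
    pi_ap: float
    pi_dp: float
    pheno_gen: int
    pheno_censored: bool


RECORD_COLUMNS = list(DivergenceRecord.__dataclass_fields__)


# ---------------------------------------------------------------------------
# frequency kernels
# ---------------------------------------------------------------------------

def pi_from_counts(counts: np.ndarray, n: int, L: float) -> float:
    """Nucleotide diversity from derived-allele counts at segregating sites."""
    if n < 2:
        raise ValueError("pi requires >= 2 haplotypes")
    p = np.asarray(counts, dtype=np.float64) / n
    het = 2.0 * p * (1.0 - p) * n / (n - 1)
    return float(het.sum() / L)


def fst_from_counts(
    counts_ap: np.ndarray,
    n_ap: int,
    counts_dp: np.ndarray,
    n_dp: int,
    fixed_ap: int = 0,
    fixed_dp: int = 0,
) -> float:
    """F_ST = 1 - sum(H_S)/sum(H_T) over segregating plus privately fixed sites.

    H_T uses the unweighted mean allele frequency of the two demes (Nei's
    convention), so per site H_T = H_S + (p1-p2)^2/2 and F_ST stays in [0, 1]
    even with very unequal deme sizes.
    """
    p1 = np.asarray(counts_ap, dtype=np.float64) / n_ap
    p2 = np.asarray(counts_dp, dtype=np.float64) / n_dp
    hs = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    pbar = (p1 + p2) / 2.0
    ht = 2.0 * pbar * (1.0 - pbar)
    # a substitution private to one deme: H_S = 0, mean frequency 1/2
    ht_fixed = (fixed_ap + fixed_dp) * 0.5
    hs_sum = float(hs.sum())
    ht_sum = float(ht.sum()) + ht_fixed
    if ht_sum == 0.0:
        return float("nan")
    return 1.0 - hs_sum / ht_sum


def dxy_from_counts(
    counts_ap: np.ndarray,
    n_ap: int,
    counts_dp: np.ndarray,
    n_dp: int,
    L: float,
    fixed_ap: int = 0,
    fixed_dp: int = 0,
) -> float:
    """Mean per-site between-population pairwise difference (Nei's d_XY)."""
    p1 = np.asarray(counts_ap, dtype=np.float64) / n_ap
    p2 = np.asarray(counts_dp, dtype=np.float64) / n_dp
    per_site = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    return float((per_site.sum() + fixed_ap + fixed_dp) / L)


# ---------------------------------------------------------------------------
# haplotype-matrix surface
# ---------------------------------------------------------------------------

def _as_matrix(sample: np.ndarray) -> np.ndarray:
    m = np.asarray(sample)
    if m.ndim != 2:
        raise ValueError("haplotype sample must be a 2-D 0/1 matrix")
    return m


def pi(sample: np.ndarray, L: float) -> float:
    """Nucleotide diversity of a haplotype matrix (rows = haplotypes)."""
    m = _as_matrix(sample)
    if m.shape[0] < 2:
        raise ValueError("pi requires >= 2 haplotypes")
    return pi_from_counts(m.sum(axis=0), m.shape[0], L)


def fst(
    ap_sample: np.ndarray,
    dp_sample: np.ndarray,
    fixed_ap: int = 0,
    fixed_dp: int = 0,
) -> float:
    """F_ST between two haplotype matrices sharing a column (site) space."""
    a, d = _as_matrix(ap_sample), _as_matrix(dp_sample)
    if a.shape[0] < 2 or d.shape[0] < 2:
        raise ValueError("fst requires >= 2 haplotypes per population")
    return fst_from_counts(
        a.sum(axis=0), a.shape[0], d.sum(axis=0), d.shape[0], fixed_ap, fixed_dp
    )


def dxy(
    ap_sample: np.ndarray,
    dp_sample: np.ndarray,
    L: float,
    fixed_ap: int = 0,
    fixed_dp: int = 0,
    normalized: bool = True,
) -> float:
    """Between-population divergence; per pair and per site unless
    ``normalized=False``, which returns the raw double sum of pairwise
    differences (audit mode; scales with sample sizes)."""
    a, d = _as_matrix(ap_sample), _as_matrix(dp_sample)
    if a.shape[0] < 1 or d.shape[0] < 1:
        raise ValueError("dxy requires >= 1 haplotype per population")
    val = dxy_from_counts(
        a.sum(axis=0), a.shape[0], d.sum(axis=0), d.shape[0], L, fixed_ap, fixed_dp
    )
    if not normalized:
        val *= a.shape[0] * d.shape[0] * L
    return val


def delta_pi(pi_ap: float, pi_dp: float) -> float:
    """log10 ratio of AP to DP diversity; NaN if either diversity is zero."""
    if pi_ap < 0 or pi_dp < 0:
        raise ValueError("pi values must be non-negative")
    if pi_ap == 0.0 or pi_dp == 0.0:
        return float("nan")
    return float(np.log10(pi_ap / pi_dp))


def window_average(values) -> float:
    """Mean over non-missing per-generation values; NaN if all are missing."""
    arr = np.asarray(values, dtype=np.float64)
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))
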