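import numpy as np
import pandas as pd
import pytest

from divergesim import runner


@pytest.fixture(scope="session")
def micro_plan():
    """A tiny full-factorial plan (all three regimes) used across stage tests."""
    return runner.desk_plan(
        3, n_regions=5, iterations=2, ap_n=50, region_length=1200, gens=200
    )


@pytest.fixture(scope="session")
def micro_table(micro_plan) -> pd.DataFrame:
    return runner.run_experiment(micro_plan)


@pytest.fixture(scope="session")
def micro_features(micro_plan, micro_table) -> pd.DataFrame:
    return runner.merge_region_features(micro_table, micro_plan.cohort())


# ---------------------------------------------------------------------------
# brute-force statistic oracles (independent of divergesim.stats internals)
# ---------------------------------------------------------------------------

def hamming(a: np.ndarray, b: np.ndarray) -> int:
    return int(np.sum(a != b))


def brute_pi(sample: np.ndarray, L: float) -> float:
    """Mean pairwise Hamming distance per site over all haplotype pairs."""
    n = sample.shape[0]
    total = sum(
        hamming(sample[i], sample[j])
        for i in range(n) for j in range(i + 1, n)
    )
    return total / (n * (n - 1) / 2) / L


def brute_dxy(ap: np.ndarray, dp: np.ndarray, L: float,
              fixed_ap: int = 0, fixed_dp: int = 0) -> float:
    """Mean between-population pairwise difference per site; privately fixed
    substitutions differ in every cross-population pair."""
    total = sum(hamming(a, d) for a in ap for d in dp)
    total += (fixed_ap + fixed_dp) * ap.shape[0] * dp.shape[0]
    return total / (ap.shape[0] * dp.shape[0]) / L


def brute_fst(ap: np.ndarray, dp: np.ndarray,
              fixed_ap: int = 0, fixed_dp: int = 0) -> float:
    """Site-by-site 1 - Hs/Ht with explicit python loops (ratio of sums)."""
    hs_sum, ht_sum = 0.0, 0.0
    for s in range(ap.shape[1]):
        p1 = float(np.mean(ap[:, s]))
        p2 = float(np.mean(dp[:, s]))
        hs_sum += (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2)) / 2
        pbar = (p1 + p2) / 2
        ht_sum += 2 * pbar * (1 - pbar)
    ht_sum += (fixed_ap + fixed_dp) * 0.5
    if ht_sum == 0:
        return float("nan")
    return 1 - hs_sum / ht_sum
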