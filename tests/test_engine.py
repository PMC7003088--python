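import numpy as np
import pytest

from divergesim import engine, regions, stats

from conftest import brute_dxy, brute_fst, brute_pi


def tiny_region(seed=1, length=800):
    arch = regions.ArchParams().scaled_to(length)
    return regions.sample_region(seed, 0, length, arch)


def neutral_params(**kw):
    defaults = dict(ap_n=30, mu=1e-4, r=1e-4, regime="neutral",
                    burn_in_gens=60, run_gens=60)
    defaults.update(kw)
    return engine.SimParams(**defaults)


class TestFitnessModel:
    def test_phenotype_additivity(self):
        eff = np.array([0.8, -0.3, 0.0])
        assert engine.phenotype([0, 0, 0], [0, 0, 0], eff) == 0.0
        assert engine.phenotype([1, 0, 0], [0, 0, 0], eff) == pytest.approx(0.8)
        assert engine.phenotype([1, 0, 0], [1, 0, 0], eff) == pytest.approx(1.6)
        assert engine.phenotype([1, 1, 0], [1, 0, 1], eff, offset=2.0) == pytest.approx(
            1.6 - 0.3 + 2.0
        )

    def test_phenotype_matches_dense_dosage_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = int(rng.integers(1, 30))
            h1 = rng.integers(0, 2, s)
            h2 = rng.integers(0, 2, s)
            eff = rng.normal(size=s)
            expected = sum((int(h1[i]) + int(h2[i])) * eff[i] for i in range(s))
            assert engine.phenotype(h1, h2, eff) == pytest.approx(expected)

    def test_selection_fitness_closed_forms(self):
        assert engine.selection_fitness(5.0, 5.0, 2.0) == 1.0
        assert engine.selection_fitness(1.0, 0.0, 1.0) == pytest.approx(np.exp(-0.5))
        assert engine.selection_fitness(0.0, 10.0, 0.1) < 1e-300
        with pytest.raises(ValueError):
            engine.selection_fitness(0.0, 0.0, 0.0)

    def test_competition_closed_forms(self):
        assert engine.competition_penalty(np.array([1.3]))[0] == 0.0
        pair = engine.competition_penalty(np.array([0.0, 0.0]))
        assert pair == pytest.approx([1.0, 1.0])
        edge = engine.competition_penalty(np.array([0.0, 1.2]))
        assert edge[0] == pytest.approx(np.exp(-4.5))
        beyond = engine.competition_penalty(np.array([0.0, 1.2000001]))
        assert beyond[0] == 0.0

    def test_competition_is_reciprocal(self):
        z = np.array([0.1, 0.5, -0.2, 0.35])
        c = engine.competition_penalty(z)
        c_rev = engine.competition_penalty(z[::-1])[::-1]
        assert c == pytest.approx(c_rev)

    def test_total_fitness_shape(self):
        params = engine.SimParams()
        solo = engine.total_fitness(np.array([0.0]), 0.0, 1.0, params)
        assert solo[0] == pytest.approx(1.0)
        # monotone decreasing in |z - optimum| without competition
        flat = engine.SimParams(c_max=0.0)
        z = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        w = engine.total_fitness(z, 0.0, 1.0, flat)
        assert np.all(np.diff(w) < 0)


class TestStepGeneration:
    def test_monomorphic_stays_monomorphic_without_mutation(self):
        reg = tiny_region()
        params = neutral_params(mu=0.0, r=0.0)
        state = engine.PopulationState([20, 10], reg.length)
        rng = np.random.default_rng(0)
        for _ in range(50):
            engine.step_generation(state, params, reg, rng)
        assert state.ncols == 0
        assert state.pheno_offset == [0.0, 0.0]

    def test_no_migration_audit(self):
        reg = tiny_region()
        params = neutral_params()
        tr = engine.TreatmentSpec(30, 1.0, 0.0)
        res = engine.run_simulation(reg, tr, params, 5)
        assert res.migrant_offspring == 0

    def test_migration_produces_migrants(self):
        reg = tiny_region()
        params = neutral_params()
        tr = engine.TreatmentSpec(30, 1.0, 0.05)
        res = engine.run_simulation(reg, tr, params, 5)
        assert res.migrant_offspring > 0

    def test_migration_homogenizes_neutral_fst(self):
        """Paired over seeds, final F_ST is lower with migration than without."""
        reg = tiny_region(seed=2, length=600)
        params = neutral_params(ap_n=40, burn_in_gens=100, run_gens=300)
        diffs = []
        for seed in range(8):
            burn = engine.run_burn_in(reg, params, seed)
            out = {}
            for m in (0.0, 0.05):
                tr = engine.TreatmentSpec(40, 1.0, m)
                res = engine.run_simulation(reg, tr, params, 100 + seed,
                                            burn_in_state=burn.copy())
                out[m] = res.records[-1]["fst"]
            diffs.append(out[0.0] - out[0.05])
        assert np.mean(diffs) > 0

    def test_steep_optimum_far_away_is_numerically_stable(self):
        reg = tiny_region(seed=4)
        params = engine.SimParams(ap_n=20, mu=1e-4, r=0.0, regime="pheno_div",
                                  burn_in_gens=20, run_gens=40)
        tr = engine.TreatmentSpec(20, 1.0, 0.0)
        # steepest selection: region with S close to 1 -> sigma near 0.1
        res = engine.run_simulation(reg, tr, params, 1)
        assert res.zero_fitness_warnings == 0
        assert len(res.records) == 12


class TestSplit:
    def test_founder_counts_and_steady_size(self):
        reg = tiny_region()
        params = neutral_params(ap_n=40)
        burn = engine.run_burn_in(reg, params, 0)
        tr = engine.TreatmentSpec(10, 0.25, 0.0)
        pair = engine.split_populations(burn, tr, 1)
        assert pair.sizes == [40, 10]          # founders
        rng = np.random.default_rng(2)
        engine.step_generation(pair, params, reg, rng,
                               next_sizes=[40, tr.dp_n(40)])
        assert pair.sizes == [40, 10]          # 0.25 * 40
        tr2 = engine.TreatmentSpec(100, 1.0, 0.0)
        with pytest.raises(ValueError, match="exceeds burn-in size"):
            engine.split_populations(burn, tr2, 1)

    def test_full_split_copies_population(self):
        reg = tiny_region()
        params = neutral_params(ap_n=30)
        burn = engine.run_burn_in(reg, params, 3)
        pair = engine.split_populations(burn, engine.TreatmentSpec(30, 1.0, 0.0), 7)
        assert pair.sizes == [30, 30]
        c_ap, c_dp = pair.counts()
        np.testing.assert_array_equal(np.sort(c_ap), np.sort(c_dp))

    def test_founder_frequencies_match_hypergeometric_sampling(self):
        """Standardized founder-frequency shifts have unit-scale variance
        under without-replacement sampling of individuals."""
        reg = tiny_region(seed=6, length=1500)
        params = neutral_params(ap_n=60, mu=2e-4, burn_in_gens=240)
        burn = engine.run_burn_in(reg, params, 11)
        c = burn.counts()[0]
        keep = (c >= 10) & (c <= 110)  # intermediate frequencies
        z2 = []
        for split_seed in range(30):
            pair = engine.split_populations(
                burn, engine.TreatmentSpec(12, 0.2, 0.0), split_seed
            )
            cf = pair.counts()[1]
            p0 = c[keep] / 120.0
            pf = cf[keep] / 24.0
            # hypergeometric draw of 24 from 120 haplotypes
            var = p0 * (1 - p0) * (120 - 24) / (24 * (120 - 1))
            z2.extend(((pf - p0) ** 2 / var).tolist())
        assert 0.5 < np.mean(z2) < 1.7


class TestRunSimulation:
    def test_sampling_schedule_has_twelve_points(self):
        assert engine.sampling_generations(10_000) == [
            100, 500, 1000, 2000, 3000, 4000, 5000,
            6000, 7000, 8000, 9000, 10_000,
        ]
        assert len(engine.sampling_generations(1000)) == 12

    def test_identical_seed_identical_records(self):
        reg = tiny_region(seed=3)
        params = engine.SimParams(ap_n=25, mu=1e-4, r=1e-4, regime="pheno_div",
                                  burn_in_gens=50, run_gens=80)
        tr = engine.TreatmentSpec(25, 0.4, 0.01)
        a = engine.run_simulation(reg, tr, params, 99)
        b = engine.run_simulation(reg, tr, params, 99)
        assert a.records == b.records
        assert a.pheno_gen == b.pheno_gen
        c = engine.run_simulation(reg, tr, params, 100)
        assert c.records != a.records

    def test_private_fixation_purge_does_not_change_statistics(self):
        """With the substitution ledger, purging privately fixed mutations
        leaves every reported statistic identical."""
        import dataclasses

        reg = tiny_region(seed=8)
        base = engine.SimParams(ap_n=15, mu=3e-4, r=1e-4, regime="pheno_div",
                                burn_in_gens=60, run_gens=150)
        tr = engine.TreatmentSpec(15, 0.4, 0.0)
        res_purge = engine.run_simulation(reg, tr, base, 21, keep_final_state=True)
        noprune = dataclasses.replace(base, purge_private_fixed=False)
        res_keep = engine.run_simulation(reg, tr, noprune, 21, keep_final_state=True)
        assert res_purge.final_state.fixed_private != [0, 0]  # ledger exercised
        assert res_keep.final_state.fixed_private == [0, 0]
        for ra, rb in zip(res_purge.records, res_keep.records):
            for key in ("fst", "dxy", "delta_pi", "pi_ap", "pi_dp"):
                assert ra[key] == pytest.approx(rb[key], nan_ok=True, abs=1e-12)

    def test_state_statistics_match_bruteforce_on_matrices(self):
        """Sparse count-based statistics equal brute-force enumeration over
        the explicit haplotype matrices plus the substitution ledger."""
        reg = tiny_region(seed=5, length=500)
        params = engine.SimParams(ap_n=12, mu=5e-4, r=1e-4, regime="pheno_div",
                                  burn_in_gens=40, run_gens=120)
        tr = engine.TreatmentSpec(12, 0.5, 0.0)
        res = engine.run_simulation(reg, tr, params, 17, keep_final_state=True)
        state = res.final_state
        st = state.divergence_stats()
        ap = state.G[0][:, :state.ncols]
        dp = state.G[1][:, :state.ncols]
        fa, fd = state.fixed_private
        L = state.length
        assert st["pi_ap"] == pytest.approx(brute_pi(ap, L), abs=1e-12)
        assert st["pi_dp"] == pytest.approx(brute_pi(dp, L), abs=1e-12)
        assert st["dxy"] == pytest.approx(brute_dxy(ap, dp, L, fa, fd), abs=1e-12)
        want_fst = brute_fst(ap, dp, fa, fd)
        assert st["fst"] == pytest.approx(want_fst, nan_ok=True, abs=1e-12)

    def test_pheno_gen_reported_and_censoring_flagged(self):
        reg = tiny_region(seed=9)
        params = engine.SimParams(ap_n=25, mu=5e-5, r=1e-4, regime="pheno_div",
                                  burn_in_gens=30, run_gens=60)
        tr = engine.TreatmentSpec(25, 1.0, 0.0)
        res = engine.run_simulation(reg, tr, params, 2)
        # optimum at 10 cannot plausibly be reached in 60 tiny generations
        assert res.pheno_censored
        assert res.pheno_gen == params.run_gens
        null = engine.run_simulation(reg, tr, params.with_regime("pheno_null"), 2)
        # burn-in population already sits at the null optimum of 0
        assert not null.pheno_censored
        assert null.pheno_gen <= 1


def test_neutral_sfs_matches_coalescent_oracle():
    """Folded site-frequency spectrum at neutral equilibrium agrees with an
    independent coalescent simulation at matched theta.

    Bin proportions are collected from snapshots spaced 4N generations apart
    and compared with the msprime expectation through a Hotelling-type
    chi-square that uses the across-snapshot covariance (sites within a
    snapshot are linked, so a per-site chi-square would be anticonservative).
    Non-rejection at alpha = 0.01.
    """
    import msprime
    from scipy.stats import chi2

    nsub, n_pop, L = 20, 50, 1000
    bins = [(1, 1), (2, 2), (3, 3), (4, 5), (6, 10)]

    def binned(h):
        return np.array([h[lo - 1:hi].sum() for lo, hi in bins])

    exp = np.zeros(nsub // 2)
    for i in range(400):
        ts = msprime.sim_ancestry(
            samples=nsub // 2, population_size=n_pop, sequence_length=L,
            recombination_rate=1e-5, random_seed=i + 1,
        )
        ts = msprime.sim_mutations(ts, rate=4.89e-5, random_seed=i + 1,
                                   discrete_genome=False)
        exp += ts.allele_frequency_spectrum(
            polarised=False, span_normalise=False
        )[1:nsub // 2 + 1]
    p0 = binned(exp)
    p0 = p0 / p0.sum()

    params = engine.SimParams(ap_n=n_pop, mu=4.89e-5, r=1e-5, regime="neutral",
                              burn_in_gens=500, run_gens=0)
    arch = regions.ArchParams().scaled_to(L)
    reg = regions.sample_region(9, 0, L, arch)
    em = reg.exon_mask()
    rng = np.random.default_rng(77)
    state = engine.run_burn_in(reg, params, 77)
    props = []
    spacing, n_snap = 200, 30
    for g in range(n_snap * spacing):
        engine.step_generation(state, params, reg, rng, exon_mask=em,
                               need_counts=(g % spacing == 0))
        if g % spacing == 0:
            rows = rng.choice(2 * n_pop, nsub, replace=False)
            cc = state.G[0][rows, :state.ncols].sum(0)
            cc = cc[(cc > 0) & (cc < nsub)]
            h = np.zeros(nsub // 2)
            np.add.at(h, np.minimum(cc, nsub - cc) - 1, 1)
            b = binned(h)
            if b.sum() > 0:
                props.append(b / b.sum())
    P = np.array(props)
    xbar = P.mean(0)[:-1]
    S = np.cov(P[:, :-1].T) / len(P)
    dvec = xbar - p0[:-1]
    stat = float(dvec @ np.linalg.solve(S, dvec))
    pval = 1 - chi2.cdf(stat, len(dvec))
    assert pval > 0.01
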