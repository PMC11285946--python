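"""Downstream statistics: variance decomposition, inbreeding depression, LD."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency

from selfpoly import stats
from selfpoly.pipeline import make_fixture
from selfpoly.simulate import (DELETERIOUS, NEUTRAL, TRAIT, Haplotype,
                               MutationTable, Population, SimulationConfig)


def seeded_pop(config, site_specs, genotypes):
    table = MutationTable(config.n_traits)
    ids = [table.append(pos, cls, eff, 0) for pos, cls, eff in site_specs]
    pop = Population(config, table)
    pop.haplotypes = [
        Haplotype.from_ids(np.array([ids[k] for k in g], dtype=np.int64),
                           table, config.deleterious_active)
        for g in genotypes]
    pop.positions_in_use = {pos for pos, _, _ in site_specs}
    return pop


class TestVarianceDecomposition:
    def test_hwe_single_locus(self, hwe_pop):
        rep = stats.variance_decomposition(hwe_pop)
        assert rep.Vg == pytest.approx(0.125)
        assert rep.VI == pytest.approx(0.0, abs=1e-12)
        assert rep.CLD == pytest.approx(0.0, abs=1e-12)
        assert rep.VG == pytest.approx(0.125)

    def test_fully_inbred_single_locus(self, inbred_pop):
        rep = stats.variance_decomposition(inbred_pop)
        assert rep.Vg == pytest.approx(0.125)
        assert rep.VI == pytest.approx(0.125)   # F = 1: VI = F * Vg
        assert rep.VG == pytest.approx(0.25)
        assert rep.CLD == pytest.approx(0.0, abs=1e-12)

    def test_complete_negative_ld_pair(self, negative_ld_pop):
        """Bulmer-type cancellation: opposing alleles in complete repulsion."""
        rep = stats.variance_decomposition(negative_ld_pop)
        assert rep.VG == pytest.approx(0.0, abs=1e-12)
        assert rep.Vg == pytest.approx(0.25)
        assert rep.VI == pytest.approx(0.0, abs=1e-12)
        assert rep.CLD == pytest.approx(-0.25)

    @pytest.mark.parametrize("p,F", [(0.5, 0.0), (0.5, 0.5), (0.5, 1.0),
                                     (0.2, 0.5), (0.2, 1.0)])
    def test_vi_over_vg_recovers_F_in_single_locus_model(self, p, F):
        """Genotypes at exact inbreeding proportions give VI = F * Vg."""
        N = 200
        q = 1 - p
        f2 = p * p + F * p * q
        f1 = 2 * p * q * (1 - F)
        n2, n1 = round(N * f2), round(N * f1)
        n0 = N - n2 - n1
        cfg = SimulationConfig(N=N, L=50_000, mu=0, rec=0, burn_in=0,
                               post_gens=0, s_del=0.0)
        genotypes = []
        for i in range(N):
            if i < n2:
                genotypes += [[0], [0]]
            elif i < n2 + n1:
                genotypes += [[0], []]
            else:
                genotypes += [[], []]
        pop = seeded_pop(cfg, [(4500, TRAIT, np.array([0.5]))], genotypes)
        rep = stats.variance_decomposition(pop)
        assert rep.VI == pytest.approx(F * rep.Vg, abs=1e-12)

    def test_identity_holds_on_every_report(self, tiny_run):
        for _, row in tiny_run.stats.iterrows():
            assert row["VG"] == pytest.approx(
                row["Vg"] + row["VI"] + row["CLD"], abs=1e-10)

    def test_per_locus_diagnostic_matches_vg_plus_vi(self, inbred_pop, hwe_pop):
        # under linkage equilibrium the summed per-locus variances equal Vg+VI
        for pop in (inbred_pop, hwe_pop):
            rep = stats.variance_decomposition(pop)
            assert rep.VG_per_locus_i[0] == pytest.approx(
                rep.Vg_i[0] + rep.VI_i[0], abs=1e-12)

    def test_empty_sample_raises(self, hwe_pop):
        with pytest.raises(ValueError):
            stats.variance_decomposition(hwe_pop, individuals=np.array([], int))


class TestInbreedingDepression:
    def test_zero_without_selected_variation(self, rng):
        cfg = SimulationConfig(N=40, L=50_000, mu=0, rec=0, burn_in=0,
                               post_gens=0, s_del=0.0)
        genotypes = [[0] if i % 3 == 0 else [] for i in range(80)]
        pop = seeded_pop(cfg, [(100, NEUTRAL, None)], genotypes)
        assert stats.inbreeding_depression(pop, rng) == pytest.approx(0.0)

    def test_partially_recessive_deleterious_site_hwe(self, rng):
        """HWE population segregating one deleterious site (|s|=0.02, h=0.2).

        Cohort expectations with fitness-weighted parent sampling give
        ID = 1 - E[w_selfed]/E[w_outcrossed] ~ 0.0015: selfing exposes the
        recessive component.
        """
        N = 100
        cfg = SimulationConfig(N=N, L=50_000, mu=0, rec=0, burn_in=0,
                               post_gens=0, s_del=0.02, h_del=0.2)
        genotypes = []
        for i in range(N):  # 25 AA, 50 Aa, 25 aa
            if i < 25:
                genotypes += [[0], [0]]
            elif i < 75:
                genotypes += [[0], []]
            else:
                genotypes += [[], []]
        pop = seeded_pop(cfg, [(4500, DELETERIOUS, None)], genotypes)
        est = np.mean([stats.inbreeding_depression(pop, rng, n_offspring=2000)
                       for _ in range(4)])
        # analytic cohort expectation (fitness-weighted parents):
        w = {"aa": 1.0, "Aa": 0.996, "AA": 0.98}
        zbar = 0.25 * w["aa"] + 0.5 * w["Aa"] + 0.25 * w["AA"]
        P = {g: f * w[g] / zbar for g, f in
             (("aa", 0.25), ("Aa", 0.5), ("AA", 0.25))}
        w_self = (P["aa"] * 1.0
                  + P["Aa"] * (0.25 * w["AA"] + 0.5 * w["Aa"] + 0.25)
                  + P["AA"] * w["AA"])
        qA = P["Aa"] / 2 + P["AA"]
        w_out = (qA**2 * w["AA"] + 2 * qA * (1 - qA) * w["Aa"] + (1 - qA) ** 2)
        expected = 1 - w_self / w_out
        assert est == pytest.approx(expected, abs=6e-4)

    def test_error_when_outcrossed_cohort_inviable(self, rng):
        cfg = SimulationConfig(N=10, L=50_000, mu=0, rec=0, burn_in=0,
                               post_gens=0, s_del=0.0)
        pop = seeded_pop(cfg, [], [[] for _ in range(20)])
        pop.fitnesses = lambda: np.zeros(10)  # degenerate source population
        with pytest.raises(ValueError):
            stats.inbreeding_depression(pop, rng)


def hap_matrix(hap_strings):
    return np.array([[int(c) for c in s] for s in hap_strings], dtype=np.int8)


class TestPairwiseLD:
    def test_perfect_coupling(self):
        H = hap_matrix(["11"] * 5 + ["00"] * 5)
        r2, dp = stats.pairwise_ld(H[:, 0], H[:, 1])
        assert r2 == pytest.approx(1.0)
        assert dp == pytest.approx(1.0)

    def test_independent_sites(self):
        H = hap_matrix(["11", "10", "01", "00"] * 25)
        r2, _ = stats.pairwise_ld(H[:, 0], H[:, 1])
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_mixture(self):
        # {AB x4, Ab x1, aB x1, ab x4}: D = 0.15, r2 = 0.36, |D'| = 0.6
        H = hap_matrix(["11"] * 4 + ["10"] + ["01"] + ["00"] * 4)
        r2, dp = stats.pairwise_ld(H[:, 0], H[:, 1])
        assert r2 == pytest.approx(0.36)
        assert dp == pytest.approx(0.6)

    @pytest.mark.parametrize("seed", range(5))
    def test_r2_matches_contingency_table_oracle(self, seed):
        """r^2 equals chi-square/n of the 2x2 haplotype contingency table."""
        rng = np.random.default_rng(seed)
        n = 200
        a = rng.random(n) < 0.4
        b = (rng.random(n) < 0.3) ^ (a & (rng.random(n) < 0.5))
        table = np.array([[np.sum(a & b), np.sum(a & ~b)],
                          [np.sum(~a & b), np.sum(~a & ~b)]])
        chi2 = chi2_contingency(table, correction=False).statistic
        r2, _ = stats.pairwise_ld(a.astype(np.int8), b.astype(np.int8))
        assert r2 == pytest.approx(chi2 / n, rel=1e-10)


class TestLDMatrixFilters:
    def test_maf_and_spacing_filters(self):
        # sites at 2%, 30%, 31%, 60% of the genome; second site fails MAF
        L = 1_000_000
        positions = np.array([0.02 * L, 0.30 * L, 0.31 * L, 0.60 * L], int)
        H = np.zeros((20, 4), dtype=np.int8)
        H[:10, 0] = 1        # p = 0.5
        H[:1, 1] = 1         # p = 0.05 -> fails MAF 0.1
        H[5:15, 2] = 1       # p = 0.5
        H[::2, 3] = 1        # p = 0.5
        tab = stats.ld_matrix(H, positions, genome_length=L)
        # default spacing 0.02 L = 20 kb; retained: 0.02L, 0.31L, 0.60L
        assert list(tab.positions) == [int(0.02 * L), int(0.31 * L),
                                       int(0.60 * L)]
        assert len(tab.pairs) == 3

    def test_greedy_thinning_keeps_first_then_spaced(self):
        L = 1_000_000
        # spacing threshold 0.5 Mb scaled: use explicit min_spacing
        positions = np.array([0, 100, 400_000, 600_000, 1_000_000 - 1])
        H = np.tile(hap_matrix(["10"] * 10 + ["01"] * 10)[:, :1], (1, 5))
        tab = stats.ld_matrix(H, positions, genome_length=L,
                              min_spacing=500_000)
        assert list(tab.positions) == [0, 600_000]

    def test_fewer_than_two_snps_warns(self):
        H = np.ones((10, 1), dtype=np.int8)
        H[0, 0] = 0
        with pytest.warns(UserWarning):
            tab = stats.ld_matrix(H, np.array([5]), genome_length=1000)
        assert len(tab.pairs) == 0


def synthetic_ld_table(dists, L=25_000_000):
    pairs = pd.DataFrame({
        "pos_i": np.zeros(len(dists)), "pos_j": dists, "dist": dists,
        "r2": np.linspace(0.1, 0.9, len(dists)),
        "dprime": np.linspace(0.2, 1.0, len(dists)),
    })
    return stats.LDTable(pairs=pairs, positions=np.unique(dists),
                         genome_length=L)


class TestLDDecay:
    def test_downsamples_to_sparsest_bin(self, rng):
        L = 25_000_000
        w = 0.02 * L
        dists = np.concatenate([
            rng.uniform(0, w, 12), rng.uniform(w, 2 * w, 30),
            rng.uniform(2 * w, 3 * w, 50)])
        per_rep, _ = stats.ld_decay([synthetic_ld_table(dists)], rng)
        assert set(per_rep["n"]) == {12}
        assert len(per_rep) == 3

    def test_replicate_dropped_when_sparsest_bin_below_ten(self, rng):
        L = 25_000_000
        w = 0.02 * L
        dists = np.concatenate([rng.uniform(0, w, 9),
                                rng.uniform(w, 2 * w, 30)])
        with pytest.warns(UserWarning):
            per_rep, mean_curve = stats.ld_decay(
                [synthetic_ld_table(dists)], rng)
        assert per_rep.empty and mean_curve.empty

    def test_pairs_beyond_half_genome_excluded(self, rng):
        L = 25_000_000
        w = 0.02 * L
        dists = np.concatenate([
            rng.uniform(0, w, 15), rng.uniform(w, 2 * w, 15),
            np.full(40, 13_000_000.0)])  # 13 Mb > 12.5 Mb cap
        per_rep, _ = stats.ld_decay([synthetic_ld_table(dists)], rng)
        assert (per_rep["bin_mid"] < 0.5 * L).all()
        assert set(per_rep["n"]) == {15}


def many_site_population(n_trait, n_neutral, N=80, fixed_trait=0):
    cfg = SimulationConfig(N=N, L=25_000_000, mu=0, rec=0, burn_in=0,
                           post_gens=0, s_del=0.0)
    table = MutationTable(1)
    specs = []
    rng = np.random.default_rng(99)
    pos_pool = rng.choice(25_000_000, size=n_trait + n_neutral, replace=False)
    for k in range(n_trait):
        specs.append((int(pos_pool[k]), TRAIT,
                      np.array([rng.normal(0, 0.25)])))
    for k in range(n_neutral):
        specs.append((int(pos_pool[n_trait + k]), NEUTRAL, None))
    ids = list(range(len(specs)))
    genotypes = []
    for _ in range(2 * N):
        carried = [m for m in ids[fixed_trait:] if rng.random() < 0.3]
        carried += ids[:fixed_trait]  # these trait sites are fixed
        genotypes.append(carried)
    return seeded_pop(cfg, specs, genotypes)


class TestHaplotypeSample:
    def test_sample_fixed_trait_mutations_excluded(self, rng):
        pop = many_site_population(n_trait=10, n_neutral=5, fixed_trait=3)
        sample = stats.haplotype_sample(pop, rng, n_individuals=50)
        assert (sample.matrix.mean(axis=0) < 1.0).all()
        assert not set(range(3)) & set(sample.annotations["id"])

    def test_trait_variants_prioritised_then_background(self, rng):
        pop = many_site_population(n_trait=80, n_neutral=60)
        sample = stats.haplotype_sample(pop, rng, n_individuals=50,
                                        max_mutations=100)
        ann = sample.annotations
        assert len(ann) == 100
        assert (ann["class"] == "trait").sum() == 80
        assert (ann["class"] == "neutral").sum() == 20

    def test_excess_trait_variants_thinned(self, rng):
        pop = many_site_population(n_trait=150, n_neutral=10)
        sample = stats.haplotype_sample(pop, rng, n_individuals=50,
                                        max_mutations=100)
        assert len(sample.annotations) == 100
        assert (sample.annotations["class"] == "trait").all()

    def test_small_population_sampled_whole_with_warning(self, rng):
        pop = many_site_population(n_trait=5, n_neutral=0, N=20)
        with pytest.warns(UserWarning):
            sample = stats.haplotype_sample(pop, rng, n_individuals=50)
        assert sample.matrix.shape[0] == 40


class TestAlleleTrajectories:
    def test_tracks_only_pre_shift_trait_mutations(self, tiny_run):
        traj = stats.allele_trajectories(tiny_run.snapshots)
        pre = tiny_run.snapshots["pre_shift"]
        counts = pre.mutation_counts()
        seg = np.nonzero(counts)[0]
        expected_ids = set(seg[pre.table.mclass[seg] == TRAIT].tolist())
        assert set(traj["id"]) == expected_ids
        for label in tiny_run.snapshots:
            col = f"freq_{label}"
            assert col in traj.columns
            assert ((traj[col] >= 0) & (traj[col] <= 1)).all()

    def test_lost_and_fixed_endpoints(self):
        cfg = SimulationConfig(N=10, L=50_000, mu=0, rec=0, burn_in=0,
                               post_gens=0, s_del=0.0)
        table = MutationTable(1)
        m_lost = table.append(100, TRAIT, np.array([0.1]), 0)
        m_fix = table.append(9000, TRAIT, np.array([0.2]), 0)
        pre = Population(cfg, table)
        pre.haplotypes = [
            Haplotype.from_ids(np.array([m_lost, m_fix]), table, False)
            if i == 0 else
            Haplotype.from_ids(np.array([m_fix]), table, False)
            for i in range(20)]
        later = Population(cfg, table)
        later.haplotypes = [Haplotype.empty(1, False) for _ in range(20)]
        later.sub_ids = [m_fix]          # fixed and swept into the ledger
        later.generation = 40
        traj = stats.allele_trajectories(
            {"pre_shift": pre, "post_40": later})
        lost = traj[traj["id"] == m_lost].iloc[0]
        fixed = traj[traj["id"] == m_fix].iloc[0]
        assert lost["freq_pre_shift"] == pytest.approx(1 / 20)
        assert lost["freq_post_40"] == 0.0
        assert fixed["freq_pre_shift"] == 1.0 or fixed["freq_pre_shift"] > 0.9
        assert fixed["freq_post_40"] == 1.0


class TestBootstrap:
    def test_ci_contains_point_estimate(self, rng):
        values = rng.normal(2.0, 0.5, 200)
        point, lo, hi = stats.bootstrap_ci(values, n_boot=1000, rng=rng)
        assert lo <= point <= hi
        assert lo == pytest.approx(2.0, abs=0.2)
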