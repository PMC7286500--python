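import numpy as np
import pandas as pd
import pytest

from gslab.gmap import GeneticMap, make_genetic_map
from gslab.simdata import (
    FounderPool,
    MatingDesign,
    TraitArchitecture,
    effective_status_number,
    make_gamete,
    mendelian_violations,
    realized_parental_contributions,
    simulate_founders,
    simulate_phenotypes,
    simulate_population,
    simulate_trial,
)
from gslab.varcomp import VarianceComponents


class TestFounders:
    def test_maf_bounds_respected_and_polymorphic(self):
        m = make_genetic_map(3, 300.0, 400, seed=1)
        pool = simulate_founders(50, m, maf_min=0.1, seed=2)
        assert pool.haplotypes.shape == (50, 2, 400)
        assert np.all(pool.freqs >= 0.1) and np.all(pool.freqs <= 0.9)
        rf = pool.realized_freqs()
        assert np.all(rf > 0) and np.all(rf < 1)

    def test_maf_half_forces_balanced_frequencies(self):
        m = make_genetic_map(2, 200.0, 300, seed=3)
        pool = simulate_founders(100, m, maf_min=0.5, seed=4)
        assert np.allclose(pool.freqs, 0.5)
        # realized frequency within ~4 binomial SDs of 0.5 (sd ~ 0.035)
        assert np.abs(pool.realized_freqs() - 0.5).max() < 0.15

    def test_founders_in_linkage_equilibrium(self):
        # brute-force mean r^2 across all marker pairs ~ its null value 1/(2n)
        m = make_genetic_map(1, 100.0, 200, seed=5)
        pool = simulate_founders(1000, m, maf_min=0.2, seed=6)
        H = pool.haplotypes.reshape(2000, 200).astype(float)
        C = np.corrcoef(H.T) ** 2
        mean_r2 = (C.sum() - np.trace(C)) / (200 * 199)
        assert mean_r2 < 3.0 / 2000  # null expectation 1/2000 with slack

    def test_invalid_maf_rejected(self):
        m = make_genetic_map(1, 50.0, 10, seed=0)
        for bad in (0.0, 0.6, -0.1):
            with pytest.raises(ValueError):
                simulate_founders(10, m, maf_min=bad, seed=0)


class TestGametes:
    def test_zero_length_chromosome_gives_intact_haplotype(self):
        gmap = GeneticMap([1e-9], [0, 0, 0], [0.0, 0.0, 0.0], ["a", "b", "c"])
        haps = np.array([[0, 0, 0], [1, 1, 1]], dtype=np.int8)
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = make_gamete(haps, gmap, rng)
            assert np.array_equal(g, haps[0]) or np.array_equal(g, haps[1])

    def test_homozygous_parent_transmits_identically(self):
        gmap = make_genetic_map(2, 200.0, 50, seed=1)
        hap = (np.arange(50) % 2).astype(np.int8)
        haps = np.stack([hap, hap])
        g = make_gamete(haps, gmap, np.random.default_rng(2))
        assert np.array_equal(g, hap)

    def test_haldane_recombination_fraction(self):
        # markers 100 cM apart: r = 0.5 (1 - e^-2) ~ 0.432
        gmap = GeneticMap([100.0], [0, 0], [0.0, 100.0], ["l", "r"])
        haps = np.array([[0, 0], [1, 1]], dtype=np.int8)
        rng = np.random.default_rng(3)
        rec = sum(
            g[0] != g[1] for g in (make_gamete(haps, gmap, rng) for _ in range(10_000))
        )
        assert rec / 10_000 == pytest.approx(0.5 * (1 - np.exp(-2)), abs=0.02)

    def test_batch_and_single_gamete_same_law(self):
        # the vectorized interval-parity sampler must match the explicit
        # crossover construction in allele frequency and recombination rate
        from gslab.simdata import _gametes_batch, _interval_recomb_fractions

        gmap = GeneticMap([50.0], [0, 0], [0.0, 50.0], ["l", "r"])
        haps = np.array([[0, 0], [1, 1]], dtype=np.int8)
        rng = np.random.default_rng(4)
        batch = _gametes_batch(haps, 20_000, gmap, _interval_recomb_fractions(gmap), rng)
        r_batch = np.mean(batch[:, 0] != batch[:, 1])
        expected = 0.5 * (1 - np.exp(-1.0))
        assert r_batch == pytest.approx(expected, abs=0.015)
        assert batch.mean() == pytest.approx(0.5, abs=0.015)


class TestPopulation:
    def test_study_scale_emulation(self):
        trial = simulate_trial("full-sib", seed=1, n_markers=600, n_qtl=50)
        pop = trial.population
        n_off = len(pop.offspring_ids)
        assert 1321 <= n_off <= 1372  # between the two printed census counts
        per_site = pop.meta.groupby("site").size()
        assert per_site.min() >= 440 and per_site.max() <= 450

    def test_mendelian_certainty_for_opposing_homozygotes(self):
        # parents fixed 0 and 2 at every marker -> offspring dosage 1 always
        gmap = make_genetic_map(2, 100.0, 40, seed=5)
        haps = np.zeros((2, 2, 40), dtype=np.int8)
        haps[1] = 1
        pool = FounderPool(haps, np.full(40, 0.5))
        design = MatingDesign("full-sib", n_families=1, offspring_per_family=30,
                              n_parents=2, n_sites=1, blocks_per_site=1)
        pop = simulate_population(pool, design, gmap, seed=6)
        assert np.all(pop.offspring_dosages() == 1)

    def test_no_mendelian_violations(self, fs_trial, hs_trial):
        assert mendelian_violations(fs_trial.population) == 0
        assert mendelian_violations(hs_trial.population) == 0

    def test_seed_reproducibility_bit_identical(self):
        kw = dict(n_families=6, offspring_per_family=10, n_markers=500, n_qtl=40)
        t1 = simulate_trial("half-sib", seed=33, pollen_pool_size=50, **kw)
        t2 = simulate_trial("half-sib", seed=33, pollen_pool_size=50, **kw)
        assert np.array_equal(t1.population.haplotypes, t2.population.haplotypes)
        assert t1.population.realized_sires == t2.population.realized_sires
        pd.testing.assert_frame_equal(t1.phenotypes, t2.phenotypes)

    def test_insufficient_founders_rejected(self):
        gmap = make_genetic_map(1, 100.0, 20, seed=0)
        pool = simulate_founders(4, gmap, 0.2, seed=1)
        design = MatingDesign("full-sib", n_families=3, offspring_per_family=5, n_parents=10)
        with pytest.raises(ValueError, match="founders"):
            simulate_population(pool, design, gmap, seed=2)

    def test_pollen_pool_of_one_makes_full_sibs(self):
        # half sibs collapse to full sibs: realized genomic relatedness ~ 0.5
        gmap = make_genetic_map(5, 1000.0, 6000, seed=7)
        design = MatingDesign("half-sib", n_families=3, offspring_per_family=20,
                              pollen_pool_size=1, n_sites=1, blocks_per_site=1)
        pool = simulate_founders(design.n_founders_required, gmap, 0.1, seed=8)
        pop = simulate_population(pool, design, gmap, seed=9)
        G = _vanraden(pop)
        fam = pop.meta["family"].to_numpy()
        same = fam[:, None] == fam[None, :]
        iu = np.triu(np.ones_like(same), k=1).astype(bool)
        assert G[same & iu].mean() == pytest.approx(0.5, abs=0.03)

    def test_realized_relatedness_matches_pedigree_expectation(self, fs_trial):
        pop = fs_trial.population
        G = _vanraden(pop)
        fam = pop.meta["family"].to_numpy()
        same = fam[:, None] == fam[None, :]
        iu = np.triu(np.ones_like(same), k=1).astype(bool)
        assert G[same & iu].mean() == pytest.approx(0.5, abs=0.03)

    def test_half_sib_within_family_relatedness(self):
        gmap = make_genetic_map(6, 1200.0, 6000, seed=10)
        design = MatingDesign("half-sib", n_families=4, offspring_per_family=25,
                              pollen_pool_size=300, n_sites=1, blocks_per_site=1)
        pool = simulate_founders(design.n_founders_required, gmap, 0.1, seed=11)
        pop = simulate_population(pool, design, gmap, seed=12)
        G = _vanraden(pop)
        fam = pop.meta["family"].to_numpy()
        same = fam[:, None] == fam[None, :]
        iu = np.triu(np.ones_like(same), k=1).astype(bool)
        assert G[same & iu].mean() == pytest.approx(0.25, abs=0.03)


def _vanraden(pop):
    """Genomic relationships standardized by founder allele frequencies."""
    X = pop.offspring_dosages().astype(float)
    p = pop.founder_freqs
    Z = X - 2 * p
    return (Z @ Z.T) / (2 * np.sum(p * (1 - p)))


class TestPhenotypes:
    def test_null_architecture_is_pure_noise(self, fs_trial):
        vc = VarianceComponents(sigma2_a=0.0, sigma2_e=3.0)
        arch = TraitArchitecture(np.array([0]), np.array([1.0]), vc)
        phen = simulate_phenotypes(fs_trial.population, arch, seed=1)
        for col in ("true_a", "true_sa", "true_srep", "true_sf", "true_f"):
            assert np.all(phen[col] == 0)
        assert np.var(phen["true_e"]) == pytest.approx(3.0)

    def test_noiseless_single_site_equals_additive_value(self):
        trial = simulate_trial(
            "full-sib", seed=21, n_families=5, offspring_per_family=12,
            n_markers=400, n_qtl=60, n_sites=1, blocks_per_site=1,
            vc=VarianceComponents(sigma2_a=2.0, sigma2_e=0.0),
        )
        phen = trial.phenotypes
        np.testing.assert_allclose(
            phen["y"] - trial.architecture.mean, phen["true_a"], atol=1e-10
        )

    def test_variance_decomposition_recovers_components(self):
        # moment oracle: realized variance of every generative term vs target
        trial = simulate_trial("full-sib", seed=22, offspring_per_family=54,
                               n_markers=700, n_qtl=200)
        phen = trial.phenotypes
        targets = {
            "true_a": 2.0, "true_sa": 1.0, "true_srep": 0.5,
            "true_sf": 0.5, "true_f": 0.5, "true_e": 5.5,
        }
        for col, target in targets.items():
            assert np.var(phen[col]) == pytest.approx(target, rel=0.15), col

    def test_family_anova_consistent_with_architecture(self):
        # independent family-level ANOVA on a single-site design: the
        # between-family component of a full-sib trait is s2_a/2 + s2_f
        from oracles import anova_oneway_family

        vc = VarianceComponents(sigma2_a=2.0, sigma2_f=0.8, sigma2_e=3.0)
        trial = simulate_trial("full-sib", seed=23, n_families=30,
                               offspring_per_family=60, n_markers=500, n_qtl=150,
                               n_sites=1, blocks_per_site=1, n_parents=60, vc=vc)
        between, within = anova_oneway_family(
            trial.phenotypes["y"].to_numpy(), trial.phenotypes["family"].to_numpy()
        )
        assert between == pytest.approx(0.5 * 2.0 + 0.8, rel=0.35)

    def test_scaling_contract_is_exact(self, fs_trial):
        assert np.var(fs_trial.phenotypes["true_a"]) == pytest.approx(2.0, rel=1e-12)
        assert fs_trial.architecture.scaling is not None

    def test_zero_variance_trait_rejected(self, fs_trial):
        vc = VarianceComponents(sigma2_a=0.0, sigma2_e=0.0)
        arch = TraitArchitecture(np.array([0]), np.array([1.0]), vc)
        with pytest.raises(ValueError):
            simulate_phenotypes(fs_trial.population, arch, seed=0)


class TestContributionsAndStatusNumber:
    def test_contributions_sum_to_one(self, fs_trial, hs_trial):
        for t in (fs_trial, hs_trial):
            c = realized_parental_contributions(t.population)
            assert c.values.sum() == pytest.approx(1.0)

    def test_study_defaults_hit_effective_size_targets(self):
        # design-time calibration targets: ~21 (full-sib), ~93 (half-sib)
        fs = simulate_trial("full-sib", seed=2, n_markers=400, n_qtl=50)
        hs = simulate_trial("half-sib", seed=2, n_markers=400, n_qtl=50)
        assert 13 <= effective_status_number(fs.population) <= 32
        assert 80 <= effective_status_number(hs.population) <= 110
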