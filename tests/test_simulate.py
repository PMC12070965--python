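import numpy as np
import pytest

from ssblup.simulate import (
    SimulationConfig,
    assign_trait,
    marker_map,
    mask_data,
    simulate_historical,
    simulate_population,
)


def small_config(**kw):
    base = dict(
        seed=0, n_chrom=2, markers_per_chrom=150, mutation_rate=2.5e-5,
        hist_size_start=120, hist_size_mid=40, hist_size_end=200,
        hist_generations=40, n_sires=10, n_dams=80, recent_generations=4,
        genotyped_generations=3, scenario=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfig:
    def test_invalid_scenario(self):
        with pytest.raises(ValueError):
            small_config(scenario=9)

    def test_invalid_h2(self):
        with pytest.raises(ValueError):
            small_config(h2=1.5)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            small_config(genotyped_fraction=1.2)


class TestHistorical:
    def test_zero_generations_keeps_freq_half(self):
        cfg = small_config(hist_generations=40)
        cfg.hist_generations = 0
        haps = simulate_historical(cfg, np.random.default_rng(0))
        freq = haps.mean(axis=0)
        assert abs(freq.mean() - 0.5) < 0.01  # binomial noise only

    def test_absorbed_loci_stay_absorbed_without_mutation(self):
        cfg = small_config(mutation_rate=0.0, hist_generations=60,
                           hist_size_start=30, hist_size_mid=10, hist_size_end=30)
        haps = simulate_historical(cfg, np.random.default_rng(1))
        freq = haps.mean(axis=0)
        assert ((freq == 0) | (freq == 1)).sum() > 0  # drift fixed some loci

    def test_ld_decays_with_distance(self):
        """Mean adjacent-marker r2 exceeds r2 between markers > 10 cM apart
        after the bottleneck (replicate-averaged)."""
        near, far = [], []
        for s in range(3):
            cfg = small_config(seed=s)
            haps = simulate_historical(cfg, np.random.default_rng(s))
            G = (haps[0::2] + haps[1::2]).astype(float)
            mm = marker_map(cfg)
            keep = np.flatnonzero(G.std(axis=0) > 0)
            C = np.corrcoef(G[:, keep].T)
            pos = mm["pos"].to_numpy()[keep]
            chrom = mm["chrom"].to_numpy()[keep]
            same = chrom[:, None] == chrom[None, :]
            d = np.abs(pos[:, None] - pos[None, :])
            r2 = C**2
            near.append(r2[same & (d > 0) & (d < 1.0)].mean())
            far.append(r2[same & (d > 10.0)].mean())
        assert np.mean(near) > np.mean(far)


class TestTrait:
    def test_scenario_counts(self, rng):
        for scen, total in [(1, 10), (2, 100), (3, 500), (4, 510)]:
            cfg = small_config(scenario=scen, markers_per_chrom=400)
            geno = rng.binomial(2, 0.5, size=(300, cfg.n_markers)).astype(float)
            tr = assign_trait(geno, cfg, np.random.default_rng(scen))
            assert tr.causal_idx.size == total

    def test_founder_tbv_variance_equals_h2(self, rng):
        cfg = small_config()
        geno = rng.binomial(2, 0.5, size=(400, cfg.n_markers)).astype(float)
        tr = assign_trait(geno, cfg, np.random.default_rng(5))
        tbv = tr.tbv(geno[:, tr.causal_idx])
        assert tbv.var() == pytest.approx(cfg.h2, rel=1e-6)

    def test_too_few_segregating_markers(self, rng):
        cfg = small_config(scenario=3)  # 500 causal > 300 markers
        geno = rng.binomial(2, 0.5, size=(50, cfg.n_markers)).astype(float)
        with pytest.raises(ValueError, match="segregating"):
            assign_trait(geno, cfg, np.random.default_rng(6))

    def test_realized_h2_calibrated(self):
        """Across replicates the realized Var(TBV)/Var(phenotype) among
        phenotyped animals stays near the configured h2 = 0.1."""
        ratios = []
        for s in range(20):
            pop = simulate_population(small_config(seed=s))
            fem = ~np.isnan(pop.phenotype)
            ratios.append(pop.tbv[fem].var() / pop.phenotype[fem].var())
        assert abs(np.mean(ratios) - 0.1) < 0.03


class TestRecentPopulation:
    def test_bookkeeping(self):
        pop = simulate_population(small_config(seed=3))
        cfg = pop.config
        assert pop.n == cfg.n_sires + cfg.n_dams * (cfg.recent_generations + 1)
        assert (pop.generation[: cfg.n_sires + cfg.n_dams] == 0).all()
        for g in range(1, cfg.recent_generations + 1):
            assert (pop.generation == g).sum() == cfg.n_dams

    def test_offspring_parents_recorded(self):
        pop = simulate_population(small_config(seed=4))
        young = pop.generation > 0
        assert (pop.sire[young] >= 0).all() and (pop.dam[young] >= 0).all()
        assert (pop.sex[pop.sire[young]] == "M").all()
        assert (pop.dam[young] < np.flatnonzero(young)).all()  # dams precede offspring

    def test_tbv_consistent_with_genotypes_and_effects(self):
        pop = simulate_population(small_config(seed=5))
        tr = pop.trait
        recomputed = tr.tbv(pop.genotype_matrix[:, tr.causal_idx].astype(float))
        assert np.allclose(recomputed, pop.tbv)

    def test_selection_beats_random_mating(self):
        """Truncation selection on pedigree-BLUP EBV must raise final-
        generation mean TBV relative to random replacement."""
        diff = []
        for s in range(8):
            sel = simulate_population(small_config(seed=s, selection="ebv"))
            ran = simulate_population(small_config(seed=s, selection="random"))
            last = sel.generation.max()
            diff.append(sel.tbv[sel.generation == last].mean()
                        - ran.tbv[ran.generation == last].mean())
        assert np.mean(diff) > 0

    def test_determinism(self):
        a = simulate_population(small_config(seed=11))
        b = simulate_population(small_config(seed=11))
        assert np.array_equal(a.genotype_matrix, b.genotype_matrix)
        assert np.array_equal(a.sire, b.sire)
        assert np.allclose(a.phenotype, b.phenotype, equal_nan=True)


class TestMasking:
    def test_full_genotyping_fraction(self):
        cfg = small_config(seed=6, genotyped_fraction=1.0)
        pop = simulate_population(cfg)
        window = pop.generation > pop.generation.max() - cfg.genotyped_generations
        assert pop.genotyped[window].all()
        assert not pop.genotyped[~window].any()

    def test_genotyped_fraction_within_binomial_ci(self):
        pop = simulate_population(small_config(seed=7))
        window = pop.generation > pop.generation.max() - 3
        n = int(window.sum())
        frac = pop.genotyped[window].mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_masked_parent_rate(self):
        cfg = small_config(seed=8, pedigree_missing_rate=0.2)
        pop = simulate_population(cfg)
        eligible = (pop.sire >= 0) | (pop.dam >= 0)
        masked = eligible & (pop.sire_masked < 0) & (pop.dam_masked < 0)
        rate = masked.sum() / eligible.sum()
        assert abs(rate - 0.2) < 3 * np.sqrt(0.2 * 0.8 / eligible.sum())

    def test_roles(self):
        pop = simulate_population(small_config(seed=9))
        last = pop.generation.max()
        assert (pop.role[pop.generation == last] == "validation").all()
        assert (pop.role[pop.generation < last] == "reference").all()


def test_write_roundtrip(tmp_path):
    pop = simulate_population(small_config(seed=10))
    pop.write(tmp_path)
    from ssblup.pedigree import read_pedigree
    from ssblup.genotypes import read_genotypes

    ped = read_pedigree(tmp_path / "pedigree.csv")
    assert ped.n == pop.n
    geno = read_genotypes(tmp_path / "genotypes.tsv", tmp_path / "markers.tsv")
    assert geno.n_animals == pop.genotyped.sum()
    assert geno.n_markers == pop.markers.shape[0]
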