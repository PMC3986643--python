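import numpy as np
import pytest
from scipy import stats

from sweepscan import windows
from sweepscan.fst import snp_fst_pair
from sweepscan.haph import haph_raw, haplotype_spectrum, segment_partition, segment_scores
from sweepscan.ihs import call_ancestral
from sweepscan.simulate import (
    BreedSpec,
    SimulationConfig,
    SweepSpec,
    TraitSpec,
    _evolve_neutral,
    _Population,
    derive_outgroup,
    error_rate_for_single_fraction,
    impose_sweep,
    insert_site,
    outgroup_allele_counts,
    simulate_dataset,
    simulate_neutral_panel,
    simulate_trait,
    split_breeds,
)


def two_breed_config(seed, t, ne=100):
    return SimulationConfig(
        seed=seed,
        chrom_length=1_000_000,
        base_ne=60,
        burn_in_factor=8,
        breeds=[BreedSpec("a", ne=ne, generations=t), BreedSpec("b", ne=ne, generations=t)],
    )


class TestConfigValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(mutation_rate=-1e-8).validate()

    def test_bad_h2_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(trait=TraitSpec(h2=1.2)).validate()

    def test_sweep_position_out_of_bounds(self):
        cfg = SimulationConfig(
            sweeps=[SweepSpec(chrom=0, position=20_000_000, s=0.1, breeds=("holstein",))]
        )
        with pytest.raises(ValueError, match="bounds"):
            cfg.validate()

    def test_small_breed_ne_rejected(self):
        with pytest.raises(ValueError, match="Ne"):
            SimulationConfig(breeds=[BreedSpec("x", ne=1)]).validate()

    def test_negative_selection_rejected(self):
        cfg = SimulationConfig(
            sweeps=[SweepSpec(chrom=0, position=100, s=-0.1, breeds=("holstein",))]
        )
        with pytest.raises(ValueError):
            cfg.validate()


class TestNeutralPanel:
    def test_zero_mutation_rate_errors(self):
        cfg = SimulationConfig(seed=0, mutation_rate=0.0, base_ne=10, chrom_length=100_000)
        with pytest.raises(RuntimeError, match="no segregating sites"):
            simulate_neutral_panel(cfg)

    def test_every_snp_segregates_and_map_sorted(self, tiny_panel):
        panel, gmap, _ = tiny_panel
        freq = panel.allele_frequencies()
        assert np.all((freq > 0) & (freq < 1))
        assert np.all(np.diff(gmap.pos) > 0)

    def test_matrix_strictly_binary(self, tiny_panel):
        panel, _, _ = tiny_panel
        assert set(np.unique(panel.haplotypes)) <= {0, 1}

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(seed=3, chrom_length=300_000, base_ne=20, burn_in_factor=6)
        p1, g1 = simulate_neutral_panel(cfg)
        p2, g2 = simulate_neutral_panel(cfg)
        assert np.array_equal(p1.haplotypes, p2.haplotypes)
        assert np.array_equal(g1.pos, g2.pos)

    def test_no_recombination_complete_linkage(self):
        # without recombination the infinite-sites genealogy is a perfect
        # phylogeny: no SNP pair shows all four gametes
        cfg = SimulationConfig(
            seed=4,
            chrom_length=200_000,
            base_ne=20,
            burn_in_factor=10,
            recombination_rate=0.0,
            mutation_rate=4e-7,
        )
        panel, gmap = simulate_neutral_panel(cfg)
        h = panel.haplotypes.astype(bool)
        rng = np.random.default_rng(0)
        m = gmap.n_snps
        for _ in range(300):
            i, j = rng.integers(0, m, 2)
            if i == j:
                continue
            gametes = {(int(a), int(b)) for a, b in zip(h[:, i], h[:, j])}
            assert len(gametes) <= 3

    def test_site_frequency_spectrum_oracle(self):
        # neutral Wright-Fisher SFS: E[# sites at derived count i] ~ 1/i
        two_n = 50
        counts = np.zeros(two_n, dtype=float)
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed,
                chrom_length=400_000,
                base_ne=two_n // 2,
                mutation_rate=4e-7,
                burn_in_factor=12,
                breeds=[],
            )
            panel, _ = simulate_neutral_panel(cfg)
            derived = panel.haplotypes.sum(axis=0)
            for x in derived:
                counts[x] += 1
        obs = counts[1:] / counts[1:].sum()
        expected = 1.0 / np.arange(1, two_n)
        expected /= expected.sum()
        bins = [(1, 2), (2, 4), (4, 8), (8, two_n)]
        for lo, hi in bins:
            o = obs[lo - 1 : hi - 1].sum()
            e = expected[lo - 1 : hi - 1].sum()
            assert o == pytest.approx(e, abs=0.04)


class TestSplitBreeds:
    def test_no_divergence_time_fst_near_zero(self):
        vals = []
        for seed in range(5):
            cfg = two_breed_config(50 + seed, t=0)
            base, _ = simulate_neutral_panel(cfg)
            panels = split_breeds(base, cfg)
            vals.append(
                np.nanmean(
                    snp_fst_pair(
                        panels["a"].allele_frequencies(), panels["b"].allele_frequencies()
                    )
                )
            )
        assert np.mean(vals) < 0.02

    def test_drift_expectation_oracle(self):
        # for the frequency-only estimator (variance with denominator r=2) the
        # drift expectation is f / (2 - f), f = 1 - exp(-t / 2Ne), not f itself
        t, ne = 40, 100
        vals = []
        for seed in range(8):
            cfg = two_breed_config(seed, t=t, ne=ne)
            base, _ = simulate_neutral_panel(cfg)
            panels = split_breeds(base, cfg)
            vals.append(
                np.nanmean(
                    snp_fst_pair(
                        panels["a"].allele_frequencies(), panels["b"].allele_frequencies()
                    )
                )
            )
        f = 1 - np.exp(-t / (2 * ne))
        target = f / (2 - f)
        mean = np.mean(vals)
        assert 0.6 * target < mean < 1.3 * target
        assert mean < 0.75 * f  # clearly distinguishes the r vs r-1 convention

    def test_single_breed_split(self, tiny_panel):
        panel, gmap, cfg0 = tiny_panel
        cfg = SimulationConfig(
            seed=1,
            chrom_length=cfg0.chrom_length,
            base_ne=cfg0.base_ne,
            breeds=[BreedSpec("only", ne=50, generations=10)],
        )
        panels = split_breeds(panel, cfg)
        assert set(panels) == {"only"}
        assert panels["only"].n_haplotypes == 100
        # shared-map invariant: breed map is a subset of the base map
        assert np.all(np.isin(panels["only"].gmap.pos, gmap.pos))

    def test_monomorphic_everywhere_dropped(self, tiny_panel):
        panel, _, cfg0 = tiny_panel
        cfg = SimulationConfig(
            seed=2,
            chrom_length=cfg0.chrom_length,
            base_ne=cfg0.base_ne,
            breeds=[BreedSpec("a", ne=30, generations=50), BreedSpec("b", ne=30, generations=50)],
        )
        panels = split_breeds(panel, cfg)
        fa = panels["a"].allele_frequencies()
        fb = panels["b"].allele_frequencies()
        seg = ((fa > 0) & (fa < 1)) | ((fb > 0) & (fb < 1))
        assert seg.all()


class TestImposeSweep:
    def small_panel(self, seed=0):
        cfg = SimulationConfig(
            seed=seed,
            chrom_length=500_000,
            base_ne=50,
            burn_in_factor=8,
            breeds=[BreedSpec("a", ne=50, generations=5)],
        )
        base, _ = simulate_neutral_panel(cfg)
        return split_breeds(base, cfg)["a"], cfg

    def test_neutral_sweep_matches_drift(self):
        # s = 0: final-frequency distribution indistinguishable from plain
        # drift (KS test) when started from a common standing variant
        panel, cfg = self.small_panel()
        freq = panel.allele_frequencies()
        site = int(np.argmin(np.abs(freq - 0.5)))
        spec = SweepSpec(
            chrom=0, position=int(panel.gmap.pos[site]), s=0.0, breeds=("a",), generations=15
        )
        rng = np.random.default_rng(1)
        swept, neutral = [], []
        for _ in range(60):
            _, f = impose_sweep(panel, spec, cfg, rng=rng)
            swept.append(f)
            pop = _Population(
                panel.haplotypes.copy(), panel.gmap.chrom.copy(), panel.gmap.pos.copy()
            )
            _evolve_neutral(pop, 50, 15, cfg, rng, mutate=False, prune=False)
            neutral.append(pop.haps[:, site].sum() / pop.n_haplotypes)
        assert stats.ks_2samp(swept, neutral).pvalue > 0.01

    def test_strong_sweep_fixes_and_haph_collapses(self):
        # higher recombination keeps the flanks variable so only the swept
        # region collapses to a single haplotype
        cfg = SimulationConfig(
            seed=3,
            chrom_length=2_000_000,
            base_ne=50,
            burn_in_factor=8,
            recombination_rate=1e-7,
            breeds=[BreedSpec("a", ne=50, generations=5)],
        )
        base, _ = simulate_neutral_panel(cfg)
        panel = split_breeds(base, cfg)["a"]
        spec = SweepSpec(chrom=0, position=1_000_000, s=0.5, breeds=("a",), generations=400)
        panels = insert_site({"a": panel}, 0, 1_000_000)
        swept, f = impose_sweep(panels["a"], spec, cfg)
        assert f == 1.0
        part = segment_partition(swept.gmap)
        scores = segment_scores(swept, part)
        sweep_seg = np.argmin(np.abs(part.midpoint - 1_000_000))
        # fixed region: single haplotype -> spectrum variance collapses to ~0
        assert scores[sweep_seg] < 0.02
        assert scores[sweep_seg] < np.nanmean(scores)

    def test_retry_exhaustion_errors(self):
        panel, cfg = self.small_panel(seed=4)
        spec = SweepSpec(
            chrom=0, position=123_456, s=0.2, breeds=("a",), generations=100, retry_limit=0
        )
        panels = insert_site({"a": panel}, 0, 123_456)
        with pytest.raises(RuntimeError, match="lost"):
            impose_sweep(panels["a"], spec, cfg)

    def test_missing_locus_rejected(self):
        panel, cfg = self.small_panel(seed=5)
        spec = SweepSpec(chrom=0, position=999_999, s=0.2, breeds=("a",))
        with pytest.raises(ValueError, match="not in the panel map"):
            impose_sweep(panel, spec, cfg)

    def test_stop_frequency_honoured(self):
        panel, cfg = self.small_panel(seed=6)
        spec = SweepSpec(
            chrom=0, position=250_000, s=0.8, breeds=("a",), generations=400, stop_frequency=0.6
        )
        panels = insert_site({"a": panel}, 0, 250_000)
        _, f = impose_sweep(panels["a"], spec, cfg)
        assert f >= 0.6


class TestSimulateTrait:
    def panels(self, seed=0):
        cfg = SimulationConfig(
            seed=seed,
            chrom_length=2_000_000,
            base_ne=50,
            burn_in_factor=8,
            breeds=[BreedSpec("a", ne=60, generations=10)],
        )
        base, _ = simulate_neutral_panel(cfg)
        return split_breeds(base, cfg), cfg

    def test_high_h2_regression_slope_one(self):
        panels, cfg = self.panels()
        trait = TraitSpec(n_qtl=50, h2=0.99)
        pheno, truth, _ = simulate_trait(panels, trait, cfg)
        y = pheno["trait"].to_numpy()
        g = pheno["genetic_value"].to_numpy()
        slope = np.polyfit(g, y, 1)[0]
        r2 = np.corrcoef(g, y)[0, 1] ** 2
        assert slope == pytest.approx(1.0, abs=0.05)
        assert r2 > 0.97
        assert truth.realized_h2 == pytest.approx(0.99, abs=0.05)

    def test_truncation_fraction_one_is_no_selection(self):
        panels, cfg = self.panels(seed=1)
        trait = TraitSpec(n_qtl=50, h2=0.5, truncation_fraction=1.0, generations=5)
        _, _, out_panels = simulate_trait(panels, trait, cfg)
        # no selection path: panels pass through untouched
        assert np.array_equal(
            out_panels["a"].haplotypes, panels["a"].haplotypes
        )

    def test_n_qtl_exceeding_snps_rejected(self):
        panels, cfg = self.panels(seed=2)
        with pytest.raises(ValueError, match="n_qtl"):
            simulate_trait(panels, TraitSpec(n_qtl=10**6, h2=0.5), cfg)

    def test_selection_response_positive(self):
        # breeder's-equation direction: truncation selection raises the mean
        # genetic value relative to the unselected counterfactual
        wins = 0
        reps = 10
        for seed in range(reps):
            panels, cfg = self.panels(seed=100 + seed)
            # selection mild enough that genetic variance survives at this Ne
            sel = TraitSpec(n_qtl=50, h2=0.6, truncation_fraction=0.5, generations=4)
            nosel = TraitSpec(n_qtl=50, h2=0.6)
            rng_sel = np.random.default_rng(seed)
            rng_nosel = np.random.default_rng(seed)  # same QTL draw
            p_sel, _, _ = simulate_trait(panels, sel, cfg, rng=rng_sel)
            p_nosel, _, _ = simulate_trait(panels, nosel, cfg, rng=rng_nosel)
            if p_sel["genetic_value"].mean() > p_nosel["genetic_value"].mean():
                wins += 1
        assert wins >= int(0.95 * reps)

    def test_zero_genetic_variance_errors(self):
        panels, cfg = self.panels(seed=3)
        # collapse the panel to a single repeated haplotype: no variance
        haps = np.repeat(panels["a"].haplotypes[:1], panels["a"].n_haplotypes, axis=0)
        from sweepscan.core import HaplotypePanel

        degenerate = {"a": HaplotypePanel("a", haps, panels["a"].gmap)}
        with pytest.raises(ValueError, match="variance"):
            simulate_trait(degenerate, TraitSpec(n_qtl=10, h2=0.5), cfg)


class TestOutgroup:
    def test_zero_error_full_recovery(self, tiny_panel):
        _, gmap, _ = tiny_panel
        og = derive_outgroup(gmap, error_rate=0.0)
        calls = call_ancestral(outgroup_allele_counts(og))
        assert np.all(calls == 0)

    def test_half_error_one_individual(self, tiny_panel):
        _, gmap, _ = tiny_panel
        correct, called_total = 0, 0
        for seed in range(5):
            og = derive_outgroup(
                gmap, n_individuals=1, error_rate=0.5, rng=np.random.default_rng(seed)
            )
            calls = call_ancestral(outgroup_allele_counts(og))
            called = calls >= 0
            correct += int((calls[called] == 0).sum())
            called_total += int(called.sum())
        # genotype Binomial(2, 1/2): hom-ancestral and hom-derived equally
        # likely, het is a tie -> among called sites recovery is a coin flip
        assert correct / called_total == pytest.approx(0.5, abs=0.05)

    def test_default_single_allele_fraction(self, tiny_panel):
        _, gmap, _ = tiny_panel
        og = derive_outgroup(gmap, rng=np.random.default_rng(1))
        counts = outgroup_allele_counts(og)
        single = (counts == 0).any(axis=1)
        assert np.mean(single) == pytest.approx(0.85, abs=0.03)

    def test_error_rate_solver(self):
        e = error_rate_for_single_fraction(0.85, 17)
        assert (1 - e) ** 34 == pytest.approx(0.85)


class TestSimulateDataset:
    def test_end_to_end_reproducible(self):
        cfg = SimulationConfig(
            seed=9,
            chrom_length=600_000,
            base_ne=30,
            burn_in_factor=6,
            breeds=[BreedSpec("a", ne=30, generations=20), BreedSpec("b", ne=30, generations=20)],
            sweeps=[SweepSpec(chrom=0, position=300_000, s=0.5, breeds=("a",), stop_frequency=0.8)],
            trait=TraitSpec(n_qtl=30, h2=0.5),
        )
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        for name in d1.panels:
            assert np.array_equal(d1.panels[name].haplotypes, d2.panels[name].haplotypes)
        assert d1.truth.sweeps == d2.truth.sweeps
        assert d1.phenotypes.equals(d2.phenotypes)
        assert d1.truth.sweeps[0]["final_frequency"]["a"] >= 0.8
        # non-target breed untouched by the sweep at insertion frequency 0
        site = np.flatnonzero(d1.gmap.pos == 300_000)
        if len(site):
            assert d1.panels["b"].haplotypes[:, site[0]].sum() == 0
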