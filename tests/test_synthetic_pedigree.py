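import numpy as np
import pytest

from pedmut.genotype_calling import HET, HOM_ALT, HOM_REF
from pedmut.synthetic_pedigree import (
    PedigreeSimConfig,
    inject_germline_mutations,
    scan_monomorphic_background,
    simulate_pedigree_genotypes,
    simulate_reference,
    simulate_site_evidence,
)


class TestReference:
    def test_zero_repeat_fraction_gives_empty_mask(self):
        panel = simulate_reference(100_000, repeat_fraction=0.0, seed=1)
        assert panel.repeat_mask.size == 0

    def test_masked_fraction_matches_target(self):
        panel = simulate_reference(100_000, repeat_fraction=0.3, seed=1)
        masked = (panel.repeat_mask[:, 1] - panel.repeat_mask[:, 0]).sum()
        n_blocks = 100_000 / 250
        se = np.sqrt(0.3 * 0.7 / n_blocks)
        assert abs(masked / 100_000 - 0.3) < 3 * se

    def test_same_seed_is_byte_identical(self):
        a = simulate_reference(50_000, 0.25, seed=9)
        b = simulate_reference(50_000, 0.25, seed=9)
        assert np.array_equal(a.sequence, b.sequence)
        assert np.array_equal(a.repeat_mask, b.repeat_mask)
        assert np.array_equal(a.mappability, b.mappability)
        assert np.array_equal(a.genes, b.genes)

    def test_structural_invariants(self, small_panel):
        rm = small_panel.repeat_mask
        assert (rm[:, 0] < rm[:, 1]).all() and (rm[:-1, 1] <= rm[1:, 0]).all()
        assert rm.min() >= 0 and rm.max() <= small_panel.length
        for sub in (small_panel.exons, small_panel.utr3):
            for s, e in sub:  # every exon/UTR inside some gene
                j = np.searchsorted(small_panel.genes[:, 0], s, side="right") - 1
                assert j >= 0 and e <= small_panel.genes[j, 1]

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            simulate_reference(0, 0.1)
        with pytest.raises(ValueError):
            simulate_reference(5000, 0.1)
        with pytest.raises(ValueError):
            simulate_reference(100_000, 0.95)


class TestGenotypes:
    def test_parental_het_density_matches_pi(self):
        panel = simulate_reference(1_000_000, 0.0, seed=2)
        cfg = PedigreeSimConfig(seed=2)
        g = simulate_pedigree_genotypes(panel, cfg)
        for parent in ("father", "mother"):
            het = g.parent_het_density(parent)
            assert abs(het - 0.003) < 5 * np.sqrt(0.003 / 1_000_000)

    def test_mendelian_consistency(self, small_panel):
        g = simulate_pedigree_genotypes(small_panel, PedigreeSimConfig(seed=3))
        father, mother = g.gt[0], g.gt[1]
        # opposite homozygotes force every offspring heterozygous
        forced = ((father == HOM_REF) & (mother == HOM_ALT)) | (
            (father == HOM_ALT) & (mother == HOM_REF)
        )
        assert (g.gt[2:][:, forced] == HET).all()
        # a hom-ref x hom-ref site cannot yield carriers (none exist in table)
        both_ref = (father == HOM_REF) & (mother == HOM_REF)
        assert not both_ref.any()
        # offspring can never carry more alt doses than parents transmitted
        max_dose = (father > 0).astype(int) + (mother > 0).astype(int)
        assert (g.gt[2:] <= max_dose[None, :]).all()

    def test_zero_pi_means_no_variant_sites(self, small_panel):
        g = simulate_pedigree_genotypes(small_panel, PedigreeSimConfig(pi=0.0, seed=4))
        assert g.n_sites == 0


class TestInjection:
    def test_fixed_mutations_transmit_to_half(self, small_panel):
        cfg = PedigreeSimConfig(
            n_dnms=200,
            mosaic_division_distribution={"fixed": 1.0},
            n_offspring_panel=50,
            seed=6,
        )
        g = simulate_pedigree_genotypes(small_panel, cfg)
        g = inject_germline_mutations(small_panel, g, cfg)
        carriers = np.array([d.panel_carriers for d in g.true_dnms])
        assert all(d.gamete_fraction == 0.5 for d in g.true_dnms)
        se = np.sqrt(50 * 0.25 / 200)
        assert abs(carriers.mean() - 25.0) < 3 * se

    def test_first_division_mosaic_transmits_quarter(self, small_panel):
        cfg = PedigreeSimConfig(
            n_dnms=200, mosaic_division_distribution={1: 1.0}, seed=6
        )
        g = inject_germline_mutations(
            small_panel, simulate_pedigree_genotypes(small_panel, cfg), cfg
        )
        assert all(d.gamete_fraction == 0.25 for d in g.true_dnms)
        carriers = np.array([d.panel_carriers for d in g.true_dnms])
        se = np.sqrt(50 * 0.25 * 0.75 / 200)
        assert abs(carriers.mean() - 12.5) < 3 * se

    def test_zero_dnms_leaves_genotypes_unchanged(self, small_panel):
        cfg = PedigreeSimConfig(n_dnms=0, seed=6)
        g = simulate_pedigree_genotypes(small_panel, cfg)
        g2 = inject_germline_mutations(small_panel, g, cfg)
        assert g2 is g

    def test_parents_stay_homozygous_reference(self, small_panel):
        cfg = PedigreeSimConfig(n_dnms=25, seed=8)
        g = inject_germline_mutations(
            small_panel, simulate_pedigree_genotypes(small_panel, cfg), cfg
        )
        dnm_idx = np.flatnonzero(g.is_dnm)
        assert (g.gt[:2, dnm_idx] == HOM_REF).all()
        for d in g.true_dnms:
            assert set(d.carrier_offspring) <= set(g.offspring)

    def test_requesting_too_many_sites_fails(self, small_panel):
        cfg = PedigreeSimConfig(n_dnms=10, seed=8)
        g = simulate_pedigree_genotypes(small_panel, cfg)
        with pytest.raises(ValueError, match="monomorphic"):
            inject_germline_mutations(
                small_panel, g, cfg, allowed_positions=np.arange(5)
            )


class TestEvidence:
    def test_pooled_het_alt_fraction_balanced(self):
        panel = simulate_reference(2_000_000, 0.0, seed=10)
        cfg = PedigreeSimConfig(pi=0.006, seed=10)
        g = simulate_pedigree_genotypes(panel, cfg)
        ev = simulate_site_evidence(g, cfg)
        het = g.gt == HET
        assert het.sum() >= 10_000
        pooled = ev.alt_count[het].sum() / ev.depth[het].sum()
        assert 0.49 <= pooled <= 0.51

    def test_homref_error_reads_match_rate(self, small_panel):
        cfg = PedigreeSimConfig(seed=12)
        g = simulate_pedigree_genotypes(small_panel, cfg)
        ev = simulate_site_evidence(g, cfg)
        ref_sites = g.gt == HOM_REF
        mean_alt = ev.alt_count[ref_sites].mean()
        expected = cfg.depth_mean * cfg.base_error  # 0.3 at the defaults
        n = ref_sites.sum()
        assert abs(mean_alt - expected) < 3 * np.sqrt(expected / n)

    def test_zero_depth_flags_no_data(self, small_panel):
        cfg = PedigreeSimConfig(depth_mean=0.0, seed=13)
        g = simulate_pedigree_genotypes(small_panel, cfg)
        ev = simulate_site_evidence(g, cfg)
        assert (ev.depth == 0).all()
        assert np.array_equal(ev.no_data_sites(), ev.positions)

    def test_determinism_with_explicit_stream(self, small_panel):
        cfg = PedigreeSimConfig(seed=14)
        g = simulate_pedigree_genotypes(small_panel, cfg)
        ev1 = simulate_site_evidence(g, cfg, np.random.default_rng(99))
        ev2 = simulate_site_evidence(g, cfg, np.random.default_rng(99))
        assert np.array_equal(ev1.alt_count, ev2.alt_count)
        assert ev1.annotations.equals(ev2.annotations)

    def test_background_scan_marginals(self, small_panel):
        cfg = PedigreeSimConfig(pi=0.0, seed=15)
        g = simulate_pedigree_genotypes(small_panel, cfg)
        bg = scan_monomorphic_background(small_panel, g, cfg, min_alt_reads=3)
        # every materialised site really has a pileup of >= 3 error reads
        assert (bg.alt_count.max(axis=0) >= 3).all()
        # expected count: sites x individuals x P(Poisson(0.3) >= 3)
        from scipy.stats import poisson

        lam = cfg.depth_mean * cfg.base_error
        p3 = poisson.sf(2, lam)
        n_ind = len(g.individuals)
        expected = small_panel.length * (1 - (1 - p3) ** n_ind)
        assert abs(bg.n_sites - expected) < 5 * np.sqrt(expected)


class TestConfigValidation:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            PedigreeSimConfig(pi=0.05)
        with pytest.raises(ValueError):
            PedigreeSimConfig(mosaic_division_distribution={"fixed": 0.5, 2: 0.4})
        with pytest.raises(ValueError):
            PedigreeSimConfig(base_error=0.7)
        with pytest.raises(ValueError):
            PedigreeSimConfig(annotation_model={"DP": (1.0, 1.0)})

    def test_expected_gamete_fraction(self):
        cfg = PedigreeSimConfig(
            mosaic_division_distribution={"fixed": 0.5, 1: 0.5}
        )
        assert cfg.expected_gamete_fraction() == pytest.approx(0.375)
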