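import dataclasses

import numpy as np
import pandas as pd
import pytest

from pedmut.error_rates import (
    FalseNegativeReport,
    empirical_false_negative_rate,
    estimate_callable,
    spike_in_false_negative_rate,
)
from pedmut.genotype_calling import CALLER_A, CALLER_B
from pedmut.site_filtering import (
    ANNOTATION_NAMES,
    CalibrationError,
    CallableMask,
    calibrate_thresholds,
)

from conftest import make_callset


def _wide_thresholds(n=100):
    ann = pd.DataFrame({a: np.linspace(-1e5, 1e5, n) for a in ANNOTATION_NAMES})
    return calibrate_thresholds(ann, np.arange(n))


class TestEmpirical:
    def _fixture(self, n_detected, n_sites):
        """Parents fixed for different alleles; one offspring; a chosen
        number of sites genotyped het, the rest miscalled hom-ref."""
        gt = np.zeros((3, n_sites), dtype=np.int8)
        gt[1] = 2
        gt[2, :n_detected] = 1
        frac = np.zeros((3, n_sites))
        frac[1] = 1.0
        frac[2, :n_detected] = 0.5
        calls = make_callset(gt, depth=40, alt_frac=frac)
        mask = CallableMask(np.array([[0, 1_000_000]]), 1_000_000)
        return calls, mask

    def test_miss_arithmetic(self):
        calls, mask = self._fixture(94, 100)
        report = empirical_false_negative_rate(calls, calls, _wide_thresholds(), mask)
        assert report.n_sites == 100
        assert report.fn_rate == pytest.approx(0.06)
        assert report.n_miscalled == 6 and report.n_nocall == 0

    def test_perfect_evidence_zero_fn(self):
        calls, mask = self._fixture(50, 50)
        report = empirical_false_negative_rate(calls, calls, _wide_thresholds(), mask)
        assert report.fn_rate == 0.0

    def test_no_qualifying_sites_raises(self):
        gt = np.zeros((3, 5), dtype=np.int8)  # parents both hom-ref everywhere
        calls = make_callset(gt)
        mask = CallableMask(np.array([[0, 10_000]]), 10_000)
        with pytest.raises(CalibrationError):
            empirical_false_negative_rate(calls, calls, _wide_thresholds(), mask)

    def test_report_invariant_enforced(self):
        with pytest.raises(ValueError):
            FalseNegativeReport("empirical", 10, 5, 2, 1)


class TestSpikeIn:
    def test_deterministic_given_stream(self, small_run):
        cfg = small_run.config
        from pedmut.pipeline import run_full_pipeline

        other = run_full_pipeline(cfg)
        assert other.fn_spikein == small_run.fn_spikein

    def test_low_allele_fraction_collapses_detection(self, small_panel):
        from pedmut.synthetic_pedigree import PedigreeSimConfig, simulate_pedigree_genotypes

        cfg = PedigreeSimConfig(seed=21)
        g = simulate_pedigree_genotypes(small_panel, cfg)
        mask = CallableMask(np.array([[0, small_panel.length]]), small_panel.length)
        report, truth = spike_in_false_negative_rate(
            small_panel, g, cfg, _wide_thresholds(), mask, CALLER_A, CALLER_B,
            af_distribution=np.array([0.1]), n_spikes=400,
            rng=np.random.default_rng(1),
        )
        # at 10% mutant reads the >25% minor-fraction het rule rarely passes
        assert report.n_detected / report.n_sites < 0.5

    def test_insufficient_monomorphic_sites(self, small_panel):
        from pedmut.synthetic_pedigree import PedigreeSimConfig, simulate_pedigree_genotypes

        cfg = PedigreeSimConfig(seed=21)
        g = simulate_pedigree_genotypes(small_panel, cfg)
        mask = CallableMask(np.array([[0, 100]]), small_panel.length)
        with pytest.raises(ValueError, match="monomorphic"):
            spike_in_false_negative_rate(
                small_panel, g, cfg, _wide_thresholds(), mask, CALLER_A, CALLER_B,
                af_distribution=np.array([0.5]), n_spikes=1000,
            )

    def test_empty_af_distribution_rejected(self, small_panel):
        from pedmut.synthetic_pedigree import PedigreeSimConfig, simulate_pedigree_genotypes

        cfg = PedigreeSimConfig(seed=21)
        g = simulate_pedigree_genotypes(small_panel, cfg)
        mask = CallableMask(np.array([[0, small_panel.length]]), small_panel.length)
        with pytest.raises(ValueError, match="af_distribution"):
            spike_in_false_negative_rate(
                small_panel, g, cfg, _wide_thresholds(), mask, CALLER_A, CALLER_B,
                af_distribution=np.array([]),
            )


class TestCallable:
    def test_toy_mask_arithmetic(self):
        mask = CallableMask(np.array([[0, 1000]]), 1000)
        depth = np.full((1000, 4), 60)
        depth[:100] = 2  # 10% of sampled positions under-covered
        report = estimate_callable(mask, depth, min_depth=10)
        assert report.insufficient_depth_fraction == pytest.approx(0.1)
        assert report.callable_bases == 900

    def test_full_depth_keeps_everything(self):
        mask = CallableMask(np.array([[0, 500]]), 500)
        report = estimate_callable(mask, np.full((500, 2), 60), min_depth=10)
        assert report.callable_bases == mask.total_bases

    def test_any_individual_below_counts(self):
        mask = CallableMask(np.array([[0, 10]]), 10)
        depth = np.full((10, 3), 60)
        depth[0, 2] = 1  # single thin individual suffices
        report = estimate_callable(mask, depth, min_depth=10)
        assert report.insufficient_depth_fraction == pytest.approx(0.1)

    def test_empty_mask_rejected(self):
        mask = CallableMask(np.empty((0, 2), dtype=np.int64), 100)
        with pytest.raises(ValueError):
            estimate_callable(mask, np.full((10, 2), 60))


class TestFnProperties:
    def test_estimators_agree_on_shared_fixture(self, small_run):
        emp, spike = small_run.fn_empirical, small_run.fn_spikein
        se = np.hypot(emp.standard_error(), spike.standard_error())
        assert abs(emp.fn_rate - spike.fn_rate) <= 3 * se

    def test_rates_are_proportions(self, small_run):
        for rep in (small_run.fn_empirical, small_run.fn_spikein):
            assert 0.0 <= rep.fn_rate <= 1.0
            assert rep.miscall_rate + rep.nocall_rate == pytest.approx(rep.fn_rate)

    def test_fn_monotone_as_thresholds_tighten(self, small_run):
        """Shrinking every annotation band can only lose more true hets."""
        from pedmut.genotype_calling import call_genotypes

        th2 = small_run.thresholds
        table = th2.table.copy()
        table["lower"] = table["mean"] - 1.0 * table["sd"]
        table["upper"] = table["mean"] + 1.0 * table["sd"]
        th1 = dataclasses.replace(th2, table=table, sd_multiplier=1.0)
        cfg = small_run.config
        import numpy as np

        from pedmut.site_filtering import build_callable_mask
        from pedmut.synthetic_pedigree import (
            inject_germline_mutations,
            simulate_pedigree_genotypes,
            simulate_reference,
            simulate_site_evidence,
        )

        ss = np.random.SeedSequence(cfg.seed)
        s_ref, s_gt, s_dnm, s_ev, s_bg, *_ = ss.spawn(7)
        panel = simulate_reference(cfg.length, cfg.repeat_fraction, seed=s_ref)
        mask = build_callable_mask(panel.mappability, panel.repeat_mask)
        g = simulate_pedigree_genotypes(panel, cfg.sim, np.random.default_rng(s_gt))
        g = inject_germline_mutations(
            panel, g, cfg.sim, np.random.default_rng(s_dnm), mask.positions()
        )
        ev = simulate_site_evidence(g, cfg.sim, np.random.default_rng(s_ev))
        calls_a = call_genotypes(ev, cfg.caller_a)
        calls_b = call_genotypes(ev, cfg.caller_b)
        fn_wide = empirical_false_negative_rate(calls_a, calls_b, th2, mask)
        fn_tight = empirical_false_negative_rate(calls_a, calls_b, th1, mask)
        assert fn_tight.fn_rate >= fn_wide.fn_rate
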