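"""End-to-end pedigree DNM pipeline: simulate -> call -> filter -> detect ->
error rates -> rate inference, plus re-derivation of the published study's
headline arithmetic from its own printed counts.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import dnm_detection, error_rates, fileio, published, rate_inference
from .exact_stats import ContingencyTable2x2, binomial_test, fisher_exact_two_sided
from .genotype_calling import (
    CALLER_A,
    CALLER_B,
    CallerConfig,
    call_genotypes,
    intersect_callsets,
)
from .rate_inference import (
    PopGenSummary,
    RateEstimate,
    count_mutation_events,
    effective_population_size,
    equilibrium_time,
    estimate_rate,
    round_sig,
)
from .site_filtering import (
    CallableMask,
    FilterThresholds,
    apply_filters,
    build_callable_mask,
    calibrate_thresholds,
    select_known_het_sites,
)
from .synthetic_pedigree import (
    PedigreeSimConfig,
    inject_germline_mutations,
    scan_monomorphic_background,
    simulate_pedigree_genotypes,
    simulate_reference,
    simulate_site_evidence,
)

__all__ = ["PipelineConfig", "PipelineReport", "run_full_pipeline", "reproduce_paper_numbers"]

logger = logging.getLogger("pedmut")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full synthetic pipeline run.

    The default fixture is a 1 Mb reference with twelve sequenced
    offspring — the study's total meiosis count — and everything else at
    the simulator's study-condition defaults.
    """

    length: int = 1_000_000
    repeat_fraction: float = 0.25
    sim: PedigreeSimConfig = field(
        default_factory=lambda: PedigreeSimConfig(n_offspring_sequenced=12)
    )
    caller_a: CallerConfig = CALLER_A
    caller_b: CallerConfig = CALLER_B
    window: int = 1000
    window_mean_min: float = 0.95
    sd_multiplier: float = 2.0
    het_fraction_min: float = 0.25
    min_linked_reads: int = 5
    min_calibration_sites: int = 30
    min_depth_callable: int = 10
    n_spikes: int = 500
    n_depth_sample: int = 20_000
    ci_level: float = 0.95
    scan_background: bool = True
    seed: int = 0
    outdir: Optional[Path] = None

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, seed=seed, sim=replace(self.sim, seed=seed))

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha1(payload).hexdigest()[:10]


@dataclass
class PipelineReport:
    config: PipelineConfig
    mask: CallableMask
    thresholds: FilterThresholds
    removal_report: pd.DataFrame
    true_dnms: tuple
    candidates: list
    false_positives: list
    fn_empirical: error_rates.FalseNegativeReport
    fn_spikein: error_rates.FalseNegativeReport
    spike_truth: pd.DataFrame
    callable_report: error_rates.CallableReport
    rate: RateEstimate
    popgen: PopGenSummary
    transmission: dict
    max_transmission_test: Optional[dict]

    def summary(self) -> dict:
        """Flat, JSON-ready roll-up of the run's headline numbers."""
        return {
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "callable_bases": self.callable_report.callable_bases,
            "n_true_dnms": len(self.true_dnms),
            "n_candidates": len(self.candidates),
            "n_false_positives": len(self.false_positives),
            "M_carrier_events": self.rate.M,
            "fn_rate_empirical": self.fn_empirical.fn_rate,
            "fn_rate_spikein": self.fn_spikein.fn_rate,
            "spikein_miscall_rate": self.fn_spikein.miscall_rate,
            "spikein_nocall_rate": self.fn_spikein.nocall_rate,
            "mu_raw": self.rate.mu_raw,
            "mu_corrected": self.rate.mu_corrected,
            "mu_ci_low": self.rate.ci[0],
            "mu_ci_high": self.rate.ci[1],
            "injected_rate": self.config.sim.expected_rate(
                self.callable_report.callable_bases
            ),
            "realized_rate": rate_inference.realized_injected_rate(
                self.true_dnms,
                self.config.sim.n_offspring_sequenced,
                self.callable_report.callable_bases,
            ),
            "Ne": self.popgen.Ne,
            "max_transmission": self.max_transmission_test,
        }


def run_full_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage on a seeded synthetic fixture.

    Stage order mirrors the real screen: mappability/repeat mask first,
    dual-caller genotyping, known-heterozygote threshold calibration,
    annotation filtering, candidate detection and characterisation, the
    two false-negative estimators, callable-size accounting, and finally
    rate and population-genetic inference.  Every stage draws from its own
    child stream of the master seed.
    """
    ss = np.random.SeedSequence(config.seed)
    (s_ref, s_gt, s_dnm, s_ev, s_bg, s_spike, s_depth) = ss.spawn(7)

    logger.info("stage=reference length=%d", config.length)
    panel = simulate_reference(config.length, config.repeat_fraction, seed=s_ref)
    mask = build_callable_mask(
        panel.mappability, panel.repeat_mask, config.window, config.window_mean_min
    )
    logger.info("stage=mask callable=%d/%d", mask.total_bases, config.length)

    genotypes = simulate_pedigree_genotypes(panel, config.sim, np.random.default_rng(s_gt))
    genotypes = inject_germline_mutations(
        panel,
        genotypes,
        config.sim,
        np.random.default_rng(s_dnm),
        allowed_positions=mask.positions(),
    )
    logger.info(
        "stage=genotypes sites=%d dnms=%d", genotypes.n_sites, len(genotypes.true_dnms)
    )

    evidence = simulate_site_evidence(genotypes, config.sim, np.random.default_rng(s_ev))
    if config.scan_background:
        background = scan_monomorphic_background(
            panel, genotypes, config.sim, np.random.default_rng(s_bg)
        )
        logger.info("stage=background suspicious_sites=%d", background.n_sites)
        evidence = evidence.concat(background)

    calls_a = call_genotypes(evidence, config.caller_a)
    calls_b = call_genotypes(evidence, config.caller_b)
    joint = intersect_callsets(calls_a, calls_b)
    logger.info("stage=calling sites_a+b=%d intersected=%d", calls_a.n_sites, joint.n_sites)

    in_mask = joint.take(np.flatnonzero(mask.contains(joint.positions)))
    known_idx = select_known_het_sites(in_mask, config.het_fraction_min)
    thresholds = calibrate_thresholds(
        in_mask.annotations, known_idx, config.sd_multiplier, config.min_calibration_sites
    )
    filtered, removal_report = apply_filters(joint, thresholds, mask)
    logger.info(
        "stage=filtering known_het=%d kept=%d removed=%d",
        known_idx.size,
        filtered.n_sites,
        len(removal_report),
    )

    raw_candidates = dnm_detection.detect_candidates(filtered, config.het_fraction_min)
    truth_by_pos = {d.position: d for d in genotypes.true_dnms}
    candidates = dnm_detection.characterize(
        raw_candidates, panel, filtered.linked_reads, config.min_linked_reads
    )
    candidates = dnm_detection.attach_panel_counts(candidates, truth_by_pos)
    false_positives = [c for c in candidates if c.position not in truth_by_pos]
    logger.info(
        "stage=detection candidates=%d false_positives=%d",
        len(candidates),
        len(false_positives),
    )

    fn_emp = error_rates.empirical_false_negative_rate(
        calls_a, calls_b, thresholds, mask, config.het_fraction_min
    )
    af_dist = error_rates.observed_het_allele_fractions(in_mask)
    fn_spike, spike_truth = error_rates.spike_in_false_negative_rate(
        panel,
        genotypes,
        config.sim,
        thresholds,
        mask,
        config.caller_a,
        config.caller_b,
        af_dist,
        n_spikes=config.n_spikes,
        rng=np.random.default_rng(s_spike),
        het_fraction_min=config.het_fraction_min,
    )
    logger.info(
        "stage=fnrate empirical=%.4f spikein=%.4f", fn_emp.fn_rate, fn_spike.fn_rate
    )

    rng_depth = np.random.default_rng(s_depth)
    depth_sample = rng_depth.poisson(
        config.sim.depth_mean,
        size=(min(config.n_depth_sample, mask.total_bases), len(config.sim.individuals)),
    )
    callable_report = error_rates.estimate_callable(
        mask, depth_sample, config.min_depth_callable
    )

    M = count_mutation_events(candidates)
    rate = estimate_rate(
        M,
        config.sim.n_offspring_sequenced,
        callable_report.callable_bases,
        fn_emp.fn_rate,
        published.CONSTANTS["generation_time_years"],
        config.ci_level,
    )
    ne = effective_population_size(config.sim.pi, rate.mu_corrected) if M else float("nan")
    popgen = PopGenSummary(
        pi=config.sim.pi,
        mu=rate.mu_corrected,
        Ne=ne,
        generation_time=rate.generation_time,
        equilibrium_generations=4.0 * ne,
        equilibrium_years=4.0 * ne * rate.generation_time,
    )

    report = PipelineReport(
        config=config,
        mask=mask,
        thresholds=thresholds,
        removal_report=removal_report,
        true_dnms=genotypes.true_dnms,
        candidates=candidates,
        false_positives=false_positives,
        fn_empirical=fn_emp,
        fn_spikein=fn_spike,
        spike_truth=spike_truth,
        callable_report=callable_report,
        rate=rate,
        popgen=popgen,
        transmission=dnm_detection.transmission_summary(candidates),
        max_transmission_test=dnm_detection.max_transmission_test(candidates),
    )
    if config.outdir is not None:
        _persist(report, panel, calls_a, calls_b, filtered, genotypes)
    return report


def _persist(report, panel, calls_a, calls_b, filtered, genotypes) -> None:
    cfg = report.config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"seed{cfg.seed}_{cfg.config_hash()}"
    fileio.write_callset_vcf(calls_a, out / f"calls_a_{tag}.vcf", cfg.length)
    fileio.write_callset_vcf(calls_b, out / f"calls_b_{tag}.vcf", cfg.length)
    fileio.write_callset_vcf(filtered, out / f"filtered_{tag}.vcf", cfg.length)
    fileio.write_bed(report.mask.intervals, out / f"callable_mask_{tag}.bed")
    fileio.write_bed(panel.repeat_mask, out / f"repeat_mask_{tag}.bed")
    report.thresholds.to_tsv(out / f"thresholds_{tag}.tsv")
    report.removal_report.to_csv(out / f"filter_report_{tag}.tsv", sep="\t", index=False)
    report.transmission["table"].to_csv(out / f"candidates_{tag}.tsv", sep="\t", index=False)
    fileio.write_truth_table(genotypes.true_dnms, out / f"truth_{tag}.tsv")
    report.spike_truth.to_csv(out / f"spike_truth_{tag}.tsv", sep="\t", index=False)
    cfg_echo = asdict(replace(cfg, outdir=str(cfg.outdir)))
    cfg_echo["sim"]["mosaic_division_distribution"] = {
        str(k): v for k, v in cfg_echo["sim"]["mosaic_division_distribution"].items()
    }
    fileio.write_yaml(cfg_echo, out / f"config_{tag}.yaml")
    summary = report.summary()
    summary["rate_table"] = {
        "mu_raw": report.rate.mu_raw,
        "mu_corrected": report.rate.mu_corrected,
        "ci": list(report.rate.ci),
        "per_genome_rate": report.rate.per_genome_rate,
        "mu_per_year": report.rate.mu_per_year,
    }
    fileio.write_yaml(_plain(summary), out / f"summary_{tag}.yaml")


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def reproduce_paper_numbers() -> dict:
    """Recompute the published study's headline quantities from its own
    printed counts and constants (no simulation involved).

    Covers the rate arithmetic, callable accounting, effective population
    size and equilibrium projection, the mutation-table roll-ups
    (transition/transversion ratio, region counts, transmission) and the
    exact tests on transmission, family mosaicism contrast, parental
    origin and CpG share.
    """
    C = published.CONSTANTS
    dnms = published.PUBLISHED_DNMS

    M = sum(len(d.carriers) for d in dnms)
    rate = estimate_rate(
        M,
        C["n_offspring"],
        C["callable_bases"],
        C["fn_rate"],
        C["generation_time_years"],
    )
    mu_2sf = round_sig(rate.mu_corrected, 2)
    ne = effective_population_size(C["pi"], mu_2sf)

    ts = sum(d.mutation_class == "transition" for d in dnms)
    tv = len(dnms) - ts
    regions = {
        r: sum(d.region == r for d in dnms)
        for r in ("intergenic", "intronic", "3'UTR", "exonic")
    }
    top = max(dnms, key=lambda d: d.panel_carriers / d.panel_size)
    fisher_top = fisher_exact_two_sided(
        ContingencyTable2x2(
            top.panel_carriers,
            top.panel_size - top.panel_carriers,
            top.panel_size // 2,
            top.panel_size - top.panel_size // 2,
        )
    )
    fam = {}
    for family in ("atlantic", "baltic"):
        sub = [d for d in dnms if d.family == family]
        fam[family] = (sum(d.shared for d in sub), sum(not d.shared for d in sub))
    fisher_family = fisher_exact_two_sided(
        ContingencyTable2x2(*fam["atlantic"], *fam["baltic"])
    )

    paternal = sum(d.origin == "paternal" for d in dnms)
    maternal = sum(d.origin == "maternal" for d in dnms)
    human_ratio = C["paternal_maternal_ratio_human"]
    origin_binom = binomial_test(
        paternal, paternal + maternal, human_ratio / (human_ratio + 1.0), "less"
    )
    cpg_count = 1  # published count; the table does not carry sequence context
    cpg_binom = binomial_test(cpg_count, len(dnms), C["cpg_reference_fraction"], "less")

    masked = C["masked_mb"] * 1e6
    callable_mb = round(masked * (1.0 - C["insufficient_depth_fraction"]) / 1e6)

    return {
        "n_dnms": len(dnms),
        "M_carrier_events": M,
        "per_genome_rate": rate.per_genome_rate,
        "mu_raw": rate.mu_raw,
        "mu_corrected": rate.mu_corrected,
        "mu_ci_low": rate.ci[0],
        "mu_ci_high": rate.ci[1],
        "mu_per_year": rate.mu_per_year,
        "callable_mb": callable_mb,
        "Ne": ne,
        "equilibrium_years": equilibrium_time(C["current_ne"], C["generation_time_years"]),
        "transitions": ts,
        "transversions": tv,
        "ts_tv_ratio": ts / tv,
        "region_counts": regions,
        "shared_count": sum(d.shared for d in dnms),
        "max_transmission_pct": round(100.0 * top.panel_carriers / top.panel_size),
        "fisher_p_max_transmission": fisher_top.p_value,
        "family_contrast_table": [list(fam["atlantic"]), list(fam["baltic"])],
        "fisher_p_family_contrast": fisher_family.p_value,
        "paternal": paternal,
        "maternal": maternal,
        "binomial_p_origin_vs_human": origin_binom.p_value,
        "cpg_count": cpg_count,
        "binomial_p_cpg_vs_human": cpg_binom.p_value,
    }
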