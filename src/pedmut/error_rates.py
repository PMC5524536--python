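"""False-negative rate estimation and callable-genome accounting.

The deliberately strict filtering that keeps false positives at zero also
throws away true heterozygotes; the resulting false-negative rate is
estimated two independent ways so the rate estimate can be corrected:

* empirically, from known heterozygous sites (parents fixed for different
  alleles, so every offspring is an obligate heterozygote), re-genotyping
  each offspring on its own so shared-variant calling power does not leak
  in — both incorrect and failed calls count as misses;
* by spike-in simulation: de novo mutations are introduced at monomorphic
  callable sites with mutant-read fractions drawn from the observed
  heterozygous allele-fraction distribution, the pipeline is re-run, and
  miscalls and no-calls are reported separately.

Callable-genome accounting multiplies the mappability/repeat-masked size
by the fraction of positions with sufficient depth in every individual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .genotype_calling import (
    CallerConfig,
    GenotypeCallSet,
    HET,
    HOM_ALT,
    HOM_REF,
    NO_CALL,
    call_genotypes,
)
from .site_filtering import (
    CalibrationError,
    CallableMask,
    FilterThresholds,
    annotation_pass,
)

__all__ = [
    "FalseNegativeReport",
    "CallableReport",
    "empirical_false_negative_rate",
    "spike_in_false_negative_rate",
    "estimate_callable",
    "observed_het_allele_fractions",
]


@dataclass(frozen=True)
class FalseNegativeReport:
    method: str          # "empirical" | "spike-in"
    n_sites: int         # genotype assays (site x offspring)
    n_detected: int
    n_miscalled: int
    n_nocall: int
    clustered_se: Optional[float] = None  # site-cluster-robust SE of fn_rate

    def __post_init__(self) -> None:
        if self.n_detected + self.n_miscalled + self.n_nocall != self.n_sites:
            raise ValueError("detected + miscalled + nocall must equal n_sites")

    @property
    def fn_rate(self) -> float:
        return (self.n_miscalled + self.n_nocall) / self.n_sites if self.n_sites else 0.0

    @property
    def miscall_rate(self) -> float:
        return self.n_miscalled / self.n_sites if self.n_sites else 0.0

    @property
    def nocall_rate(self) -> float:
        return self.n_nocall / self.n_sites if self.n_sites else 0.0

    def standard_error(self) -> float:
        """Cluster-robust SE where available (assays at one site share its
        filter fate, so they are not independent); binomial otherwise."""
        if self.clustered_se is not None:
            return self.clustered_se
        p = self.fn_rate
        return float(np.sqrt(p * (1.0 - p) / self.n_sites)) if self.n_sites else 0.0


@dataclass(frozen=True)
class CallableReport:
    masked_bases: float
    insufficient_depth_fraction: float
    min_depth: int

    @property
    def callable_bases(self) -> float:
        return round(self.masked_bases * (1.0 - self.insufficient_depth_fraction))


def _offspring_detection(
    calls_a: GenotypeCallSet,
    calls_b: GenotypeCallSet,
    site_idx: np.ndarray,
    site_callable: np.ndarray,
    het_fraction_min: float,
    offspring_idx: Optional[np.ndarray] = None,
) -> tuple[int, int, int]:
    """Classify each (site, offspring) assay as detected / miscalled / no-call.

    A heterozygote is detected when both callers call het and the
    minor-allele read fraction clears ``het_fraction_min``.  Assays at
    filtered-out sites, or where either caller returns no-call, count as
    no-calls; everything else called is a miscall (including a het call
    whose allele fraction fails the rule — the pipeline would have
    rejected that genotype).
    """
    gt_a = calls_a.gt[2:][:, site_idx]
    gt_b = calls_b.gt[2:][:, site_idx]
    depth = calls_a.depth[2:][:, site_idx]
    alt = calls_a.alt_count[2:][:, site_idx]
    with np.errstate(invalid="ignore"):
        frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
    minor = np.minimum(frac, 1.0 - frac)

    if offspring_idx is None:
        assay = np.ones(gt_a.shape, dtype=bool)
    else:  # one designated target offspring per site
        assay = np.zeros(gt_a.shape, dtype=bool)
        assay[np.asarray(offspring_idx), np.arange(gt_a.shape[1])] = True

    callable_ = np.broadcast_to(site_callable[None, :], gt_a.shape)
    nocall = ~callable_ | (gt_a == NO_CALL) | (gt_b == NO_CALL)
    detected = ~nocall & (gt_a == HET) & (gt_b == HET) & (minor > het_fraction_min)
    miscalled = ~nocall & ~detected

    # cluster-robust SE: assays at one site share that site's filter fate
    miss = (miscalled | nocall) & assay
    m_i = miss.sum(axis=0).astype(float)
    n_i = assay.sum(axis=0).astype(float)
    n_total = n_i.sum()
    fn = m_i.sum() / n_total if n_total else 0.0
    se = float(np.sqrt(((m_i - fn * n_i) ** 2).sum()) / n_total) if n_total else 0.0

    return (
        int(detected[assay].sum()),
        int(miscalled[assay].sum()),
        int((nocall & assay).sum()),
        se,
    )


def empirical_false_negative_rate(
    calls_a: GenotypeCallSet,
    calls_b: GenotypeCallSet,
    thresholds: FilterThresholds,
    mask: CallableMask,
    het_fraction_min: float = 0.25,
) -> FalseNegativeReport:
    """FN rate from obligate heterozygotes at parent-fixed-different sites.

    Qualifying sites are taken from the joint calls (parents called
    homozygous for different alleles, no missing parent) inside the
    callable mask — the same territory the candidate search and the rate
    denominator use; each offspring is then scored independently through
    the full detection stack: caller agreement, allele-fraction rule and
    annotation bands.
    """
    father, mother = calls_a.gt[0], calls_a.gt[1]
    qualifying = np.flatnonzero(
        (((father == HOM_REF) & (mother == HOM_ALT))
         | ((father == HOM_ALT) & (mother == HOM_REF)))
        & mask.contains(calls_a.positions)
    )
    if qualifying.size == 0:
        raise CalibrationError("no callable sites with parents fixed for different alleles")

    site_callable = annotation_pass(calls_a.annotations, thresholds)[qualifying]
    det, mis, noc, se = _offspring_detection(
        calls_a, calls_b, qualifying, site_callable, het_fraction_min
    )
    return FalseNegativeReport("empirical", det + mis + noc, det, mis, noc, clustered_se=se)


def observed_het_allele_fractions(calls: GenotypeCallSet) -> np.ndarray:
    """Alt-read fractions of offspring genotypes called heterozygous — the
    spike-in allele-fraction pool the real procedure samples from."""
    gt = calls.gt[2:]
    depth = calls.depth[2:]
    alt = calls.alt_count[2:]
    sel = (gt == HET) & (depth > 0)
    return (alt[sel] / depth[sel]).astype(float)


def spike_in_false_negative_rate(
    panel,
    genotypes,
    config,
    thresholds: FilterThresholds,
    mask: CallableMask,
    caller_a: CallerConfig,
    caller_b: CallerConfig,
    af_distribution: np.ndarray,
    n_spikes: int = 1000,
    rng: Optional[np.random.Generator] = None,
    het_fraction_min: float = 0.25,
) -> tuple[FalseNegativeReport, pd.DataFrame]:
    """Spike artificial DNMs into monomorphic callable sites and re-detect.

    Each spike targets one offspring; its mutant-read fraction is a draw
    from ``af_distribution``, evidence is regenerated site-by-site, and the
    full calling/filtering stack is re-run.  Returns the report (miscall
    and no-call fractions separately) and the spike truth table for audit.
    """
    from .synthetic_pedigree import PedigreeEvidence, _draw_annotations

    if af_distribution is None or len(af_distribution) == 0:
        raise ValueError("af_distribution must be nonempty")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 7)

    mono = mask.to_track()
    mono[genotypes.positions] = False
    pool = np.flatnonzero(mono)
    if pool.size < n_spikes:
        raise ValueError(f"only {pool.size} monomorphic callable sites for {n_spikes} spikes")
    positions = np.sort(rng.choice(pool, size=n_spikes, replace=False))

    individuals = genotypes.individuals
    n_ind, n_off = len(individuals), len(individuals) - 2
    target = rng.integers(0, n_off, size=n_spikes)
    af = rng.choice(np.asarray(af_distribution, dtype=float), size=n_spikes, replace=True)

    depth = rng.poisson(config.depth_mean, size=(n_ind, n_spikes))
    p = np.full((n_ind, n_spikes), config.base_error)
    p[target + 2, np.arange(n_spikes)] = af
    alt_count = rng.binomial(depth, p)
    ref = panel.sequence[positions]
    evidence = PedigreeEvidence(
        individuals=individuals,
        positions=positions,
        ref=ref,
        alt=((ref + rng.integers(1, 4, size=n_spikes)) % 4).astype(np.uint8),
        depth=depth,
        alt_count=alt_count,
        annotations=_draw_annotations(config, n_spikes, rng),
        linked_reads={},
    )
    calls_a = call_genotypes(evidence, caller_a)
    calls_b = call_genotypes(evidence, caller_b)
    site_callable = annotation_pass(calls_a.annotations, thresholds)  # in-mask by choice

    det, mis, noc, se = _offspring_detection(
        calls_a,
        calls_b,
        np.arange(n_spikes),
        site_callable,
        het_fraction_min,
        offspring_idx=target,
    )
    truth = pd.DataFrame(
        {
            "position": positions,
            "offspring": [individuals[2 + t] for t in target],
            "allele_fraction": af,
        }
    )
    return FalseNegativeReport("spike-in", det + mis + noc, det, mis, noc, clustered_se=se), truth


def estimate_callable(
    mask: CallableMask, depth_sample: np.ndarray, min_depth: int = 10
) -> CallableReport:
    """Callable bases = masked bases x (1 - insufficient-depth fraction).

    ``depth_sample`` is (positions, individuals) of per-individual depths at
    a random subset of masked positions; a position has insufficient depth
    if any individual falls below ``min_depth``.
    """
    if mask.total_bases == 0:
        raise ValueError("empty callable mask")
    sample = np.atleast_2d(np.asarray(depth_sample))
    if sample.size == 0:
        raise ValueError("depth sample is empty")
    frac = float((sample < min_depth).any(axis=1).mean())
    return CallableReport(
        masked_bases=float(mask.total_bases),
        insufficient_depth_fraction=frac,
        min_depth=min_depth,
    )
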