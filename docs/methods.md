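# Methods

## The problem

`pedmut` implements a pedigree-based (parent–offspring) estimate of the
spontaneous point-mutation rate, modelled on the design used for the
Atlantic herring: two parents and a set of deeply sequenced offspring, a
dual-caller variant-calling scheme with deliberately strict quality
filtering, explicit estimation of the false-negative rate that strictness
creates, and a final per-generation rate

    mu = M / (2 · n · C · (1 − FN))

where `M` counts mutation *carrier events* among the sequenced offspring
(a mutation shared by k siblings contributes k events — one per
transmitted gamete), `n` is the number of sequenced offspring (2n
transmitted haploid genomes), `C` the callable sites per haploid genome,
and `FN` the false-negative proportion. The confidence interval treats
`M` as a Poisson count (exact Garwood interval) and scales both endpoints
by `1/(2nC(1−FN))`.

Downstream, the neutral-diversity relation `pi = 4·Ne·mu` converts the
corrected rate into a long-term effective population size, and
`4·Ne·generations` gives the time scale to approach mutation–drift
equilibrium. Generation time for an age-structured stock is the
fecundity-weighted mean age of spawners (weight as fecundity proxy).

## The synthetic fixture

Real rediscovery of the study's mutations requires ~50× whole-genome data
for 16 individuals; the package instead validates every pipeline stage on
seeded synthetic fixtures produced by `synthetic_pedigree`. The simulator
emulates the study conditions:

* **Reference**: random sequence with a block-wise repeat mask (default
  25% masked), a mappability track that is 1 almost everywhere with
  occasional low-mappability blocks, and a simple gene model (genes with
  exons and one 3'UTR; everything else intergenic).
* **Diversity**: SNP sites seeded so parental heterozygous density equals
  `pi` (default 0.003, the herring's diversity), with Hardy–Weinberg
  parent genotypes at allele frequencies uniform on [0.05, 0.95] and
  Mendelian transmission to offspring. Sites where the parents are
  homozygous for different alleles form the "known heterozygote" class:
  every offspring is an obligate het, which calibrates the filters and
  feeds the empirical false-negative estimator.
* **Coverage and errors**: per-site per-individual depth is
  Poisson(60) (the study's 45–75× range), alt reads Binomial(depth, a)
  with a = 0.5 / base-error / 1−base-error by genotype; the per-read-base
  error rate defaults to 0.005.
* **Quality annotations** (total depth, mapping quality, three rank sums,
  base quality, quality-by-depth, genotype-quality proxy, allele depth)
  are drawn directly from per-annotation normal models rather than from
  simulated reads. The filtering scheme treats them as approximately
  normal marginals and thresholds each at mean ± 2 sd calibrated on
  known-het sites, so only their marginals matter; with nine independent
  annotations the expected retention of a true site is 0.9545⁹ ≈ 0.66,
  which is precisely the false-negative pressure the estimators must then
  measure.
* **Germline mosaicism**: a mutation arising at germline cleavage
  division d is carried by 2^−d of germ cells, hence by a gamete fraction
  f = 2^−(d+1); the "fixed" state (every germ cell heterozygous) has
  f = 0.5. Offspring — sequenced and in the larger transmission panel —
  carry a mutation independently with probability f. The default division
  distribution `{"fixed": 0.05, 2: 0.10, 3: 0.15, 4: 0.20, 5: 0.25,
  6: 0.15, 7: 0.10}` is skewed toward later divisions to reproduce the
  transmission spectrum observed for validated herring DNMs: panel
  frequencies of 2–18%, about half the mutations shared by ≥2 panel
  siblings and none approaching the 50% of a fixed mutation.
* **Monomorphic background**: false positives can only come from
  error-read pileups at monomorphic sites, so the whole background is
  screened exactly using the Poisson-thinning identity (marginal alt
  count ~ Poisson(depth·error); conditional depth = alt +
  Poisson(depth·(1−error))). Only sites with ≥3 error reads in some
  individual are materialised as full evidence.

What the fixture does **not** emulate: alignment artefacts, mapping-error
haplotypes, indels, batch effects between sequencing runs, correlated
annotation failures, or GC/coverage waves. Passing tests therefore show
the pipeline's logic and calibration behave as designed under the stated
generative model — not that the model captures every real-data failure
mode; on real data the dual-caller intersection and the validated-site
calibration are doing work the simulation cannot probe.

## Calling, intersection and filtering

The simplified caller computes binomial genotype likelihoods and
maximum-posterior diploid genotypes with a heterozygote prior; genotype
quality is phred-scaled and capped at 99; depth below a configurable
minimum yields no-call. Two configurations ("A": het prior 10⁻³, minimum
depth 8; "B": 2×10⁻³, minimum depth 4) stand in for the two independent
callers of the real screen; only sites reported as variant by both, with
the same alternate allele and per-individual compatible genotypes (a
no-call defers to the other caller), survive intersection. Per-genotype
compatibility is stricter than pure site-level intersection; it is a
documented design choice.

The callable mask keeps positions with mappability exactly 1 inside
non-overlapping 1 kb windows (tiled from 0 — the window convention is a
design choice) of mean mappability > 0.95, outside the repeat mask.
Threshold bounds are inclusive; two-sided bounds are applied to every
annotation; missing (NaN) annotation values pass, since a filter cannot
fail on absent evidence. A heterozygous genotype is only accepted as a
carrier or obligate het when its minor-allele read fraction exceeds 0.25.

## False-negative estimation

* **Empirical**: at in-mask sites where the parents are fixed for
  different alleles, every offspring is an obligate het; each offspring
  is scored independently through the full detection stack (both callers
  het, allele-fraction rule, annotation bands). Misses include both
  miscalls and failed calls. Qualifying sites are restricted to the
  callable mask because the candidate search and the denominator `C` are.
  The report carries a site-cluster-robust standard error: all offspring
  share a site's filter fate, so assays are not independent.
* **Spike-in**: ~1000 artificial heterozygotes are injected at
  monomorphic callable sites, one target offspring each, with mutant-read
  fractions drawn from the observed allele-fraction distribution of
  called heterozygotes; the pipeline is re-run and miscall and no-call
  fractions reported separately.

The rate correction uses the empirical estimate, mirroring the source
study's choice of the estimate "derived directly from the data set".

## Confidence-interval semantics

The interval on the corrected rate is a detection-stage interval: Poisson
on the observed event count, FN-corrected. Under germline mosaicism the
*ensemble* injected rate (`n_dnms · E[f] / 2C`) carries large
between-mutation transmission variance — whole blocks of siblings are
correlated through the shared gamete fraction — which no count-based
interval can absorb (its Fano factor is ~3 under the default mosaic
distribution). The pipeline therefore reports, and its recovery tests
target, the *realized* injected rate `M_true/(2nC)`: the carrier events
actually present in the sequenced offspring. This matches the assumption
the estimator itself makes ("mutations are Poisson distributed") and is
the quantity a pedigree screen can in principle recover.

## Numerical and convention choices

* Exact statistics are enumerated in-package (hypergeometric and binomial
  in log-space via `gammaln`; Poisson interval via the chi-square
  quantile identity); two-sided p-values use the minimum-likelihood rule,
  the dominant convention in mainstream statistics packages. scipy's
  implementations serve as independent oracles in the test suite only.
* Parental origin requires ≥5 linked reads supporting one parent and
  zero supporting the other; balanced support raises a phase-conflict
  error rather than guessing.
* Coordinates are 0-based half-open internally; 1-based only at VCF
  boundaries. Each simulation stage draws from its own child stream of a
  master seed, so stages are reproducible in isolation and runs are
  byte-deterministic.
* Rates are kept at full precision internally and rounded to two
  significant figures only at the presentation layer.
* The minimum depth for the "insufficient depth" callable correction
  defaults to 10; the under-covered fraction is measured on a random
  sample of masked positions, flagging positions where any individual
  falls below the minimum.

## Problem sizes

Synthetic validation runs on a 1 Mb reference with 12 sequenced offspring
(the study's total meiosis count) — large enough that the known-het
calibration class holds several hundred sites and the background scan
covers ~10⁶ monomorphic positions, small enough for hundred-replicate
studies on a laptop. The coverage study injects 80 DNMs per replicate so
the detected event count (~35) is of the same order as the study's
M = 19. The exhaustive Fisher cross-check enumerates every 2×2 table
with total count ≤ 36 plus a seeded sample with margins up to 60.

## Known limitations

* The family-mosaicism contrast on the published table
  ([[7, 2], [1, 7]] shared-vs-private by family) gives p ≈ 0.015 by exact
  two-sided Fisher; the source reported p = 0.01 with an unstated table
  construction. Both "panel" and "sequenced-offspring" sharing
  definitions are provided; neither is asserted to reproduce 0.01.
* The published binomial p-values for parental-origin bias (0.004) and
  CpG share (0.06) are not reproduced by standard exact conventions on
  the stated counts (0.020 and 0.139 one-sided); the package computes by
  its declared conventions and does not guess the original constructions.
* The published CIs (1.1–2.7 and 1.1–2.9 ×10⁻⁹) do not match any single
  standard Poisson-interval method at 2-digit rounding; intervals here
  are method-declared (Garwood) rather than matched.
* The simulated per-site depth has no genomic autocorrelation, so the
  insufficient-depth fraction in fixtures is essentially zero rather than
  the study's 2.6%; the accounting arithmetic is exercised separately.
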