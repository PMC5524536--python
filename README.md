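# pedmut

Pedigree-based estimation of the spontaneous point-mutation rate, built
around the design used for the Atlantic herring — a species whose
moderate nucleotide diversity (π ≈ 0.3%) despite an enormous census
population is partly explained by the lowest per-generation mutation
rate measured in a vertebrate.

The package is for population geneticists who want a tested, reusable
version of the parent–offspring ("trio") mutation-rate workflow: given
deep whole-genome sequencing of two parents and their offspring, detect
de novo mutations (DNMs) with a dual-caller, strictly filtered scheme;
quantify the false negatives that strictness creates; and convert counts
into a mutation rate with exact confidence intervals and downstream
population-genetic quantities. Because the real data volume (~50× WGS of
16 individuals) is not reproducible at desk scale, a first-class
synthetic-pedigree simulator generates seeded fixtures that emulate the
study conditions, so every stage is testable end to end.

## The model

A de novo mutation is a site where both parents are homozygous reference
and ≥1 offspring is heterozygous. With `M` mutation carrier events among
`n` sequenced offspring (a mutation shared by k siblings counts k times),
`C` callable sites per haploid genome and false-negative rate `FN`:

    mu_raw       = M / (2 n C)
    mu_corrected = mu_raw / (1 − FN)
    CI           = Garwood-exact Poisson interval on M, same scaling

Filtering is calibrated on "known heterozygous" sites (parents fixed for
different alleles, so every offspring is an obligate het): each of nine
site quality annotations is bounded at mean ± 2 sd of its known-het
distribution. The false-negative rate is estimated empirically (obligate
hets re-genotyped per offspring) and by spike-in simulation; germline
mosaicism is modelled by a gamete fraction f = 2^−(d+1) for a mutation at
cleavage division d (f = 0.5 when fixed), which shapes how often siblings
share a mutation. Downstream: Ne = π/(4μ), equilibrium ≈ 4·Ne
generations, and generation time as the fecundity-weighted mean age of
spawners.

## Worked example

Re-derive the published herring numbers from the study's own counts
(M = 19 events, n = 12 offspring, C = 431 Mb, FN = 5.9%, generation time
6 y, π = 0.0032):

```
$ pedmut estimate -m 19 -n 12 -c 431e6 --fn-rate 0.059 -g 6
{
  "mu_raw": 1.836813611755607e-09,
  "mu_corrected": 1.9519804588263623e-09,
  "ci": [1.1752197482445258e-09, 3.048259282549129e-09],
  "per_genome_rate": 0.7916666666666666,
  "mu_per_year": 3.253300764710604e-10
}
```

i.e. 1.8×10⁻⁹ per site per generation uncorrected, 2.0×10⁻⁹ corrected
(≈0.79 mutations per transmitted genome, 3.3×10⁻¹⁰ per site per year) —
with Ne = π/(4μ) ≈ 4×10⁵. `pedmut reproduce` prints the full set
(mutation spectrum Ts/Tv = 10/7 ≈ 1.4, region counts, transmission
Fisher test p ≈ 1.4×10⁻³, …).

Run the whole pipeline on a seeded synthetic fixture and keep every
intermediate (VCFs, masks, thresholds, reports):

```
$ pedmut run --seed 7 --outdir out/
{
  "seed": 7,
  "callable_bases": 695000,
  "n_true_dnms": 20,
  "n_candidates": 7,
  "n_false_positives": 0,
  "M_carrier_events": 16,
  "fn_rate_empirical": 0.3146853146853147,
  "fn_rate_spikein": 0.338,
  "mu_raw": 9.592326139088728e-07,
  "mu_corrected": 1.399696569275192e-06,
  "mu_ci_low": 8.000475278169741e-07,
  "mu_ci_high": 2.273019537299475e-06,
  "realized_rate": 1.079136690647482e-06,
  ...
}
```

Here 20 germline DNMs were injected into a 1 Mb fixture; 7 reached a
detectable carrier and survived the strict filters (16 carrier events),
no false positive was called, and the two independent false-negative
estimators agree that roughly a third of true heterozygotes are lost —
the loss the corrected rate divides out. The CI brackets the realized
injected rate (the carrier events actually transmitted, 1.08×10⁻⁶ on
this deliberately mutation-dense fixture).

Generation time from an age-structured stock table
(`age  abundance  maturity  mean_weight`, TSV):

```
$ pedmut gentime stock.tsv
6.222
```

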