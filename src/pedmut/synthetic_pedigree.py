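"""Seeded synthetic pedigree sequencing fixtures.

Emulates the study design behind a pedigree-based mutation-rate screen in a
high-fecundity fish: two parents and a set of sequenced offspring from a
much larger clutch, short-read coverage of 45-75x, nucleotide diversity
around 0.3%, and germline de novo mutations whose transmission to siblings
reflects parental germline mosaicism.

The simulator produces per-site read-level allele counts plus the site
quality annotations the filtering stage calibrates on.  Quality annotations
are drawn directly from per-annotation normal models rather than derived
from simulated reads: the filtering scheme treats them as approximately
normal marginals and thresholds them at mean +/- 2 sd, so their joint
read-level structure is irrelevant to everything downstream.

Mosaicism model: a mutation arising at germline cleavage division d is
carried by 2^-d of germ cells and hence by a fraction f = 2^-(d+1) of
gametes; a "fixed" mutation (present in every germ cell, heterozygous) has
f = 0.5, the classical expectation for a single-meiosis transmission test.
Each offspring — sequenced or in the larger genotyping panel — carries the
mutation independently with probability f.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .genotype_calling import HET, HOM_ALT, HOM_REF
from .site_filtering import ANNOTATION_NAMES

__all__ = [
    "NUCLEOTIDES",
    "ReferencePanel",
    "PedigreeSimConfig",
    "TrueDNM",
    "PedigreeGenotypes",
    "PedigreeEvidence",
    "simulate_reference",
    "simulate_pedigree_genotypes",
    "inject_germline_mutations",
    "simulate_site_evidence",
    "scan_monomorphic_background",
    "intervals_from_bool",
    "bool_from_intervals",
]

NUCLEOTIDES = np.frombuffer(b"ACGT", dtype=np.uint8)

FATHER, MOTHER = "father", "mother"


def intervals_from_bool(track: np.ndarray) -> np.ndarray:
    """Half-open [start, end) intervals of the True runs of a boolean track."""
    track = np.asarray(track, dtype=bool)
    if track.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    padded = np.concatenate(([False], track, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return np.column_stack([starts, ends]).astype(np.int64)


def bool_from_intervals(intervals: np.ndarray, length: int) -> np.ndarray:
    track = np.zeros(length, dtype=bool)
    for s, e in np.asarray(intervals, dtype=np.int64).reshape(-1, 2):
        track[s:e] = True
    return track


@dataclass(frozen=True)
class ReferencePanel:
    """A synthetic reference: sequence, repeat mask, mappability and a
    simple gene annotation (genes containing exons and one 3'UTR each;
    everything outside genes is intergenic)."""

    sequence: np.ndarray          # uint8 codes 0..3 -> ACGT
    repeat_mask: np.ndarray       # (k, 2) sorted, non-overlapping
    mappability: np.ndarray       # float in [0, 1], one per base
    genes: np.ndarray             # (g, 2)
    exons: np.ndarray             # (e, 2), inside genes
    utr3: np.ndarray              # (u, 2), inside genes

    @property
    def length(self) -> int:
        return int(self.sequence.size)

    def base(self, position: int) -> str:
        return chr(NUCLEOTIDES[self.sequence[position]])

    def trinucleotide(self, position: int) -> str:
        """Context prev+ref+next; 'N' padding at the ends."""
        out = []
        for p in (position - 1, position, position + 1):
            out.append(self.base(p) if 0 <= p < self.length else "N")
        return "".join(out)

    def __post_init__(self) -> None:
        if np.any((self.mappability < 0) | (self.mappability > 1)):
            raise ValueError("mappability values must lie in [0, 1]")
        if self.mappability.size != self.sequence.size:
            raise ValueError("mappability track length mismatch")
        rm = np.asarray(self.repeat_mask)
        if rm.size and (np.any(rm[:-1, 1] > rm[1:, 0]) or rm[0, 0] < 0 or rm[-1, 1] > self.length):
            raise ValueError("repeat mask intervals must be sorted, disjoint and in range")


def _random_block_track(
    length: int, block: int, p_block: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean track built from independent fixed-size blocks."""
    n_blocks = -(-length // block)
    hit = rng.random(n_blocks) < p_block
    return np.repeat(hit, block)[:length]


def simulate_reference(
    length: int,
    repeat_fraction: float = 0.25,
    seed: int = 0,
    *,
    repeat_block: int = 250,
    low_mappability_block_fraction: float = 0.04,
    low_mappability_block: int = 500,
) -> ReferencePanel:
    """Generate a random reference panel.

    Repeats are laid down as independent 250 bp blocks hit with probability
    ``repeat_fraction``, so the realised masked proportion is binomial
    around the target.  A small fraction of 500 bp blocks get mappability
    below 1 (uniform on [0, 0.99]); everything else is mappability 1.
    """
    if length < 1:
        raise ValueError("length must be positive")
    if length < 10_000:
        raise ValueError("reference shorter than 10 kb is below the supported scale")
    if not 0.0 <= repeat_fraction <= 0.9:
        raise ValueError(f"repeat_fraction {repeat_fraction} outside [0, 0.9]")
    rng = np.random.default_rng(seed)
    sequence = rng.integers(0, 4, size=length, dtype=np.uint8)

    repeat_track = (
        _random_block_track(length, repeat_block, repeat_fraction, rng)
        if repeat_fraction > 0
        else np.zeros(length, dtype=bool)
    )
    repeat_mask = intervals_from_bool(repeat_track)

    mappability = np.ones(length, dtype=np.float64)
    low_track = _random_block_track(length, low_mappability_block, low_mappability_block_fraction, rng)
    for s, e in intervals_from_bool(low_track):
        mappability[s:e] = rng.uniform(0.0, 0.99)

    genes, exons, utr3 = [], [], []
    pos = int(rng.integers(500, 4000))
    while pos < length - 4000:
        glen = int(rng.integers(2000, 8000))
        gend = min(pos + glen, length)
        genes.append((pos, gend))
        utr = (max(pos, gend - 300), gend)
        utr3.append(utr)
        n_ex = max(1, (gend - pos) // 2500)
        for _ in range(n_ex):
            es = int(rng.integers(pos, max(pos + 1, utr[0] - 150)))
            exons.append((es, min(es + 150, utr[0])))
        pos = gend + int(rng.integers(2000, 10000))

    def _arr(iv):
        a = np.array(sorted(iv), dtype=np.int64).reshape(-1, 2)
        return a

    return ReferencePanel(
        sequence=sequence,
        repeat_mask=repeat_mask,
        mappability=mappability,
        genes=_arr(genes),
        exons=_arr(exons),
        utr3=_arr(utr3),
    )


# per-annotation (mean, sd) of the simulated site quality statistics; values
# are on the scales the corresponding caller annotations usually take, but
# only their normality matters to the calibrated +/- 2 sd filter
DEFAULT_ANNOTATION_MODEL: dict[str, tuple[float, float]] = {
    "DP": (960.0, 90.0),
    "MQ": (60.0, 3.0),
    "MQRankSum": (0.0, 1.0),
    "BaseQ": (30.0, 2.0),
    "BaseQRankSum": (0.0, 1.0),
    "ReadPosRankSum": (0.0, 1.0),
    "QD": (20.0, 5.0),
    "GQ": (80.0, 10.0),
    "AD": (30.0, 6.0),
}


@dataclass(frozen=True)
class PedigreeSimConfig:
    """Study-design parameters for one simulated pedigree.

    Defaults mirror the real design: heterozygosity pi = 0.003, six
    sequenced offspring from a clutch of 50, ~60x coverage with 125 bp
    reads.  ``mosaic_division_distribution`` gives probability weights over
    the germline division index d >= 1 (gamete fraction 2^-(d+1)) plus the
    "fixed" state (f = 0.5).  Its default is skewed toward later divisions
    (small f), chosen to reproduce the observed transmission spectrum of
    validated herring DNMs — panel frequencies of 2-18%, half the
    mutations near-singletons, none approaching the 50% of a germline-fixed
    mutation — while leaving a small weight on the fixed state the model
    must support.
    """

    pi: float = 0.003
    n_offspring_sequenced: int = 6
    n_offspring_panel: int = 50
    depth_mean: float = 60.0
    read_length: int = 125
    base_error: float = 0.005
    n_dnms: int = 20
    mosaic_division_distribution: Mapping[Union[str, int], float] = field(
        default_factory=lambda: {"fixed": 0.05, 2: 0.10, 3: 0.15, 4: 0.20, 5: 0.25, 6: 0.15, 7: 0.10}
    )
    annotation_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ANNOTATION_MODEL)
    )
    phase_informative_prob: float = 0.8
    linked_reads_mean: float = 8.0
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pi <= 0.01:
            raise ValueError(f"pi {self.pi} outside [0, 0.01]")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be non-negative")
        if not 0.0 < self.base_error < 0.5:
            raise ValueError("base_error must lie in (0, 0.5)")
        if self.n_dnms < 0 or self.n_offspring_sequenced < 1:
            raise ValueError("counts must be non-negative (and >=1 sequenced offspring)")
        total = float(sum(self.mosaic_division_distribution.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError("mosaic division probabilities must sum to 1")
        for k in self.mosaic_division_distribution:
            if k != "fixed" and (int(k) != k or k < 1):
                raise ValueError(f"division index must be 'fixed' or an integer >= 1, got {k!r}")
        if set(self.annotation_model) != set(ANNOTATION_NAMES):
            raise ValueError("annotation_model must cover exactly the calibration annotation list")

    @property
    def offspring_ids(self) -> tuple[str, ...]:
        return tuple(f"off{i + 1:02d}" for i in range(self.n_offspring_sequenced))

    @property
    def individuals(self) -> tuple[str, ...]:
        return (FATHER, MOTHER) + self.offspring_ids

    def expected_gamete_fraction(self) -> float:
        """E[f] under the mosaic division distribution."""
        total = 0.0
        for d, w in self.mosaic_division_distribution.items():
            f = 0.5 if d == "fixed" else 2.0 ** (-(int(d) + 1))
            total += w * f
        return total

    def expected_rate(self, callable_bases: float) -> float:
        """Injected per-site per-generation rate implied by the config:
        n_dnms * E[f] / (2 C), the expectation of M / (2 n C)."""
        return self.n_dnms * self.expected_gamete_fraction() / (2.0 * callable_bases)


@dataclass(frozen=True)
class TrueDNM:
    """Ground truth for one injected germline mutation."""

    position: int
    ref_allele: str
    alt_allele: str
    origin_parent: str                 # "maternal" | "paternal"
    division: Union[str, int]          # "fixed" or cleavage division index
    gamete_fraction: float
    carrier_offspring: tuple[str, ...]  # among sequenced offspring
    panel_carriers: int
    panel_size: int
    phase_informative: bool

    def __post_init__(self) -> None:
        if self.alt_allele == self.ref_allele:
            raise ValueError("alt allele must differ from ref")
        if not 0.0 < self.gamete_fraction <= 0.5:
            raise ValueError("gamete fraction must lie in (0, 0.5]")
        if self.panel_carriers > self.panel_size:
            raise ValueError("panel carriers cannot exceed panel size")


@dataclass(frozen=True)
class PedigreeGenotypes:
    """True diploid genotypes at the pedigree's variant sites.

    ``gt`` is (n_individuals, n_sites) with codes 0 hom-ref, 1 het,
    2 hom-alt; row order is father, mother, then offspring.  Sites absent
    from ``positions`` are homozygous reference in everyone.
    """

    individuals: tuple[str, ...]
    positions: np.ndarray
    ref: np.ndarray                    # uint8 codes
    alt: np.ndarray
    gt: np.ndarray
    length: int
    is_dnm: np.ndarray
    true_dnms: tuple[TrueDNM, ...] = ()

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    @property
    def offspring(self) -> tuple[str, ...]:
        return self.individuals[2:]

    def parent_het_density(self, parent: str) -> float:
        row = self.gt[self.individuals.index(parent)]
        return float((row == HET).sum()) / self.length


def _spawn(config: PedigreeSimConfig, stage: str) -> np.random.Generator:
    """One independent RNG stream per simulation stage, keyed on the master
    seed and a stage label, so stages are reproducible in isolation."""
    label = np.frombuffer(stage.encode(), dtype=np.uint8)
    return np.random.default_rng(np.random.SeedSequence((config.seed, *label.tolist())))


def simulate_pedigree_genotypes(
    panel: ReferencePanel,
    config: PedigreeSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> PedigreeGenotypes:
    """Draw parental genotypes and Mendelian offspring at SNP sites.

    SNP sites are seeded at density pi / E[2q(1-q)] with population allele
    frequency q uniform on ``allele_freq_range``; parent genotypes are
    Hardy-Weinberg draws, so per-parent heterozygous density comes out at
    pi.  Sites monomorphic hom-ref in both parents are dropped (they are
    indistinguishable from the reference background, which the evidence
    stage screens separately).  Offspring receive one uniformly chosen
    allele per parent, independently across sites.
    """
    rng = rng if rng is not None else _spawn(config, "genotypes")
    length = panel.length
    a, b = config.allele_freq_range
    # E[2q(1-q)] for q ~ U(a, b), from E[q] and E[q^2]
    eq, eq2 = (a + b) / 2.0, (a * a + a * b + b * b) / 3.0
    mean_het = 2.0 * (eq - eq2)
    density = config.pi / mean_het if config.pi > 0 else 0.0

    positions = np.flatnonzero(rng.random(length) < density)
    q = rng.uniform(a, b, size=positions.size)
    gt_father = rng.binomial(2, q).astype(np.int8)
    gt_mother = rng.binomial(2, q).astype(np.int8)
    keep = (gt_father + gt_mother) > 0
    positions, gt_father, gt_mother = positions[keep], gt_father[keep], gt_mother[keep]

    n_sites = positions.size
    ref = panel.sequence[positions]
    alt = ((ref + rng.integers(1, 4, size=n_sites)) % 4).astype(np.uint8)

    n_off = config.n_offspring_sequenced
    gt = np.empty((2 + n_off, n_sites), dtype=np.int8)
    gt[0], gt[1] = gt_father, gt_mother
    for j, parent_gt in enumerate((gt_father, gt_mother)):
        transmit_alt = (parent_gt == HOM_ALT) | (
            (parent_gt == HET) & (rng.random((n_off, n_sites)) < 0.5)
        )
        if j == 0:
            alt_doses = transmit_alt.astype(np.int8)
        else:
            alt_doses += transmit_alt.astype(np.int8)
    gt[2:] = alt_doses

    return PedigreeGenotypes(
        individuals=config.individuals,
        positions=positions,
        ref=ref,
        alt=alt,
        gt=gt,
        length=length,
        is_dnm=np.zeros(n_sites, dtype=bool),
        true_dnms=(),
    )


def inject_germline_mutations(
    panel: ReferencePanel,
    genotypes: PedigreeGenotypes,
    config: PedigreeSimConfig,
    rng: Optional[np.random.Generator] = None,
    allowed_positions: Optional[np.ndarray] = None,
) -> PedigreeGenotypes:
    """Inject germline de novo mutations at parentally monomorphic sites.

    Each mutation gets an origin parent (fair coin), a division index from
    the mosaic distribution (gamete fraction f = 2^-(d+1); "fixed" means
    f = 0.5), and independent Bernoulli(f) carrier draws for the sequenced
    offspring and for the larger genotyping panel.  Parents stay
    homozygous reference somatically — the mutation lives only in the
    origin parent's germ line.  ``allowed_positions`` restricts injection
    (e.g. to the callable mask) so injected truth matches the region the
    rate estimator will later normalise by.
    """
    rng = rng if rng is not None else _spawn(config, "dnms")
    if config.n_dnms == 0:
        return genotypes

    candidate = np.ones(genotypes.length, dtype=bool)
    candidate[genotypes.positions] = False
    if allowed_positions is not None:
        restricted = np.zeros(genotypes.length, dtype=bool)
        restricted[np.asarray(allowed_positions, dtype=np.int64)] = True
        candidate &= restricted
    pool = np.flatnonzero(candidate)
    if pool.size < config.n_dnms:
        raise ValueError(
            f"requested {config.n_dnms} DNMs but only {pool.size} monomorphic candidate sites"
        )
    sites = np.sort(rng.choice(pool, size=config.n_dnms, replace=False))

    states = list(config.mosaic_division_distribution)
    weights = np.array([config.mosaic_division_distribution[s] for s in states], dtype=float)
    chosen = rng.choice(len(states), size=config.n_dnms, p=weights / weights.sum())

    offspring = genotypes.offspring
    n_off = len(offspring)
    dnms: list[TrueDNM] = []
    gt_new = np.zeros((len(genotypes.individuals), config.n_dnms), dtype=np.int8)
    ref_new = panel.sequence[sites]
    alt_new = ((ref_new + rng.integers(1, 4, size=config.n_dnms)) % 4).astype(np.uint8)

    for i, pos in enumerate(sites):
        state = states[chosen[i]]
        f = 0.5 if state == "fixed" else 2.0 ** (-(int(state) + 1))
        carriers_mask = rng.random(n_off) < f
        carriers = tuple(o for o, hit in zip(offspring, carriers_mask) if hit)
        gt_new[2:, i] = np.where(carriers_mask, HET, HOM_REF)
        dnms.append(
            TrueDNM(
                position=int(pos),
                ref_allele=chr(NUCLEOTIDES[ref_new[i]]),
                alt_allele=chr(NUCLEOTIDES[alt_new[i]]),
                origin_parent="paternal" if rng.random() < 0.5 else "maternal",
                division=state,
                gamete_fraction=f,
                carrier_offspring=carriers,
                panel_carriers=int(rng.binomial(config.n_offspring_panel, f)),
                panel_size=config.n_offspring_panel,
                phase_informative=bool(rng.random() < config.phase_informative_prob),
            )
        )

    positions = np.concatenate([genotypes.positions, sites])
    order = np.argsort(positions, kind="stable")
    return PedigreeGenotypes(
        individuals=genotypes.individuals,
        positions=positions[order],
        ref=np.concatenate([genotypes.ref, ref_new])[order],
        alt=np.concatenate([genotypes.alt, alt_new])[order],
        gt=np.concatenate([genotypes.gt, gt_new], axis=1)[:, order],
        length=genotypes.length,
        is_dnm=np.concatenate([genotypes.is_dnm, np.ones(config.n_dnms, dtype=bool)])[order],
        true_dnms=genotypes.true_dnms + tuple(dnms),
    )


@dataclass(frozen=True)
class PedigreeEvidence:
    """Read-level evidence and site annotations at candidate variant sites.

    ``depth`` and ``alt_count`` are (n_individuals, n_sites);
    ``annotations`` holds one simulated site-level value per calibration
    annotation.  ``linked_reads`` maps a DNM position to counts of reads
    jointly covering the mutant allele and a parent-diagnostic flanking
    allele, keyed "father"/"mother".
    """

    individuals: tuple[str, ...]
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    depth: np.ndarray
    alt_count: np.ndarray
    annotations: pd.DataFrame
    linked_reads: dict[int, dict[str, int]] = field(default_factory=dict)

    @property
    def ref_count(self) -> np.ndarray:
        return self.depth - self.alt_count

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def no_data_sites(self) -> np.ndarray:
        """Positions where no individual produced a single read."""
        return self.positions[self.depth.sum(axis=0) == 0]

    def concat(self, other: "PedigreeEvidence") -> "PedigreeEvidence":
        if self.individuals != other.individuals:
            raise ValueError("evidence sample lists differ")
        positions = np.concatenate([self.positions, other.positions])
        order = np.argsort(positions, kind="stable")
        ann = pd.concat([self.annotations, other.annotations], ignore_index=True)
        return PedigreeEvidence(
            individuals=self.individuals,
            positions=positions[order],
            ref=np.concatenate([self.ref, other.ref])[order],
            alt=np.concatenate([self.alt, other.alt])[order],
            depth=np.concatenate([self.depth, other.depth], axis=1)[:, order],
            alt_count=np.concatenate([self.alt_count, other.alt_count], axis=1)[:, order],
            annotations=ann.iloc[order].reset_index(drop=True),
            linked_reads={**self.linked_reads, **other.linked_reads},
        )


def _draw_annotations(
    config: PedigreeSimConfig, n_sites: int, rng: np.random.Generator
) -> pd.DataFrame:
    cols = {
        name: rng.normal(*config.annotation_model[name], size=n_sites)
        for name in ANNOTATION_NAMES
    }
    return pd.DataFrame(cols)


def simulate_site_evidence(
    genotypes: PedigreeGenotypes,
    config: PedigreeSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> PedigreeEvidence:
    """Per-individual read counts and site annotations at the variant sites.

    Depth is Poisson(depth_mean); alt reads are Binomial(depth, a) with
    a = 0.5 for heterozygotes, base_error for hom-ref and 1 - base_error
    for hom-alt.  For true-DNM sites with a phase-informative flanking
    heterozygote, linked-read support for the origin parent is Poisson
    around ``linked_reads_mean`` with zero reads supporting the other
    parent.
    """
    rng = rng if rng is not None else _spawn(config, "evidence")
    n_ind, n_sites = genotypes.gt.shape
    depth = rng.poisson(config.depth_mean, size=(n_ind, n_sites))
    e = config.base_error
    af = np.choose(genotypes.gt, [e, 0.5, 1.0 - e])
    alt_count = rng.binomial(depth, af)

    linked: dict[int, dict[str, int]] = {}
    for dnm in genotypes.true_dnms:
        if dnm.phase_informative:
            support = int(rng.poisson(config.linked_reads_mean))
            origin = FATHER if dnm.origin_parent == "paternal" else MOTHER
            other = MOTHER if origin == FATHER else FATHER
            linked[dnm.position] = {origin: support, other: 0}
        else:
            linked[dnm.position] = {FATHER: 0, MOTHER: 0}

    return PedigreeEvidence(
        individuals=genotypes.individuals,
        positions=genotypes.positions.copy(),
        ref=genotypes.ref.copy(),
        alt=genotypes.alt.copy(),
        depth=depth,
        alt_count=alt_count,
        annotations=_draw_annotations(config, n_sites, rng),
        linked_reads=linked,
    )


def scan_monomorphic_background(
    panel: ReferencePanel,
    genotypes: PedigreeGenotypes,
    config: PedigreeSimConfig,
    rng: Optional[np.random.Generator] = None,
    min_alt_reads: int = 3,
) -> PedigreeEvidence:
    """Screen every monomorphic reference site for error-read pileups.

    Marginally the alt-read count of a hom-ref individual is
    Poisson(depth_mean * base_error) (Poisson depth thinned by the error
    rate), so the whole background can be screened with one Poisson draw
    per site and individual.  Sites where any individual accumulates
    ``min_alt_reads`` or more error reads — the only ones that could ever
    tempt a caller toward a false positive — are materialised as full
    evidence rows, with depth completed from the exact conditional
    depth = alt + Poisson(depth_mean * (1 - base_error)).
    """
    rng = rng if rng is not None else _spawn(config, "background")
    mono = np.ones(genotypes.length, dtype=bool)
    mono[genotypes.positions] = False
    mono_pos = np.flatnonzero(mono)
    n_ind = len(genotypes.individuals)
    lam_alt = config.depth_mean * config.base_error

    alt = np.empty((n_ind, mono_pos.size), dtype=np.uint8)
    for i in range(n_ind):
        alt[i] = np.minimum(rng.poisson(lam_alt, size=mono_pos.size), 255).astype(np.uint8)
    hot = np.flatnonzero((alt >= min_alt_reads).any(axis=0))

    positions = mono_pos[hot]
    alt_count = alt[:, hot].astype(np.int64)
    depth = alt_count + rng.poisson(config.depth_mean * (1.0 - config.base_error), size=alt_count.shape)
    ref = panel.sequence[positions]
    alt_allele = ((ref + rng.integers(1, 4, size=positions.size)) % 4).astype(np.uint8)
    return PedigreeEvidence(
        individuals=genotypes.individuals,
        positions=positions,
        ref=ref,
        alt=alt_allele,
        depth=depth,
        alt_count=alt_count,
        annotations=_draw_annotations(config, positions.size, rng),
        linked_reads={},
    )
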