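"""A simplified likelihood-based diploid genotype caller.

Stands in for the dual external callers of the real screen: the same
binomial read-count model is run under two configurations (different
heterozygote priors and minimum call depths), and only variants detected
by both configurations survive intersection.  For a biallelic site with n
reads of which k support the alternate allele and per-read error e:

    L(hom-ref) = C(n,k) (1-e)^(n-k) e^k
    L(het)     = C(n,k) 0.5^n
    L(hom-alt) = C(n,k) e^(n-k) (1-e)^k

Posteriors apply a prior of het_prior on the heterozygote and equal shares
of the remainder on each homozygote; genotype quality is the phred-scaled
probability that the chosen genotype is wrong, capped at 99.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "NO_CALL",
    "CallerConfig",
    "GenotypeCallSet",
    "genotype_likelihoods",
    "call_site",
    "call_genotypes",
    "intersect_callsets",
]

HOM_REF, HET, HOM_ALT, NO_CALL = 0, 1, 2, -1

MAX_GQ = 99.0


@dataclass(frozen=True)
class CallerConfig:
    base_error: float = 0.005
    het_prior: float = 1e-3
    min_depth_for_call: int = 8
    label: str = "A"

    def __post_init__(self) -> None:
        if not 0.0 < self.base_error < 0.5:
            raise ValueError(f"base_error {self.base_error} outside (0, 0.5)")
        if not 0.0 < self.het_prior < 1.0:
            raise ValueError(f"het_prior {self.het_prior} outside (0, 1)")
        if self.min_depth_for_call < 0:
            raise ValueError("min_depth_for_call must be non-negative")


# two default configurations, different enough that their intersection is
# non-trivial; the values are artifact configuration, not doctrine
CALLER_A = CallerConfig(het_prior=1e-3, min_depth_for_call=8, label="A")
CALLER_B = CallerConfig(het_prior=2e-3, min_depth_for_call=4, label="B")


def genotype_likelihoods(ref_count, alt_count, base_error: float) -> np.ndarray:
    """Normalized likelihood triple(s) (hom-ref, het, hom-alt).

    Accepts scalars or arrays; returns shape (..., 3) summing to 1 along
    the last axis.  Zero total depth yields the uniform triple.
    """
    if not 0.0 < base_error < 0.5:
        raise ValueError(f"base_error {base_error} outside (0, 0.5)")
    ref = np.asarray(ref_count)
    alt = np.asarray(alt_count)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("read counts must be non-negative")
    n = ref + alt
    log_e, log_1me = np.log(base_error), np.log1p(-base_error)
    loglik = np.stack(
        [
            ref * log_1me + alt * log_e,
            n * np.log(0.5),
            ref * log_e + alt * log_1me,
        ],
        axis=-1,
    )
    loglik -= loglik.max(axis=-1, keepdims=True)
    lik = np.exp(loglik)
    lik /= lik.sum(axis=-1, keepdims=True)
    return lik


@dataclass(frozen=True)
class GenotypeCallSet:
    """Genotype calls from one caller configuration.

    ``gt`` is (n_individuals, n_sites) of {0 hom-ref, 1 het, 2 hom-alt,
    -1 no-call}; allele depths are carried so downstream allele-fraction
    rules can be applied; site annotations ride along from the evidence.
    """

    label: str
    individuals: tuple[str, ...]
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    gt: np.ndarray
    gq: np.ndarray
    depth: np.ndarray
    alt_count: np.ndarray
    annotations: pd.DataFrame
    linked_reads: dict = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return int(self.positions.size)

    def variant_site_index(self) -> np.ndarray:
        """Indices of sites where at least one call carries the alt allele."""
        return np.flatnonzero(((self.gt == HET) | (self.gt == HOM_ALT)).any(axis=0))

    def take(self, idx: np.ndarray) -> "GenotypeCallSet":
        keep = set(self.positions[idx].tolist())
        return replace(
            self,
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            gt=self.gt[:, idx],
            gq=self.gq[:, idx],
            depth=self.depth[:, idx],
            alt_count=self.alt_count[:, idx],
            annotations=self.annotations.iloc[idx].reset_index(drop=True),
            linked_reads={p: v for p, v in self.linked_reads.items() if p in keep},
        )


def _posterior(lik: np.ndarray, het_prior: float) -> np.ndarray:
    prior = np.array([(1.0 - het_prior) / 2.0, het_prior, (1.0 - het_prior) / 2.0])
    post = lik * prior
    post /= post.sum(axis=-1, keepdims=True)
    return post


def call_site(ref_count: int, alt_count: int, config: CallerConfig) -> tuple[int, float]:
    """Call one individual at one site; returns (genotype code, quality)."""
    if ref_count + alt_count < config.min_depth_for_call:
        return NO_CALL, 0.0
    post = _posterior(genotype_likelihoods(ref_count, alt_count, config.base_error),
                      config.het_prior)
    g = int(np.argmax(post))
    err = max(1.0 - float(post[g]), 10 ** (-MAX_GQ / 10.0))
    return g, min(-10.0 * np.log10(err), MAX_GQ)


def call_genotypes(evidence, config: CallerConfig) -> GenotypeCallSet:
    """Vectorised calling of every individual at every evidence site."""
    ref_count = evidence.ref_count
    alt_count = evidence.alt_count
    post = _posterior(
        genotype_likelihoods(ref_count, alt_count, config.base_error), config.het_prior
    )
    gt = np.argmax(post, axis=-1).astype(np.int8)
    best = np.take_along_axis(post, gt[..., None].astype(np.int64), axis=-1)[..., 0]
    err = np.maximum(1.0 - best, 10 ** (-MAX_GQ / 10.0))
    gq = np.minimum(-10.0 * np.log10(err), MAX_GQ)
    nocall = evidence.depth < config.min_depth_for_call
    gt[nocall] = NO_CALL
    gq[nocall] = 0.0
    return GenotypeCallSet(
        label=config.label,
        individuals=tuple(evidence.individuals),
        positions=evidence.positions.copy(),
        ref=evidence.ref.copy(),
        alt=evidence.alt.copy(),
        gt=gt,
        gq=gq,
        depth=evidence.depth.copy(),
        alt_count=evidence.alt_count.copy(),
        annotations=evidence.annotations.copy(),
        linked_reads=dict(evidence.linked_reads),
    )


def intersect_callsets(set_a: GenotypeCallSet, set_b: GenotypeCallSet) -> GenotypeCallSet:
    """Variant sites detected by both callers, with compatible genotypes.

    A site is retained iff both call sets report a variant (some individual
    called het or hom-alt) at the same position with the same alternate
    allele, and every individual's genotypes are compatible: identical, or
    a no-call in one caller deferring to the other.  Resolved genotypes take
    the called value where one side is a no-call; annotations come from
    ``set_a``.
    """
    if tuple(set_a.individuals) != tuple(set_b.individuals):
        raise ValueError("call sets cover different sample lists")
    ia = set_a.variant_site_index()
    ib = set_b.variant_site_index()
    pos_a = set_a.positions[ia]
    pos_b = set_b.positions[ib]
    common, sub_a, sub_b = np.intersect1d(pos_a, pos_b, return_indices=True)
    ja, jb = ia[sub_a], ib[sub_b]

    same_alt = set_a.alt[ja] == set_b.alt[jb]
    gt_a, gt_b = set_a.gt[:, ja], set_b.gt[:, jb]
    compatible = ((gt_a == gt_b) | (gt_a == NO_CALL) | (gt_b == NO_CALL)).all(axis=0)
    keep = same_alt & compatible

    ja, jb = ja[keep], jb[keep]
    out = set_a.take(ja)
    resolved = out.gt.copy()
    fill = resolved == NO_CALL
    resolved[fill] = set_b.gt[:, jb][fill]
    return replace(out, label=f"{set_a.label}&{set_b.label}", gt=resolved)
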