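"""Candidate de novo mutation detection and characterisation.

A candidate DNM is a filtered, caller-intersected site where both parents
are called homozygous reference and at least one offspring is a convincing
heterozygote.  Candidates are then characterised: transition/transversion
class, CpG context, genomic region (exonic > 3'UTR > intronic >
intergenic), read-backed parental origin, and transmission frequency in
the larger sibling panel — the signature used to diagnose parental
germline mosaicism, since a germline-fixed mutation should reach half the
siblings while early-division mosaics transmit less often.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exact_stats import ContingencyTable2x2, ExactTestResult, fisher_exact_two_sided
from .genotype_calling import GenotypeCallSet, HET, HOM_REF

__all__ = [
    "CandidateDNM",
    "PhaseConflictError",
    "detect_candidates",
    "classify_mutation",
    "annotate_region",
    "infer_parental_origin",
    "transmission_summary",
    "mosaicism_contrast",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
VALID = PURINES | PYRIMIDINES

REGION_PRECEDENCE = ("exonic", "3'UTR", "intronic", "intergenic")


class PhaseConflictError(RuntimeError):
    """Linked reads support both parental origins above threshold."""


@dataclass(frozen=True)
class CandidateDNM:
    position: int
    ref_allele: str
    alt_allele: str
    carrier_offspring: tuple[str, ...]   # sequenced offspring called het
    mutation_class: str = "unknown"      # "transition" | "transversion"
    cpg_flag: bool = False
    region_class: str = "unknown"
    origin: str = "unknown"              # "maternal" | "paternal" | "unknown"
    panel_carriers: int = 0
    panel_size: int = 0
    family: str = ""

    def __post_init__(self) -> None:
        if not self.carrier_offspring:
            raise ValueError("a candidate DNM needs at least one carrier offspring")
        if self.panel_carriers > self.panel_size:
            raise ValueError("panel carriers cannot exceed panel size")

    @property
    def shared(self) -> bool:
        """Carried by two or more panel siblings (the mosaicism signal)."""
        return self.panel_carriers >= 2

    @property
    def shared_sequenced(self) -> bool:
        return len(self.carrier_offspring) >= 2

    def freq_string(self) -> str:
        """Panel transmission as 'carriers/size (pct%)', the percentage
        withheld (dash) when fewer than two carriers were seen."""
        if self.panel_size == 0:
            return "-"
        base = f"{self.panel_carriers}/{self.panel_size}"
        if self.panel_carriers >= 2:
            return f"{base} ({round(100 * self.panel_carriers / self.panel_size):g}%)"
        return f"{base} (-)"


def detect_candidates(
    calls: GenotypeCallSet, het_fraction_min: float = 0.25
) -> list[CandidateDNM]:
    """Sites with both parents called hom-ref and >= 1 heterozygous offspring.

    Offspring heterozygotes must pass the same minor-allele-fraction rule
    used for the known-het calibration set.  Multiple heterozygous siblings
    at one site yield a single candidate with several carriers.
    """
    father, mother = calls.gt[0], calls.gt[1]
    parents_ref = (father == HOM_REF) & (mother == HOM_REF)

    off_gt = calls.gt[2:]
    off_depth = calls.depth[2:]
    off_alt = calls.alt_count[2:]
    with np.errstate(invalid="ignore"):
        alt_frac = np.where(off_depth > 0, off_alt / np.maximum(off_depth, 1), 0.0)
    minor = np.minimum(alt_frac, 1.0 - alt_frac)
    carrier = (off_gt == HET) & (minor > het_fraction_min)

    offspring = calls.individuals[2:]

    def _nuc(x) -> str:  # accept simulator base codes 0..3 or plain letters
        return "ACGT"[int(x)] if not isinstance(x, str) else x

    out: list[CandidateDNM] = []
    for i in np.flatnonzero(parents_ref & carrier.any(axis=0)):
        carriers = tuple(o for o, hit in zip(offspring, carrier[:, i]) if hit)
        out.append(
            CandidateDNM(
                position=int(calls.positions[i]),
                ref_allele=_nuc(calls.ref[i]),
                alt_allele=_nuc(calls.alt[i]),
                carrier_offspring=carriers,
            )
        )
    return out


def classify_mutation(ref: str, alt: str, context: str = "NNN") -> tuple[str, bool]:
    """Transition/transversion class and CpG flag for a substitution.

    ``context`` is the trinucleotide previous+ref+next.  The CpG flag marks
    C>T with a following G, or its reverse-strand image G>A with a
    preceding C, so the classification is strand-symmetric.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in VALID or alt not in VALID:
        raise ValueError(f"invalid nucleotide in {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if len(context) != 3:
        raise ValueError("context must be a trinucleotide")
    transition = {ref, alt} in ({"A", "G"}, {"C", "T"})
    mclass = "transition" if transition else "transversion"
    cpg = (ref == "C" and alt == "T" and context[2].upper() == "G") or (
        ref == "G" and alt == "A" and context[0].upper() == "C"
    )
    return mclass, cpg


def _in_intervals(position: int, intervals: np.ndarray) -> bool:
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if not iv.size:
        return False
    j = np.searchsorted(iv[:, 0], position, side="right") - 1
    return j >= 0 and position < iv[j, 1]


def annotate_region(position: int, genes, exons, utr3) -> str:
    """Region class with precedence exonic > 3'UTR > intronic > intergenic."""
    if _in_intervals(position, exons):
        return "exonic"
    if _in_intervals(position, utr3):
        return "3'UTR"
    if _in_intervals(position, genes):
        return "intronic"
    return "intergenic"


def infer_parental_origin(
    linked_support: Optional[dict], min_linked_reads: int = 5
) -> str:
    """Parental origin from reads linking the DNM to parent-diagnostic alleles.

    Requires at least ``min_linked_reads`` reads jointly carrying the
    mutant allele and an allele unique to one parent, with zero such reads
    for the other parent; anything weaker is "unknown", and support for
    both parents at threshold raises ``PhaseConflictError`` — a tie is
    never resolved to a guess.
    """
    if not linked_support:
        return "unknown"
    f = int(linked_support.get("father", 0))
    m = int(linked_support.get("mother", 0))
    if f >= min_linked_reads and m >= min_linked_reads:
        raise PhaseConflictError(f"linked reads support both parents (father={f}, mother={m})")
    if f >= min_linked_reads and m == 0:
        return "paternal"
    if m >= min_linked_reads and f == 0:
        return "maternal"
    return "unknown"


def characterize(
    dnms: Sequence[CandidateDNM],
    panel,
    linked_reads: dict,
    min_linked_reads: int = 5,
) -> list[CandidateDNM]:
    """Fill spectrum, region and origin fields from the reference panel and
    linked-read evidence."""
    out = []
    for d in dnms:
        mclass, cpg = classify_mutation(
            d.ref_allele, d.alt_allele, panel.trinucleotide(d.position)
        )
        out.append(
            replace(
                d,
                mutation_class=mclass,
                cpg_flag=cpg,
                region_class=annotate_region(d.position, panel.genes, panel.exons, panel.utr3),
                origin=infer_parental_origin(linked_reads.get(d.position), min_linked_reads),
            )
        )
    return out


def attach_panel_counts(
    dnms: Sequence[CandidateDNM], truth_by_position: dict
) -> list[CandidateDNM]:
    """Copy panel transmission counts from a genotyped sibling panel
    (simulated truth or an external genotyping result)."""
    out = []
    for d in dnms:
        t = truth_by_position.get(d.position)
        if t is None:
            out.append(d)
        else:
            out.append(replace(d, panel_carriers=t.panel_carriers, panel_size=t.panel_size))
    return out


def transmission_summary(dnms: Sequence[CandidateDNM]) -> dict:
    """Spectrum/region/transmission roll-up over a set of candidate DNMs."""
    ts = sum(d.mutation_class == "transition" for d in dnms)
    tv = sum(d.mutation_class == "transversion" for d in dnms)
    regions = {r: sum(d.region_class == r for d in dnms) for r in REGION_PRECEDENCE}
    per_dnm = pd.DataFrame(
        {
            "position": [d.position for d in dnms],
            "ref": [d.ref_allele for d in dnms],
            "var": [d.alt_allele for d in dnms],
            "carriers": [",".join(d.carrier_offspring) for d in dnms],
            "freq": [d.freq_string() for d in dnms],
            "origin": [d.origin for d in dnms],
            "type": ["TS" if d.mutation_class == "transition" else "TV" for d in dnms],
            "region": [d.region_class for d in dnms],
        }
    )
    return {
        "n_dnms": len(dnms),
        "transitions": ts,
        "transversions": tv,
        "ts_tv_ratio": (ts / tv) if tv else float("inf"),
        "cpg_count": sum(d.cpg_flag for d in dnms),
        "region_counts": regions,
        "shared_count": sum(d.shared for d in dnms),
        "shared_sequenced_count": sum(d.shared_sequenced for d in dnms),
        "table": per_dnm,
    }


def max_transmission_test(dnms: Sequence[CandidateDNM]) -> Optional[dict]:
    """Fisher test of the most-transmitted DNM against the 50% expected for
    a germline-fixed mutation: [[carriers, non-carriers], [n/2, n/2]]."""
    genotyped = [d for d in dnms if d.panel_size > 0]
    if not genotyped:
        return None
    top = max(genotyped, key=lambda d: d.panel_carriers / d.panel_size)
    n = top.panel_size
    table = ContingencyTable2x2(top.panel_carriers, n - top.panel_carriers, n // 2, n - n // 2)
    result = fisher_exact_two_sided(table)
    return {
        "position": top.position,
        "carriers": top.panel_carriers,
        "panel_size": n,
        "p_value": result.p_value,
    }


def mosaicism_contrast(
    dnms: Sequence[CandidateDNM], mode: str = "panel"
) -> tuple[ContingencyTable2x2, ExactTestResult]:
    """Family contrast of shared vs private DNMs (2x2 Fisher).

    ``mode`` "panel" counts a DNM as shared when two or more panel siblings
    carry it; "sequenced" when two or more of the sequenced offspring do.
    Requires the ``family`` field to distinguish exactly two families.
    """
    families = sorted({d.family for d in dnms})
    if len(families) != 2:
        raise ValueError(f"contrast needs exactly two families, got {families}")
    if mode not in ("panel", "sequenced"):
        raise ValueError(f"unknown mode {mode!r}")

    def shared(d: CandidateDNM) -> bool:
        return d.shared if mode == "panel" else d.shared_sequenced

    cells = []
    for fam in families:
        sub = [d for d in dnms if d.family == fam]
        s = sum(shared(d) for d in sub)
        cells.append((s, len(sub) - s))
    table = ContingencyTable2x2(cells[0][0], cells[0][1], cells[1][0], cells[1][1])
    return table, fisher_exact_two_sided(table)
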