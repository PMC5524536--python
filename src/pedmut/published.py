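"""Reference data from the published Atlantic herring pedigree study.

The study sequenced two pedigrees (an Atlantic and a Baltic full-sib
family, two parents and six offspring each, 45-75x coverage), validated 17
de novo mutations by Sanger sequencing, and genotyped each mutation in a
larger sibling panel (50 and 46 progeny per family) to measure
transmission.  The table below reproduces that mutation set — scaffold
locus, carrier offspring among the sequenced six, panel transmission,
parental origin, substitution type and genomic region — together with the
headline constants of the rate calculation.  These values are inputs to
the re-derivation operations; nothing here is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PublishedDNM", "PUBLISHED_DNMS", "CONSTANTS"]


@dataclass(frozen=True)
class PublishedDNM:
    locus: str                    # scaffold:position
    family: str                   # "atlantic" | "baltic"
    carriers: tuple[str, ...]     # sequenced offspring carrying the mutation
    ref: str
    var: str
    panel_carriers: int
    panel_size: int
    origin: str                   # "maternal" | "paternal" | "unknown"
    mutation_class: str           # "transition" | "transversion"
    region: str                   # "exonic" | "3'UTR" | "intronic" | "intergenic"

    @property
    def shared(self) -> bool:
        return self.panel_carriers >= 2


_TS, _TV = "transition", "transversion"

PUBLISHED_DNMS: tuple[PublishedDNM, ...] = (
    PublishedDNM("1157:174127", "atlantic", ("AA4",), "T", "A", 1, 50, "maternal", _TV, "intergenic"),
    PublishedDNM("153:2684380", "atlantic", ("AA2",), "T", "G", 9, 50, "paternal", _TV, "intronic"),
    PublishedDNM("241:7752158", "atlantic", ("AA5",), "C", "A", 5, 50, "maternal", _TV, "intergenic"),
    PublishedDNM("4:5098858", "atlantic", ("AA5",), "T", "C", 2, 50, "maternal", _TS, "intronic"),
    PublishedDNM("481:1927799", "atlantic", ("AA4", "AA5"), "C", "A", 6, 50, "paternal", _TV, "3'UTR"),
    PublishedDNM("61:815077", "atlantic", ("AA4",), "A", "T", 3, 50, "unknown", _TV, "intergenic"),
    PublishedDNM("62:613919", "atlantic", ("AA1", "AA6"), "C", "A", 6, 50, "maternal", _TV, "intergenic"),
    PublishedDNM("729:1499224", "atlantic", ("AA2",), "C", "T", 4, 50, "maternal", _TS, "intronic"),
    PublishedDNM("887:195946", "atlantic", ("AA5",), "G", "A", 1, 50, "paternal", _TS, "intronic"),
    PublishedDNM("10:1443002", "baltic", ("BB4",), "C", "T", 1, 46, "paternal", _TS, "intronic"),
    PublishedDNM("151:267875", "baltic", ("BB5",), "A", "T", 1, 46, "paternal", _TV, "exonic"),
    PublishedDNM("177:1045894", "baltic", ("BB1",), "A", "G", 1, 46, "paternal", _TS, "intronic"),
    PublishedDNM("194:478776", "baltic", ("BB6",), "A", "G", 1, 46, "unknown", _TS, "intronic"),
    PublishedDNM("246:1890479", "baltic", ("BB4",), "T", "C", 1, 46, "paternal", _TS, "intergenic"),
    PublishedDNM("257:380993", "baltic", ("BB2",), "G", "A", 1, 46, "maternal", _TS, "intergenic"),
    PublishedDNM("26:2976192", "baltic", ("BB1",), "T", "C", 2, 46, "paternal", _TS, "intronic"),
    PublishedDNM("37:1374669", "baltic", ("BB5",), "G", "A", 1, 46, "maternal", _TS, "intronic"),
)

# headline constants of the published rate calculation
CONSTANTS = {
    "n_offspring": 12,            # sequenced offspring across the two pedigrees
    "masked_mb": 442.0,           # Mb passing mappability + repeat filtering
    "insufficient_depth_fraction": 0.026,
    "callable_bases": 431e6,      # 442 Mb x 0.974, the rate denominator C
    "fn_rate": 0.059,             # empirical false-negative rate
    "generation_time_years": 6.0,
    "pi": 0.0032,                 # neutral nucleotide diversity
    "current_ne": 1e7,            # conservative present-day Ne
    "cpg_reference_fraction": 0.19,   # human CpG>TpG share, comparison point
    "paternal_maternal_ratio_human": 3.9,
}
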