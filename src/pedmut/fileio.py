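"""File interfaces: multi-sample VCF (via pysam), BED, TSV and YAML echo."""

from __future__ import annotations

from os import PathLike
from typing import Sequence, Union

import numpy as np
import pandas as pd
import pysam
import yaml

from .genotype_calling import GenotypeCallSet, HET, HOM_ALT, HOM_REF, NO_CALL
from .site_filtering import ANNOTATION_NAMES

__all__ = [
    "write_callset_vcf",
    "read_callset_vcf",
    "write_bed",
    "write_mappability_tsv",
    "write_truth_table",
    "write_yaml",
]

Path = Union[str, PathLike]

CONTIG = "sim1"

_GT_TO_TUPLE = {HOM_REF: (0, 0), HET: (0, 1), HOM_ALT: (1, 1), NO_CALL: (None, None)}
_TUPLE_TO_GT = {(0, 0): HOM_REF, (0, 1): HET, (1, 0): HET, (1, 1): HOM_ALT}

_NUC = "ACGT"


def _letter(x) -> str:
    return x if isinstance(x, str) else _NUC[int(x)]


def write_callset_vcf(calls: GenotypeCallSet, path: Path, contig_length: int) -> None:
    """Write a call set as a multi-sample VCF with GT/DP/AD/GQ fields and
    the site annotations as INFO; the caller label is recorded in the
    header."""
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={CONTIG},length={contig_length}>")
    header.add_line(f"##source=pedmut_caller_{calls.label}")
    # annotation INFO keys carry an A_ prefix: bare DP/AD would clash with
    # the reserved VCF keys of different number/type
    for name in calls.annotations.columns:
        header.add_line(
            f'##INFO=<ID=A_{name},Number=1,Type=Float,Description="site annotation {name}">'
        )
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">')
    header.add_line('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
    for s in calls.individuals:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in range(calls.n_sites):
            rec = vcf.new_record(
                contig=CONTIG,
                start=int(calls.positions[i]),
                alleles=(_letter(calls.ref[i]), _letter(calls.alt[i])),
            )
            for name in calls.annotations.columns:
                rec.info[f"A_{name}"] = float(calls.annotations[name].iloc[i])
            for j, s in enumerate(calls.individuals):
                g = int(calls.gt[j, i])
                rec.samples[s]["GT"] = _GT_TO_TUPLE[g]
                rec.samples[s]["DP"] = int(calls.depth[j, i])
                rec.samples[s]["AD"] = (
                    int(calls.depth[j, i] - calls.alt_count[j, i]),
                    int(calls.alt_count[j, i]),
                )
                rec.samples[s]["GQ"] = int(round(calls.gq[j, i]))
            vcf.write(rec)


def read_callset_vcf(path: Path) -> GenotypeCallSet:
    """Read a VCF written by :func:`write_callset_vcf` back into a call set.

    Multiallelic records are skipped with a warning — the pipeline is
    strictly biallelic.
    """
    import warnings

    with pysam.VariantFile(str(path)) as vcf:
        samples = tuple(vcf.header.samples)
        label = "vcf"
        for line in str(vcf.header).splitlines():
            if line.startswith("##source=pedmut_caller_"):
                label = line.split("pedmut_caller_", 1)[1]
        rows = []
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                warnings.warn(f"skipping multiallelic record at {rec.chrom}:{rec.pos}")
                continue
            rows.append(rec.copy())

    n = len(rows)
    positions = np.array([r.start for r in rows], dtype=np.int64)
    ref = np.array([r.ref for r in rows], dtype="U1")
    alt = np.array([r.alts[0] for r in rows], dtype="U1")
    gt = np.empty((len(samples), n), dtype=np.int8)
    gq = np.zeros((len(samples), n), dtype=float)
    depth = np.zeros((len(samples), n), dtype=np.int64)
    alt_count = np.zeros((len(samples), n), dtype=np.int64)
    ann = {name: np.full(n, np.nan) for name in ANNOTATION_NAMES}
    for i, rec in enumerate(rows):
        for name in ANNOTATION_NAMES:
            if f"A_{name}" in rec.info:
                ann[name][i] = float(rec.info[f"A_{name}"])
        for j, s in enumerate(samples):
            smp = rec.samples[s]
            gt[j, i] = _TUPLE_TO_GT.get(tuple(smp["GT"]), NO_CALL) if smp["GT"][0] is not None else NO_CALL
            depth[j, i] = smp["DP"] if smp["DP"] is not None else 0
            ad = smp.get("AD")
            alt_count[j, i] = ad[1] if ad and ad[1] is not None else 0
            gq[j, i] = smp["GQ"] if smp["GQ"] is not None else 0
    return GenotypeCallSet(
        label=label,
        individuals=samples,
        positions=positions,
        ref=ref,
        alt=alt,
        gt=gt,
        gq=gq,
        depth=depth,
        alt_count=alt_count,
        annotations=pd.DataFrame(ann),
    )


def write_bed(intervals: np.ndarray, path: Path, name: str = CONTIG) -> None:
    iv = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    with open(path, "w") as fh:
        for s, e in iv:
            fh.write(f"{name}\t{s}\t{e}\n")


def write_mappability_tsv(mappability: np.ndarray, path: Path) -> None:
    pd.DataFrame(
        {"pos": np.arange(len(mappability)), "mappability": mappability}
    ).to_csv(path, sep="\t", index=False)


def write_truth_table(dnms: Sequence, path: Path) -> None:
    pd.DataFrame(
        {
            "position": [d.position for d in dnms],
            "ref": [d.ref_allele for d in dnms],
            "alt": [d.alt_allele for d in dnms],
            "origin": [d.origin_parent for d in dnms],
            "division": [d.division for d in dnms],
            "gamete_fraction": [d.gamete_fraction for d in dnms],
            "carriers": [",".join(d.carrier_offspring) for d in dnms],
            "panel_carriers": [d.panel_carriers for d in dnms],
            "panel_size": [d.panel_size for d in dnms],
        }
    ).to_csv(path, sep="\t", index=False)


def write_yaml(obj, path: Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
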