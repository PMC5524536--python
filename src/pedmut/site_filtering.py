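"""Callable-region mask construction and known-heterozygote-calibrated
quality filtering.

The mask keeps a position only if its own mappability is exactly 1, the
mean mappability of its enclosing non-overlapping 1 kb window exceeds
0.95, and it lies outside the repeat mask.  Quality filtering is
calibrated on "known heterozygous" sites — sites where the parents are
homozygous for different alleles, so every offspring is an obligate
heterozygote — whose annotation values are approximately normal; each
annotation is then bounded at mean +/- 2 standard deviations, and a site
must fall inside every band to survive.  This deliberately strict scheme
trades false negatives (later estimated and corrected for) for a
near-zero false-positive rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_calling import GenotypeCallSet, HET, HOM_ALT, HOM_REF, NO_CALL

__all__ = [
    "ANNOTATION_NAMES",
    "CalibrationError",
    "CallableMask",
    "FilterThresholds",
    "build_callable_mask",
    "select_known_het_sites",
    "calibrate_thresholds",
    "apply_filters",
]

# the calibration list: site quality statistics thresholded at mean +/- 2 sd
ANNOTATION_NAMES: tuple[str, ...] = (
    "DP",              # total read depth
    "MQ",              # mapping quality
    "MQRankSum",       # mapping quality rank sum
    "BaseQ",           # base quality
    "BaseQRankSum",    # base quality rank sum
    "ReadPosRankSum",  # read position rank sum
    "QD",              # quality by depth
    "GQ",              # genotype quality proxy
    "AD",              # allele depth
)


class CalibrationError(RuntimeError):
    """Raised when threshold calibration lacks enough qualifying sites."""


@dataclass(frozen=True)
class CallableMask:
    """Sorted, non-overlapping half-open intervals of callable sequence."""

    intervals: np.ndarray  # (k, 2) int64
    genome_length: int

    def __post_init__(self) -> None:
        iv = self.intervals
        if iv.size and (np.any(iv[:, 0] >= iv[:, 1]) or np.any(iv[:-1, 1] > iv[1:, 0])):
            raise ValueError("mask intervals must be non-empty, sorted and disjoint")

    @property
    def total_bases(self) -> int:
        return int((self.intervals[:, 1] - self.intervals[:, 0]).sum()) if self.intervals.size else 0

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean membership for an array of positions."""
        positions = np.asarray(positions)
        if not self.intervals.size:
            return np.zeros(positions.shape, dtype=bool)
        idx = np.searchsorted(self.intervals[:, 0], positions, side="right") - 1
        idx_clip = np.clip(idx, 0, len(self.intervals) - 1)
        return (idx >= 0) & (positions < self.intervals[idx_clip, 1])

    def to_track(self) -> np.ndarray:
        track = np.zeros(self.genome_length, dtype=bool)
        for s, e in self.intervals:
            track[s:e] = True
        return track

    def positions(self) -> np.ndarray:
        return np.flatnonzero(self.to_track())


def build_callable_mask(
    mappability: np.ndarray,
    repeat_mask: np.ndarray,
    window: int = 1000,
    window_mean_min: float = 0.95,
) -> CallableMask:
    """Mappability-and-repeat mask over non-overlapping windows tiled from 0.

    A position is callable iff its mappability equals 1, the mean
    mappability of its window is strictly greater than ``window_mean_min``,
    and it lies outside ``repeat_mask``.  The trailing partial window is
    averaged over its actual length.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    mappability = np.asarray(mappability, dtype=np.float64)
    if np.any((mappability < 0) | (mappability > 1)):
        raise ValueError("mappability values must lie in [0, 1]")
    length = mappability.size

    n_windows = -(-length // window)
    padded = np.pad(mappability, (0, n_windows * window - length))
    counts = np.full(n_windows, window, dtype=np.int64)
    if length % window:
        counts[-1] = length % window
    window_means = padded.reshape(n_windows, window).sum(axis=1) / counts

    ok = np.repeat(window_means > window_mean_min, window)[:length]
    ok &= mappability == 1.0
    for s, e in np.asarray(repeat_mask, dtype=np.int64).reshape(-1, 2):
        ok[s:e] = False

    from .synthetic_pedigree import intervals_from_bool  # local import avoids cycle at load

    return CallableMask(intervals=intervals_from_bool(ok), genome_length=length)


def select_known_het_sites(
    calls: GenotypeCallSet, het_fraction_min: float = 0.25
) -> np.ndarray:
    """Indices of sites where the parents are homozygous for different
    alleles and every offspring is a convincing heterozygote.

    Sites with a missing (no-call) parental genotype are excluded first.
    An offspring heterozygote is accepted only if it is called het and its
    minor-allele read fraction exceeds ``het_fraction_min``.
    """
    father, mother = calls.gt[0], calls.gt[1]
    parents_called = (father != NO_CALL) & (mother != NO_CALL)
    opposite = ((father == HOM_REF) & (mother == HOM_ALT)) | (
        (father == HOM_ALT) & (mother == HOM_REF)
    )

    off_gt = calls.gt[2:]
    off_depth = calls.depth[2:]
    off_alt = calls.alt_count[2:]
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_frac = np.where(off_depth > 0, off_alt / np.maximum(off_depth, 1), 0.0)
    minor_frac = np.minimum(alt_frac, 1.0 - alt_frac)
    convincing_het = (off_gt == HET) & (minor_frac > het_fraction_min)
    return np.flatnonzero(parents_called & opposite & convincing_het.all(axis=0))


@dataclass(frozen=True)
class FilterThresholds:
    """Per-annotation inclusive bounds mean +/- sd_multiplier * sd."""

    table: pd.DataFrame  # index: annotation; columns: mean, sd, lower, upper, n
    sd_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if (self.table["n"] <= 0).any():
            raise ValueError("calibration site count must be positive")

    @property
    def annotations(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def degenerate(self) -> tuple[str, ...]:
        """Annotations with zero calibration variance (lower == upper)."""
        return tuple(self.table.index[self.table["sd"] == 0.0])

    def bounds(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["lower"]), float(row["upper"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="annotation")


def calibrate_thresholds(
    annotations: pd.DataFrame,
    calibration_index: np.ndarray,
    sd_multiplier: float = 2.0,
    min_sites: int = 30,
) -> FilterThresholds:
    """Fit mean +/- sd_multiplier*sd bounds per annotation over the
    calibration (known-het) sites."""
    sub = annotations.iloc[np.asarray(calibration_index)]
    rows = {}
    for name in annotations.columns:
        values = sub[name].dropna()
        if len(values) < min_sites:
            raise CalibrationError(
                f"annotation {name!r}: only {len(values)} calibration sites (need {min_sites})"
            )
        mean, sd = float(values.mean()), float(values.std(ddof=1))
        rows[name] = {
            "mean": mean,
            "sd": sd,
            "lower": mean - sd_multiplier * sd,
            "upper": mean + sd_multiplier * sd,
            "n": len(values),
        }
    return FilterThresholds(table=pd.DataFrame(rows).T, sd_multiplier=sd_multiplier)


def annotation_pass(annotations: pd.DataFrame, thresholds: FilterThresholds) -> np.ndarray:
    """Per-site boolean: every annotation value inside its inclusive band.

    Missing (NaN) values pass — a filter cannot fail on absent evidence
    (rank-sum statistics are undefined at homozygous sites).
    """
    missing = [c for c in annotations.columns if c not in thresholds.annotations]
    if missing:
        raise ValueError(f"annotations without calibrated thresholds: {missing}")
    ok = np.ones(len(annotations), dtype=bool)
    for name in annotations.columns:
        lo, hi = thresholds.bounds(name)
        v = annotations[name].to_numpy()
        ok &= np.isnan(v) | ((v >= lo) & (v <= hi))
    return ok


def apply_filters(
    calls: GenotypeCallSet,
    thresholds: FilterThresholds,
    mask: CallableMask,
) -> tuple[GenotypeCallSet, pd.DataFrame]:
    """Retain in-mask sites whose every annotation is inside its band.

    Returns the filtered call set and a per-removed-site report with one
    reason each ("outside_mask" takes precedence, then the first
    out-of-band annotation in calibration order), so reasons partition the
    removed sites.
    """
    in_mask = mask.contains(calls.positions)
    ann_ok = annotation_pass(calls.annotations, thresholds)
    keep = in_mask & ann_ok

    reasons = []
    for i in np.flatnonzero(~keep):
        if not in_mask[i]:
            reason = "outside_mask"
        else:
            reason = "annotation_failure"
            for name in calls.annotations.columns:
                lo, hi = thresholds.bounds(name)
                v = calls.annotations[name].iloc[i]
                if not np.isnan(v) and not (lo <= v <= hi):
                    reason = f"annotation:{name}"
                    break
        reasons.append({"position": int(calls.positions[i]), "reason": reason})
    report = pd.DataFrame(reasons, columns=["position", "reason"])
    return calls.take(np.flatnonzero(keep)), report
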