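import numpy as np
import pandas as pd
import pytest

from pedmut.site_filtering import (
    ANNOTATION_NAMES,
    CalibrationError,
    CallableMask,
    annotation_pass,
    apply_filters,
    build_callable_mask,
    calibrate_thresholds,
    select_known_het_sites,
)

from conftest import make_callset


class TestCallableMask:
    def test_perfect_track_covers_everything(self):
        mask = build_callable_mask(np.ones(5000), np.empty((0, 2), dtype=np.int64))
        assert mask.total_bases == 5000
        assert np.array_equal(mask.intervals, [[0, 5000]])

    def test_low_window_mean_excludes_whole_window(self):
        track = np.ones(3000)
        track[1000:1060] = 0.0  # window [1000, 2000) mean drops to 0.94
        mask = build_callable_mask(track, np.empty((0, 2)))
        assert not mask.contains(np.array([1500, 1999])).any()  # mappability-1 positions too
        assert mask.contains(np.array([500, 2500])).all()

    def test_low_position_in_good_window_excluded(self):
        track = np.ones(2000)
        track[700] = 0.8  # window mean 0.9999 still passes
        mask = build_callable_mask(track, np.empty((0, 2)))
        assert not mask.contains(np.array([700]))[0]
        assert mask.contains(np.array([699, 701])).all()

    def test_repeat_intervals_removed(self):
        mask = build_callable_mask(np.ones(2000), np.array([[100, 200]]))
        assert not mask.contains(np.array([150]))[0]
        assert mask.total_bases == 1900

    def test_idempotent_on_binary_tracks(self):
        """Rebuilding from a mask's own 0/1 track reaches a fixed point: a
        fractional track can leave partial windows whose retained density
        is below the window threshold, but one rebuild on the binary track
        resolves them and further rebuilds change nothing."""
        rng = np.random.default_rng(3)
        track = np.ones(20_000)
        for s in rng.integers(0, 19_000, size=15):
            track[s : s + rng.integers(10, 900)] = rng.uniform(0, 1)
        empty = np.empty((0, 2), dtype=np.int64)
        first = build_callable_mask(track, np.array([[5000, 5500]]))
        second = build_callable_mask(first.to_track().astype(float), empty)
        third = build_callable_mask(second.to_track().astype(float), empty)
        assert np.array_equal(second.intervals, third.intervals)
        # and a mask built from a binary track is itself a fixed point
        binary = (track == 1.0).astype(float)
        m1 = build_callable_mask(binary, empty)
        m2 = build_callable_mask(m1.to_track().astype(float), empty)
        assert np.array_equal(m1.intervals, m2.intervals)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            build_callable_mask(np.ones(100), np.empty((0, 2)), window=0)


class TestKnownHetSelection:
    def _base(self, off_frac):
        gt = np.array([[0, 0], [2, 2], [1, 1], [1, 1]], dtype=np.int8)
        frac = np.array([[0.0, 0.0], [1.0, 1.0], [0.5, off_frac], [0.5, 0.5]])
        return make_callset(gt, depth=10, alt_frac=frac)

    def test_obligate_hets_selected(self):
        idx = select_known_het_sites(self._base(0.4))
        assert idx.tolist() == [0, 1]

    def test_low_minor_fraction_rejected(self):
        # one offspring at 2/10 alt reads: minor fraction 0.2 fails the >25% rule
        idx = select_known_het_sites(self._base(0.2))
        assert idx.tolist() == [0]

    def test_missing_parent_excluded(self):
        calls = self._base(0.5)
        calls.gt[0, 1] = -1
        assert select_known_het_sites(calls).tolist() == [0]

    def test_same_allele_parents_not_selected(self):
        gt = np.array([[0], [0], [1], [1]], dtype=np.int8)
        assert select_known_het_sites(make_callset(gt)).size == 0


class TestCalibration:
    def test_bounds_are_mean_pm_two_sd(self):
        rng = np.random.default_rng(0)
        ann = pd.DataFrame({n: rng.normal(size=100) for n in ANNOTATION_NAMES})
        ann["DP"] = np.repeat([15.0, 25.0], 50)  # mean 20, sd ~5.025
        th = calibrate_thresholds(ann, np.arange(100))
        lo, hi = th.bounds("DP")
        sd = ann["DP"].std(ddof=1)
        assert lo == pytest.approx(20 - 2 * sd) and hi == pytest.approx(20 + 2 * sd)

    def test_constant_annotation_flagged_degenerate(self):
        ann = pd.DataFrame({n: np.full(50, 7.0) for n in ANNOTATION_NAMES})
        th = calibrate_thresholds(ann, np.arange(50))
        assert set(th.degenerate()) == set(ANNOTATION_NAMES)
        assert th.bounds("MQ") == (7.0, 7.0)

    def test_too_few_sites_raises_with_annotation_name(self):
        ann = pd.DataFrame({n: np.zeros(10) for n in ANNOTATION_NAMES})
        with pytest.raises(CalibrationError, match="DP"):
            calibrate_thresholds(ann, np.arange(10))

    def test_normal_coverage_near_9545(self):
        rng = np.random.default_rng(1)
        n = 10_000
        ann = pd.DataFrame({name: rng.normal(30, 4, size=n) for name in ANNOTATION_NAMES})
        th = calibrate_thresholds(ann, np.arange(n))
        lo, hi = th.bounds("QD")
        inside = ((ann["QD"] >= lo) & (ann["QD"] <= hi)).mean()
        se = np.sqrt(0.9545 * 0.0455 / n)
        assert abs(inside - 0.95449974) < 3 * se + 2 / n


class TestApplyFilters:
    def _thresholds(self):
        ann = pd.DataFrame({n: np.linspace(10, 30, 100) for n in ANNOTATION_NAMES})
        return calibrate_thresholds(ann, np.arange(100))

    def test_out_of_band_value_removed_with_reason(self):
        th = self._thresholds()
        lo, hi = th.bounds("MQ")
        ann = pd.DataFrame({n: np.full(2, 20.0) for n in ANNOTATION_NAMES})
        ann.loc[1, "MQ"] = hi + 1.0
        calls = make_callset(np.zeros((3, 2), dtype=np.int8), annotations=ann)
        mask = CallableMask(np.array([[0, 10_000]]), 10_000)
        kept, report = apply_filters(calls, th, mask)
        assert kept.n_sites == 1
        assert report["reason"].tolist() == ["annotation:MQ"]

    def test_site_outside_mask_removed_regardless_of_annotations(self):
        th = self._thresholds()
        ann = pd.DataFrame({n: np.full(1, 20.0) for n in ANNOTATION_NAMES})
        calls = make_callset(np.zeros((3, 1), dtype=np.int8), annotations=ann)
        mask = CallableMask(np.array([[5000, 6000]]), 10_000)  # site at 50 not inside
        kept, report = apply_filters(calls, th, mask)
        assert kept.n_sites == 0
        assert report["reason"].tolist() == ["outside_mask"]

    def test_missing_annotation_value_passes(self):
        th = self._thresholds()
        ann = pd.DataFrame({n: np.full(1, 20.0) for n in ANNOTATION_NAMES})
        ann.loc[0, "MQRankSum"] = np.nan
        ok = annotation_pass(ann, th)
        assert ok.all()

    def test_unknown_annotation_rejected(self):
        th = self._thresholds()
        ann = pd.DataFrame({"mystery": [1.0]})
        with pytest.raises(ValueError, match="mystery"):
            annotation_pass(ann, th)

    def test_reasons_partition_removed_sites(self, small_run):
        report = small_run.removal_report
        assert len(report) == len(report["position"].unique())
        assert (report["reason"] != "").all()


def test_independent_annotation_retention_matches_normal_coverage():
    """Strict +/-2 sd filtering over k independent annotations should retain
    ~0.9545^k of true sites — the false negatives the pipeline later
    estimates and corrects."""
    rng = np.random.default_rng(7)
    n_cal, n_apply = 4000, 8000
    k = len(ANNOTATION_NAMES)
    cal = pd.DataFrame({n: rng.normal(0, 1, n_cal) for n in ANNOTATION_NAMES})
    fresh = pd.DataFrame({n: rng.normal(0, 1, n_apply) for n in ANNOTATION_NAMES})
    th = calibrate_thresholds(cal, np.arange(n_cal))
    retained = annotation_pass(fresh, th).mean()
    expected = 0.95449974**k
    se = np.sqrt(expected * (1 - expected) / n_apply)
    assert abs(retained - expected) < 4 * se
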