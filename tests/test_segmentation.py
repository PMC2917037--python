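"""Tests for circular binary segmentation, adaptive calling, and FGA."""

import numpy as np
import pandas as pd
import pytest

from cnakit import segmentation as sg
from cnakit.io import CopyNumberMatrix

from conftest import make_probe_map


def brute_force_max_arc(x):
    """Reference implementation of the maximal circular-arc statistic."""
    n = len(x)
    total = x.sum()
    best, bi, bj = -1.0, -1, -1
    for i in range(n + 1):
        for j in range(i + 2, n + 1):
            k = j - i
            if k < 2 or n - k < 2:
                continue
            if i == 1 or j == n - 1:
                continue
            stat = abs(x[i:j].sum() - k * total / n) / np.sqrt(k * (n - k) / n)
            if stat > best:
                best, bi, bj = stat, i, j
    return best, bi, bj


class TestMaxArcStat:
    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 40))
            x = rng.normal(size=n)
            c = np.concatenate(([0.0], np.cumsum(x)))
            got, gi, gj = sg._max_arc_stat(c, n)
            want, wi, wj = brute_force_max_arc(x)
            assert got == pytest.approx(want, rel=1e-10)
            assert (gi, gj) == (wi, wj)

    def test_no_short_linear_pieces(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            x = rng.normal(size=n)
            c = np.concatenate(([0.0], np.cumsum(x)))
            _, i, j = sg._max_arc_stat(c, n)
            k = j - i
            assert k >= 2 and n - k >= 2
            assert i != 1 and j != n - 1


class TestCbsSegment:
    def test_flat_profile_single_segment(self, probe_map_1chr):
        x = np.full(100, 0.05)
        prof = sg.cbs_segment(x, probe_map_1chr, seed=1)
        assert len(prof.records) == 1
        assert prof.records[0].n_probes == 100
        assert prof.probe_seg_mean[0] == pytest.approx(0.05)

    def test_single_step_recovered_exactly(self, probe_map_1chr, rng):
        x = np.zeros(100)
        x[40:] = 1.0
        x += rng.normal(0, 0.05, 100)
        prof = sg.cbs_segment(x, probe_map_1chr, seed=1)
        bounds = sorted(r.start for r in prof.records)
        starts = probe_map_1chr.table["start"].to_numpy()
        assert starts[40] in bounds
        assert len(prof.records) == 2

    def test_focal_amplicon_recovered(self, probe_map_1chr):
        x = np.zeros(100)
        x[50:56] = 1.8
        prof = sg.cbs_segment(x, probe_map_1chr, seed=1)
        means = sorted(r.seg_mean for r in prof.records)
        assert means[-1] == pytest.approx(1.8)
        amp = [r for r in prof.records if r.seg_mean > 1.0]
        assert len(amp) == 1 and amp[0].n_probes == 6

    def test_segments_partition_each_chromosome(self, probe_map_2chr, rng):
        x = rng.normal(0, 0.1, 100)
        x[:20] += 0.8
        prof = sg.cbs_segment(x, probe_map_2chr, seed=2)
        for chrom, block in probe_map_2chr.chromosome_blocks():
            recs = [r for r in prof.records if r.chrom == chrom]
            assert sum(r.n_probes for r in recs) == len(block)
        assert np.all(np.isfinite(prof.probe_seg_mean))

    def test_segments_never_cross_chromosomes(self, probe_map_2chr):
        x = np.full(100, 0.5)  # same level on both chromosomes
        prof = sg.cbs_segment(x, probe_map_2chr, seed=0)
        assert sorted(r.chrom for r in prof.records) == ["chr1", "chr2"]

    def test_missing_probes_stay_missing(self, probe_map_1chr):
        x = np.zeros(100)
        x[10:20] = np.nan
        prof = sg.cbs_segment(x, probe_map_1chr, seed=0)
        assert np.isnan(prof.probe_seg_mean[10:20]).all()
        assert np.isfinite(prof.probe_seg_mean[20:]).all()

    def test_deterministic_given_seed(self, probe_map_1chr, rng):
        x = rng.normal(0, 0.3, 100)
        a = sg.cbs_segment(x, probe_map_1chr, seed=7)
        b = sg.cbs_segment(x, probe_map_1chr, seed=7)
        assert a.records == b.records

    def test_bad_alpha_rejected(self, probe_map_1chr):
        with pytest.raises(sg.SegmentationError):
            sg.cbs_segment(np.zeros(100), probe_map_1chr, alpha=1.5)

    def test_length_mismatch_rejected(self, probe_map_1chr):
        with pytest.raises(sg.SegmentationError):
            sg.cbs_segment(np.zeros(99), probe_map_1chr)


class TestSmoothing:
    def test_window_mean_respects_positions(self):
        pm = make_probe_map({"chr1": 5}, spacing=100_000, width=50_000)
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        out = sg.smooth_window(x, pm, window_bp=250_000)
        # midpoints 100 kb apart; +-125 kb window = self + both neighbors
        assert out[2] == pytest.approx(2.0)
        assert out[0] == pytest.approx(0.5)
        assert out[4] == pytest.approx(3.5)

    def test_smoothing_does_not_cross_chromosomes(self):
        pm = make_probe_map({"chr1": 3, "chr2": 3}, spacing=100_000)
        x = np.array([0.0, 0.0, 0.0, 9.0, 9.0, 9.0])
        out = sg.smooth_window(x, pm, window_bp=10_000_000)
        assert np.allclose(out[:3], 0.0)
        assert np.allclose(out[3:], 9.0)

    def test_nan_excluded_from_windows(self):
        pm = make_probe_map({"chr1": 3}, spacing=100_000)
        x = np.array([1.0, np.nan, 3.0])
        out = sg.smooth_window(x, pm, window_bp=600_000)
        assert out[0] == pytest.approx(2.0)
        assert np.isnan(out[1])


class TestAdaptiveThresholds:
    def test_mad_based_thresholds(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 0.2, 5000)
        tau_gain, tau_loss = sg.adaptive_thresholds(x, k=2.5, tau_min=0.1)
        med = np.median(x)
        s = 1.4826 * np.median(np.abs(x - med))
        assert tau_gain == pytest.approx(med + 2.5 * s)
        assert tau_loss == pytest.approx(med - 2.5 * s)

    def test_floor_applies_for_quiet_samples(self):
        x = np.zeros(100)
        tau_gain, tau_loss = sg.adaptive_thresholds(x, k=2.5, tau_min=0.1)
        assert tau_gain == pytest.approx(0.1)
        assert tau_loss == pytest.approx(-0.1)

    def test_too_few_values_rejected(self):
        with pytest.raises(sg.SegmentationError):
            sg.adaptive_thresholds(np.zeros(5))


class TestCallingAndFga:
    def make_cohort(self, x, pm):
        vals = pd.DataFrame({"S1": x}, index=pm.probe_ids)
        return CopyNumberMatrix(vals, pm)

    def test_states_follow_thresholds_and_min_probes(self, probe_map_1chr):
        x = np.zeros(100)
        x[10:30] = 0.6   # 20-probe gain
        x[50:53] = -0.9  # 3-probe dip: forced neutral
        x[70:80] = 1.4   # high amplification
        cn = self.make_cohort(x, probe_map_1chr)
        seg = sg.segment_cohort(cn, seed=5)
        calls = sg.call_cohort(cn, seg)
        s = calls.states["S1"].to_numpy()
        h = calls.high_amp["S1"].to_numpy()
        assert (s[10:30] == sg.STATE_GAIN).all()
        assert (s[50:53] == sg.STATE_NEUTRAL).all()
        assert (s[70:80] == sg.STATE_GAIN).all() and h[70:80].all()
        assert not h[10:30].any()
        assert (s[:10] == sg.STATE_NEUTRAL).all()

    def test_fga_counts_gained_and_lost_fractions(self, probe_map_1chr):
        x = np.zeros(100)
        x[0:20] = 0.8
        x[40:50] = -0.8
        cn = self.make_cohort(x, probe_map_1chr)
        seg = sg.segment_cohort(cn, seed=5)
        calls = sg.call_cohort(cn, seg)
        table = sg.fga_cohort(calls)
        assert table.loc["S1", "fga_gain"] == pytest.approx(0.20)
        assert table.loc["S1", "fga_loss"] == pytest.approx(0.10)
        assert table.loc["S1", "fga_total"] == pytest.approx(0.30)

    def test_calls_roundtrip(self, probe_map_1chr, tmp_path):
        x = np.zeros(100)
        x[0:20] = 0.8
        x[70:80] = 1.5
        cn = self.make_cohort(x, probe_map_1chr)
        seg = sg.segment_cohort(cn, seed=5)
        calls = sg.call_cohort(cn, seg)
        path = tmp_path / "calls.tsv"
        sg.write_calls(calls, path)
        back = sg.read_calls(path, probe_map_1chr)
        assert (back.states.to_numpy() == calls.states.to_numpy()).all()
        assert (back.high_amp.to_numpy() == calls.high_amp.to_numpy()).all()

    def test_seg_records_roundtrip_through_cohort(self, probe_map_1chr):
        x = np.zeros(100)
        x[30:60] = 0.7
        cn = self.make_cohort(x, probe_map_1chr)
        seg = sg.segment_cohort(cn, seed=5)
        back = sg.cohort_from_records(seg.records, probe_map_1chr)
        assert np.allclose(
            back.seg_means.to_numpy(), seg.seg_means.to_numpy(), equal_nan=True
        )
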