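"""Nuclear-localization extraction, normalization, filtering, correlations."""
import numpy as np
import pytest

from duplinoise import imaging
from duplinoise import synthetic as syn
from duplinoise.datatypes import CellRecord, ImageStack, ParameterError, TraceSet


def _stack(frames, missing=()):
    return ImageStack(frames={"GFP": np.asarray(frames, dtype=float)},
                      missing_frames=frozenset(missing))


class TestPreprocess:
    def test_constant_frame_becomes_zero_away_from_borders(self):
        out = imaging.preprocess_frames(_stack(np.full((3, 80, 80), 7.0)))
        inner = out.frames["GFP"][0][30:50, 30:50]
        np.testing.assert_allclose(inner, 0.0, atol=1e-9)

    def test_missing_frame_interpolates_mean_of_neighbors(self):
        frames = np.stack([np.full((60, 60), 2.0), np.zeros((60, 60)), np.full((60, 60), 4.0)])
        out = imaging.preprocess_frames(_stack(frames, missing={1}))
        # after background subtraction neighbors are ~0 in the interior but the
        # raw interpolation rule is exact: frame1 = (frame0 + frame2) / 2
        np.testing.assert_allclose(
            out.frames["GFP"][1], (out.frames["GFP"][0] + out.frames["GFP"][2]) / 2
        )
        assert not out.missing_frames

    def test_median_removes_single_hot_pixel(self):
        frame = np.zeros((60, 60))
        frame[30, 30] = 100.0
        out = imaging.preprocess_frames(_stack(np.stack([frame] * 3)))
        assert abs(out.frames["GFP"][0][30, 30]) < 1.0

    @pytest.mark.parametrize("missing", [{0}, {3}, {1, 2}])
    def test_uninterpolatable_missing_frames_raise(self, missing):
        with pytest.raises(ParameterError):
            imaging.preprocess_frames(_stack(np.zeros((4, 20, 20)), missing=missing))


def _uniform_cell(value=5.0, radius=10, size=32, frames=4):
    yy, xx = np.mgrid[0:size, 0:size]
    mask = (yy - size // 2) ** 2 + (xx - size // 2) ** 2 <= radius**2
    img = np.where(mask, value, 0.0)
    stack = _stack(np.stack([img] * frames))
    cell = CellRecord(cell_id=1, mask=mask, area=np.full(frames, mask.sum(), float),
                      seg_score=np.full(frames, 10.0))
    return stack, cell


class TestLocalizationTrace:
    def test_uniform_cell_gives_ratio_one(self):
        stack, cell = _uniform_cell()
        trace = imaging.nuclear_localization_trace(stack, cell, "GFP")
        np.testing.assert_allclose(trace, 1.0)

    def test_rendered_nuclear_fold_recovered_within_ten_percent(self):
        ts, _ = syn.simulate_localization_traces(1, 20, True, pulse_rate=0.0, noise_sd=0.0, seed=1)
        ts.raw["GFP"][:] = 3.0
        stacks, _, cells, _ = syn.render_trace_movie(ts, image_shape=(34, 34), seed=1)
        trace = imaging.nuclear_localization_trace(stacks["GFP"], cells[0], "GFP")
        assert np.all(np.abs(trace - 3.0) / 3.0 < 0.10)

    def test_offset_nucleus_centre_found_within_one_pixel(self):
        size = 41
        yy, xx = np.mgrid[0:size, 0:size]
        mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        rng = np.random.default_rng(2)
        for cy, cx in [(14, 20), (25, 26), (20, 12)]:
            nucleus = (yy - cy) ** 2 + (xx - cx) ** 2 <= 3**2
            img = np.where(mask, 100.0, 0.0)
            img[nucleus] = 300.0
            img += rng.normal(0, 40.0, img.shape)  # SNR = 200/40 = 5
            stack = _stack(img[None])
            cell = CellRecord(1, mask, np.array([mask.sum()], float), np.array([10.0]))
            foot = imaging.disk_footprint(3).astype(float)
            from scipy import ndimage

            num = ndimage.correlate(img * mask, foot, mode="constant")
            den = ndimage.correlate(mask.astype(float), foot, mode="constant")
            with np.errstate(invalid="ignore", divide="ignore"):
                filt = np.where(den > 0, num / den, -np.inf)
            filt[~mask] = -np.inf
            got = np.unravel_index(np.argmax(filt), filt.shape)
            assert abs(got[0] - cy) <= 1 and abs(got[1] - cx) <= 1

    def test_ratio_invariant_to_global_intensity_scaling(self):
        stack, cell = _uniform_cell()
        img = stack.frames["GFP"].copy()
        img[0][cell.mask] += np.linspace(0, 50, cell.mask.sum())  # non-trivial profile
        t1 = imaging.nuclear_localization_trace(_stack(img), cell, "GFP")
        t2 = imaging.nuclear_localization_trace(_stack(img * 7.3), cell, "GFP")
        np.testing.assert_allclose(t1, t2, rtol=1e-12)

    def test_mask_smaller_than_disk_raises(self):
        stack, cell = _uniform_cell(radius=2)
        with pytest.raises(ParameterError):
            imaging.nuclear_localization_trace(stack, cell, "GFP")


class TestNormalize:
    def test_min_normalization_and_amplitude(self):
        ts = TraceSet(raw={"GFP": np.array([[2.0, 4.0, 6.0]])}, cell_ids=[1])
        out = imaging.normalize_traces(ts)
        np.testing.assert_allclose(out.normalized["GFP"][0], [1, 2, 3])
        assert out.amplitude["GFP"][0] == 3.0

    def test_normalized_minimum_is_exactly_one(self, rng):
        ts = TraceSet(raw={"GFP": rng.uniform(0.5, 4.0, (20, 30))}, cell_ids=np.arange(20))
        out = imaging.normalize_traces(ts)
        np.testing.assert_array_equal(out.normalized["GFP"].min(axis=1), 1.0)

    def test_constant_series_zscore_flagged_nan(self):
        ts = TraceSet(raw={"GFP": np.array([[2.0, 2.0, 2.0]])}, cell_ids=[1])
        out = imaging.normalize_traces(ts)
        assert np.isnan(out.zscored["GFP"]).all()

    def test_zero_minimum_rejected(self):
        ts = TraceSet(raw={"GFP": np.array([[0.0, 1.0, 2.0]])}, cell_ids=[1])
        with pytest.raises(ParameterError):
            imaging.normalize_traces(ts)


def _cohort(n=10, frames=50, amp=2.0, seed=0):
    rng = np.random.default_rng(seed)
    raw = np.ones((n, frames)) + rng.uniform(0.01, 0.02, (n, frames))
    raw[:, 20:25] = amp
    ts = TraceSet(raw={"GFP": raw}, cell_ids=np.arange(n))
    cells = [
        CellRecord(i, np.ones((4, 4), bool), np.full(frames, 100.0), np.full(frames, 10.0))
        for i in range(n)
    ]
    return ts, cells


class TestFilterCells:
    def test_low_amplitude_removed_with_reason(self):
        ts, cells = _cohort()
        ts.raw["GFP"][3] = 1.0 + np.linspace(0, 0.05, ts.n_frames)  # amplitude 1.05
        kept, reasons = imaging.filter_cells(ts, cells)
        assert 3 not in kept and reasons[3] == ["amplitude_low"]

    def test_high_amplitude_removed(self):
        ts, cells = _cohort()
        ts.raw["GFP"][2, 20:25] = 7.0
        kept, reasons = imaging.filter_cells(ts, cells)
        assert reasons[2] == ["amplitude_high"]

    def test_seg_score_rule_uses_ten_percent_of_frames(self):
        ts, cells = _cohort()
        cells[1].seg_score[:8] = 7.0  # 16% of 50 frames below 8
        cells[4].seg_score[:4] = 7.0  # 8% — kept
        kept, reasons = imaging.filter_cells(ts, cells)
        assert "seg_score" in reasons[1] and 4 in kept

    def test_identical_areas_never_trip_area_rule(self):
        ts, cells = _cohort()
        kept, reasons = imaging.filter_cells(ts, cells)
        assert not any("area" in r for r in reasons.values())

    def test_late_appearance_removed(self):
        ts, cells = _cohort()
        cells[5].present_from = 3
        kept, reasons = imaging.filter_cells(ts, cells)
        assert "late_appearance" in reasons[5]

    def test_filtering_is_idempotent(self):
        ts, cells = _cohort(n=20, seed=3)
        ts.raw["GFP"][0] = 1.0  # amplitude too low -> removed in round 2
        cells[7].seg_score[:30] = 5.0
        kept, _ = imaging.filter_cells(ts, cells)
        keep_idx = [i for i, c in enumerate(cells) if c.cell_id in kept]
        ts2 = TraceSet(raw={"GFP": ts.raw["GFP"][keep_idx]}, cell_ids=np.array(kept))
        kept2, reasons2 = imaging.filter_cells(ts2, [cells[i] for i in keep_idx])
        assert kept2 == kept and not reasons2


class TestTraceCorrelations:
    @staticmethod
    def _zscored(ts):
        return imaging.normalize_traces(ts).zscored

    def test_identical_channels_give_unit_same_cell_r(self):
        ts, _ = syn.simulate_localization_traces(10, 60, True, noise_sd=0.05, seed=4)
        z = self._zscored(ts)
        res = imaging.trace_correlations(z["GFP"], z["GFP"])
        np.testing.assert_allclose(res["same_cell"], 1.0)

    def test_shared_pulses_separate_same_from_cross(self):
        ts, _ = syn.simulate_localization_traces(
            60, 100, True, pulse_amplitude=3.0, noise_sd=0.05, seed=5
        )
        z = self._zscored(ts)
        res = imaging.trace_correlations(z["GFP"], z["mCherry"], seed=5)
        assert res["same_summary"]["median"] > 0.8
        assert res["cross_summary"]["median"] < 0.2

    def test_independent_pulses_collapse_separation(self):
        ts, _ = syn.simulate_localization_traces(
            60, 100, False, pulse_amplitude=3.0, noise_sd=0.05, seed=6
        )
        z = self._zscored(ts)
        res = imaging.trace_correlations(z["GFP"], z["mCherry"], seed=6)
        assert abs(res["same_summary"]["median"] - res["cross_summary"]["median"]) < 0.1

    def test_cross_cell_null_invariant_under_label_permutation(self, rng):
        ts, _ = syn.simulate_localization_traces(30, 80, True, noise_sd=0.05, seed=7)
        z = self._zscored(ts)
        res1 = imaging.trace_correlations(z["GFP"], z["mCherry"], max_pairs=200, seed=9)
        perm = rng.permutation(30)
        res2 = imaging.trace_correlations(z["GFP"][perm], z["mCherry"][perm], max_pairs=200, seed=9)
        # the sampled pair set differs but the distribution is exchangeable
        assert abs(np.median(res1["cross_cell"]) - np.median(res2["cross_cell"])) < 0.15

    def test_short_window_rejected(self):
        ts, _ = syn.simulate_localization_traces(5, 20, True, seed=8)
        z = self._zscored(ts)
        with pytest.raises(ParameterError):
            imaging.trace_correlations(z["GFP"], z["mCherry"], window=(0, 2))


def test_threshold_segmenter_recovers_rendered_cells():
    ts, _ = syn.simulate_localization_traces(4, 12, True, noise_sd=0.0, seed=9)
    stacks, labels, _, _ = syn.render_trace_movie(ts, image_shape=(96, 96), seed=9)
    seg = imaging.segment_threshold(stacks["GFP"].frames["GFP"][0])
    assert len(np.unique(seg)) == 5  # background + 4 cells
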