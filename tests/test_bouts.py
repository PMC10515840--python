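"""Bout detection, exclusion rules, and repeat-level QC."""

import numpy as np
import pytest

from zfkin.bouts import (
    ExtractionConfig,
    RepeatDataset,
    SwimTrace,
    apply_bout_exclusions,
    compute_speed,
    filter_circadian_day,
    qc_and_match_repeat,
    segment_bouts,
)

from conftest import single_pulse_trace


def brute_force_runs(speed, threshold):
    """Reference segmentation: scan every sample for threshold runs."""
    runs, start = [], None
    for i, s in enumerate(speed):
        if s > threshold and start is None:
            start = i
        elif s <= threshold and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(speed) - 1))
    return runs


class TestComputeSpeed:
    def test_stationary_fish_is_zero(self):
        n = 100
        tr = SwimTrace(time=np.arange(n) / 160, x=np.zeros(n), z=np.zeros(n),
                       pitch=np.zeros(n), fps=160)
        assert np.allclose(compute_speed(tr), 0.0)

    def test_constant_x_advance(self):
        n = 100
        tr = SwimTrace(time=np.arange(n) / 160, x=0.05 * np.arange(n),
                       z=np.zeros(n), pitch=np.zeros(n), fps=160)
        assert np.allclose(compute_speed(tr), 8.0)

    def test_diagonal_advance(self):
        n = 100
        d = 0.03 * np.arange(n)
        tr = SwimTrace(time=np.arange(n) / 160, x=d, z=d.copy(),
                       pitch=np.zeros(n), fps=160)
        assert np.allclose(compute_speed(tr), 0.03 * np.sqrt(2) * 160)

    def test_single_frame_rejected(self):
        tr = SwimTrace(time=np.array([0.0]), x=np.array([0.0]),
                       z=np.array([0.0]), pitch=np.array([0.0]), fps=160)
        with pytest.raises(ValueError):
            compute_speed(tr)


class TestSegmentBouts:
    def test_subthreshold_trace_yields_nothing(self):
        n = 400
        tr = SwimTrace(time=np.arange(n) / 160, x=0.02 * np.arange(n),
                       z=np.zeros(n), pitch=np.zeros(n), fps=160)
        assert segment_bouts(tr) == []

    @pytest.mark.parametrize("fps", [40.0, 160.0])
    def test_single_pulse_peak_within_one_frame(self, fps):
        tr = single_pulse_trace(fps=fps, peak=12.0, t_peak=1.0)
        bouts = segment_bouts(tr)
        assert len(bouts) == 1
        assert abs(bouts[0].t_peak - 1.0) <= 1.0 / fps + 1e-9
        # brute-force scan agrees on the run boundaries
        speed = compute_speed(tr)
        runs = brute_force_runs(speed, 5.0)
        assert len(runs) == 1

    def test_two_pulses_ordered(self):
        tr1 = single_pulse_trace(t_peak=0.7, duration=3.0)
        tr2 = single_pulse_trace(t_peak=2.2, duration=3.0)
        tr = SwimTrace(time=tr1.time, x=tr1.x + tr2.x, z=np.zeros(len(tr1)),
                       pitch=np.zeros(len(tr1)), fps=160)
        bouts = segment_bouts(tr)
        assert len(bouts) == 2
        assert bouts[0].t_peak < bouts[1].t_peak

    def test_short_dip_merged_by_gap_rule(self):
        fps = 160.0
        n = int(3 * fps) + 1
        t = np.arange(n) / fps
        v = np.where(np.abs(t - 1.0) < 0.1, 12.0, 0.0)
        # 2-frame sub-threshold dip inside the run
        dip = (t > 0.99) & (t < 1.01)
        v[dip] = 1.0
        x = np.concatenate([[0], np.cumsum((v[1:] + v[:-1]) / 2 / fps)])
        tr = SwimTrace(time=t, x=x, z=np.zeros(n), pitch=np.zeros(n), fps=fps)
        assert len(segment_bouts(tr, ExtractionConfig(merge_gap=0.05))) == 1

    def test_prepended_quiet_frames_do_not_change_result(self):
        tr = single_pulse_trace(t_peak=1.0, duration=2.0)
        pad = 160
        t2 = np.arange(len(tr) + pad) / 160
        tr2 = SwimTrace(time=t2,
                        x=np.concatenate([np.zeros(pad), tr.x]),
                        z=np.concatenate([np.zeros(pad), tr.z]),
                        pitch=np.concatenate([np.zeros(pad), tr.pitch]),
                        fps=160)
        b1 = segment_bouts(tr)
        b2 = segment_bouts(tr2)
        assert len(b1) == len(b2) == 1
        assert b2[0].t_peak == pytest.approx(b1[0].t_peak + pad / 160, abs=1e-9)

    def test_truncated_window_dropped(self):
        tr = single_pulse_trace(t_peak=0.15, duration=1.0)  # too close to edge
        assert segment_bouts(tr) == []


class TestExclusions:
    @staticmethod
    def _bout_with_rotation(rot_deg):
        tr = single_pulse_trace(t_peak=1.0, duration=2.0)
        pitch = np.where(tr.time < 1.0,
                         rot_deg * np.clip((tr.time - 0.75) / 0.25, 0, 1),
                         rot_deg)
        tr = SwimTrace(time=tr.time, x=tr.x, z=tr.z, pitch=pitch, fps=160)
        return segment_bouts(tr)

    def test_hyper_rotating_bout_excluded(self):
        bouts = self._bout_with_rotation(35.0)
        kept, log = apply_bout_exclusions(bouts)
        assert kept == [] and log["reasons"]["rotation"] == 1

    def test_moderate_rotation_kept(self):
        bouts = self._bout_with_rotation(29.0)
        kept, log = apply_bout_exclusions(bouts)
        assert len(kept) == 1 and log["reasons"]["rotation"] == 0

    def test_counts_conserved(self):
        bouts = self._bout_with_rotation(35.0) + self._bout_with_rotation(10.0)
        kept, log = apply_bout_exclusions(bouts)
        assert len(kept) + log["reasons"]["rotation"] == log["n_input"]

    def test_programmed_hyper_rotators_excluded_at_expected_rate(self):
        # 1% of bouts programmed with rotations far beyond the 30 deg limit
        from zfkin.synth import SwimSimParams, generate_swim_trace
        from zfkin.bouts import extract_bouts
        rng = np.random.default_rng(0)
        n_in = n_excl = 0
        for seed in range(4):
            res = generate_swim_trace(SwimSimParams(duration=1500.0, seed=seed))
            tr = res.trace
            # inject a 40 deg step into ~1% of acceleration windows
            hyper = res.truth.sample(frac=0.01, random_state=seed)
            pitch = tr.pitch.copy()
            for tp in hyper.t_peak_s:
                pitch[(tr.time > tp - 0.2) & (tr.time <= tp + 0.3)] += 40.0
            tr2 = SwimTrace(time=tr.time, x=tr.x, z=tr.z,
                            pitch=np.clip(pitch, -179.9, 180.0), fps=tr.fps)
            kept, log = extract_bouts(tr2)
            n_in += log["n_input"]
            n_excl += log["reasons"]["rotation"]
        frac = n_excl / n_in
        # binomial CI around the programmed 1%
        assert 0.005 <= frac <= 0.02


class TestCircadianFilter:
    def test_all_day_schedule_is_identity(self):
        bouts = segment_bouts(single_pulse_trace(t_peak=1.0, duration=2.0))
        assert filter_circadian_day(bouts, [(0.0, 10.0)]) == bouts

    def test_night_bout_removed(self):
        bouts = segment_bouts(single_pulse_trace(t_peak=1.0, duration=2.0))
        assert filter_circadian_day(bouts, [(5.0, 10.0)]) == []

    def test_missing_schedule_rejected(self):
        with pytest.raises(ValueError):
            filter_circadian_day([], None)

    def test_day_fraction_of_uniform_bouts(self):
        # 14/10 h cycle scaled down; bouts spread uniformly in time
        class FakeBout:
            def __init__(self, tp):
                self.t_peak = tp
        day = [(d * 24.0, d * 24.0 + 14.0) for d in range(10)]
        bouts = [FakeBout(tp) for tp in np.linspace(0, 240, 5000, endpoint=False)]
        kept = filter_circadian_day(bouts, day)
        assert len(kept) / len(bouts) == pytest.approx(14 / 24, abs=0.01)


class TestRepeatQC:
    @staticmethod
    def _repeat(nc, nx):
        return RepeatDataset(repeat_id="r0",
                             control_bouts=list(range(nc)),
                             condition_bouts=list(range(nx)))

    def test_low_count_boundary_excluded(self):
        rep = qc_and_match_repeat(self._repeat(649, 1000))
        assert rep.qc_status == "excluded_low_count"

    def test_exact_threshold_kept(self):
        rep = qc_and_match_repeat(self._repeat(650, 650))
        assert rep.qc_status == "kept" and rep.matched_n == 650

    def test_matching_downsamples_and_is_deterministic(self):
        rep1 = qc_and_match_repeat(self._repeat(800, 1200), seed=3)
        rep2 = qc_and_match_repeat(self._repeat(800, 1200), seed=3)
        assert rep1.matched_n == 800
        assert len(rep1.condition_bouts) == 800
        assert rep1.condition_bouts == rep2.condition_bouts
        rep3 = qc_and_match_repeat(self._repeat(800, 1200), seed=4)
        assert rep3.condition_bouts != rep1.condition_bouts


class TestSwimTraceValidation:
    def test_nonuniform_time_rejected(self):
        with pytest.raises(ValueError):
            SwimTrace(time=np.array([0.0, 0.01, 0.03]), x=np.zeros(3),
                      z=np.zeros(3), pitch=np.zeros(3), fps=160)

    def test_pitch_out_of_range_rejected(self):
        n = 3
        with pytest.raises(ValueError):
            SwimTrace(time=np.arange(n) / 160, x=np.zeros(n), z=np.zeros(n),
                      pitch=np.array([0.0, 190.0, 0.0]), fps=160)

    def test_round_trip_through_frame(self):
        tr = single_pulse_trace()
        tr2 = SwimTrace.from_frame(tr.to_frame(), fps=tr.fps)
        assert np.array_equal(tr.x, tr2.x)
        assert np.array_equal(tr.pitch, tr2.pitch)
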