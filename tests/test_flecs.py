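"""Micropattern contraction quantification against generator ground truth."""

import numpy as np
import pytest

from conftest import match_tracks_to_truth
from mechanoquant.flecs import (
    ContractionCurve,
    ContractionMetrics,
    analyze_flecs,
    classify_acceleration,
    contraction_curves,
    contraction_metrics,
    gate_occupancy,
    segment_patterns,
)
from mechanoquant.io import ImageStack
from mechanoquant.simulate import FlecsSimSpec, simulate_flecs_stack


class TestSegmentation:
    def test_all_patterns_found(self, flecs_fixture):
        _, stack, truth = flecs_fixture
        _, tracks = segment_patterns(stack)
        assert len(tracks) == truth.pattern_id.nunique()

    def test_blank_frame_yields_no_patterns(self):
        stack = ImageStack(np.zeros((2, 2, 64, 64)), 1.0, 1.0)
        with pytest.warns(UserWarning, match="no patterns"):
            _, tracks = segment_patterns(stack)
        assert tracks == []

    def test_border_pattern_excluded(self, flecs_fixture):
        _, stack, _ = flecs_fixture
        # crop so that the first pattern column is cut by the image border
        cut = ImageStack(
            stack.frames[:, :, :, 60:], stack.pixel_size_um,
            stack.frame_interval_s, list(stack.channel_names),
        )
        _, full_tracks = segment_patterns(stack)
        _, cut_tracks = segment_patterns(cut)
        assert len(cut_tracks) < len(full_tracks)

    def test_oversized_component_flagged_as_merged(self):
        # two crosses bridged into one component
        spec = FlecsSimSpec(n_patterns=6, occupancy_fraction=0.0,
                            noise_sd=0.0, rng_seed=2)
        stack, _ = simulate_flecs_stack(spec, 2)
        frames = stack.frames.copy()
        _, tracks = segment_patterns(stack)
        a, b = tracks[0], tracks[1]
        y0 = int((a.centroid[0] + b.centroid[0]) / 2)
        frames[:, 0,
               y0 - 4: y0 + 4,
               int(min(a.centroid[1], b.centroid[1])):
               int(max(a.centroid[1], b.centroid[1]))] = 200.0
        bridged = ImageStack(frames, stack.pixel_size_um,
                             stack.frame_interval_s)
        _, tracks2 = segment_patterns(bridged)
        assert len(tracks2) == len(tracks) - 1
        assert any(t.merged_suspect for t in tracks2)


class TestOccupancyGating:
    def test_flags_match_generator_truth_exactly(self, flecs_fixture):
        _, stack, truth = flecs_fixture
        labels, tracks = segment_patterns(stack)
        tracks = gate_occupancy(labels, tracks, stack.channel("nuclear")[0])
        for track, row in match_tracks_to_truth(tracks, truth):
            assert track.occupied == bool(row.occupied)

    def test_nucleus_outside_all_patterns_unoccupied(self, flecs_fixture):
        _, stack, _ = flecs_fixture
        labels, tracks = segment_patterns(stack)
        blank = np.zeros_like(stack.channel("nuclear")[0])
        blank[0:3, 0:3] = 200.0  # nucleus far from every pattern
        tracks = gate_occupancy(labels, tracks, blank)
        assert not any(t.occupied for t in tracks)

    def test_overlap_below_threshold_is_unoccupied(self):
        labels = np.zeros((16, 16), dtype=int)
        labels[4:12, 4:12] = 1
        from mechanoquant.flecs import PatternTrack

        track = PatternTrack(1, (8.0, 8.0), (4, 4, 12, 12), 64.0)
        nuc = np.zeros((16, 16))
        nuc[4, 4] = 255.0  # single-pixel overlap
        (track,) = gate_occupancy(labels, [track], nuc, min_overlap_px=5)
        assert not track.occupied


class TestContractionCurves:
    def test_contraction_is_reciprocal_area_fraction(self):
        curve = ContractionCurve(
            pattern_id=0, time_s=np.array([0.0, 180.0]),
            area_px=np.array([1000.0, 800.0]), stimulus_frame=1,
        )
        assert np.allclose(curve.area_fraction, [1.0, 0.8])
        assert np.allclose(curve.contraction, [1.0, 1.25])

    def test_static_fixture_contraction_stays_near_one(
        self, flecs_static_fixture
    ):
        _, stack, _ = flecs_static_fixture
        curves, _ = analyze_flecs(stack, stimulus_frame=10)
        assert np.allclose(curves.contraction, 1.0, atol=0.02)

    def test_measured_area_fraction_tracks_closed_form(self, flecs_fixture):
        spec, stack, _ = flecs_fixture
        curves, _ = analyze_flecs(stack, stimulus_frame=spec.stimulus_frame)
        expected = spec.area_fraction(np.arange(stack.n_frames))
        by_pattern = curves.pivot(index="frame", columns="pattern_id",
                                  values="area_fraction")
        assert np.abs(by_pattern.values - expected[:, None]).max() < 0.02

    def test_unoccupied_patterns_absent_from_output(self, flecs_fixture):
        _, stack, truth = flecs_fixture
        curves, _ = analyze_flecs(stack, stimulus_frame=10)
        n_occupied = int(truth[truth.frame == 0].occupied.sum())
        assert curves.pattern_id.nunique() == n_occupied

    def test_detached_pattern_truncated_at_loss_frame(self):
        """A pattern collapsing below a quarter of its initial area ends its
        track at the loss frame (detachment regime)."""
        frames = np.full((16, 2, 80, 80), 10.0)
        for t in range(16):
            half = 30 if t < 10 else 8  # area drops to ~7% at frame 10
            frames[t, 0, 40 - half: 40 + half, 40 - half: 40 + half] = 200.0
        frames[:, 1, 35:45, 35:45] = 180.0  # nucleus
        stack = ImageStack(frames, 1.0, 180.0, ["pattern", "nuclear"])
        labels, tracks = segment_patterns(stack, min_area_px=100)
        tracks = gate_occupancy(labels, tracks, stack.channel("nuclear")[0])
        (curve,) = contraction_curves(stack, labels, tracks,
                                      stimulus_frame=5)
        assert curve.lost_frame == 10
        assert curve.n_frames == 10
        metrics = contraction_metrics(curve, 180.0)
        assert metrics.truncated

    def test_stimulus_frame_beyond_stack_rejected(self, flecs_fixture):
        _, stack, _ = flecs_fixture
        labels, tracks = segment_patterns(stack)
        with pytest.raises(ValueError):
            contraction_curves(stack, labels, tracks,
                               stimulus_frame=stack.n_frames)


class TestContractionMetrics:
    def _curve_from_contraction(self, contraction, stimulus_frame, dt=180.0):
        contraction = np.asarray(contraction, dtype=float)
        return ContractionCurve(
            pattern_id=0,
            time_s=np.arange(len(contraction)) * dt,
            area_px=1000.0 / contraction,
            stimulus_frame=stimulus_frame,
        )

    def test_piecewise_linear_curve_gives_exact_ratio(self):
        b = 1e-4
        t = np.arange(30) * 180.0
        c = np.where(t <= 10 * 180.0,
                     1 + b * t,
                     1 + b * 10 * 180.0 + 3 * b * (t - 10 * 180.0))
        m = contraction_metrics(self._curve_from_contraction(c, 10), 180.0)
        assert m.speed_ratio == pytest.approx(3.0, rel=1e-9)
        assert m.speed_ratio_defined

    def test_flat_baseline_flagged_undefined(self):
        c = np.concatenate([np.ones(10), 1 + 0.01 * np.arange(20)])
        m = contraction_metrics(self._curve_from_contraction(c, 10), 180.0)
        assert not m.speed_ratio_defined
        assert np.isnan(m.speed_ratio)

    def test_max_contraction_taken_within_post_window(self):
        c = np.ones(30)
        c[12] = 1.4   # inside the window
        m = contraction_metrics(self._curve_from_contraction(c, 10), 180.0)
        assert m.max_contraction == pytest.approx(1.4)

    def test_speed_ratio_recovery_mean_within_10pct(self):
        spec = FlecsSimSpec(n_patterns=12, occupancy_fraction=1.0,
                            rng_seed=11)
        stack, _ = simulate_flecs_stack(spec, 45)
        _, metrics = analyze_flecs(stack, stimulus_frame=spec.stimulus_frame)
        ok = metrics[metrics.speed_ratio_defined]
        assert len(ok) == 12
        assert ok.speed_ratio.mean() == pytest.approx(3.0, rel=0.10)

    def test_stronger_stimulus_increases_recovered_speed_ratio(self):
        means = []
        for m_factor in (1.5, 3.0):
            spec = FlecsSimSpec(n_patterns=8, occupancy_fraction=1.0,
                                stimulus_multiplier=m_factor, rng_seed=4)
            stack, _ = simulate_flecs_stack(spec, 35)
            _, metrics = analyze_flecs(stack,
                                       stimulus_frame=spec.stimulus_frame)
            means.append(metrics.speed_ratio.mean())
        assert means[1] > means[0]


class TestClassification:
    @staticmethod
    def _metric(ratio, defined=True):
        return ContractionMetrics(
            pattern_id=0, max_contraction=1.0, baseline_slope=1.0,
            post_slope=ratio, speed_ratio=ratio, speed_ratio_defined=defined,
        )

    def test_threshold_rule_and_percentage(self):
        control = [self._metric(r) for r in (0.8, 1.0, 1.2)]  # mean 1.0
        treated = [self._metric(r) for r in (0.5, 1.2, 3.0)]
        flags, pct = classify_acceleration(treated, control)
        assert flags == [False, True, True]
        assert pct == pytest.approx(66.667, abs=0.01)

    def test_undefined_ratios_never_accelerated(self):
        control = [self._metric(1.0)]
        treated = [self._metric(np.nan, defined=False), self._metric(2.0)]
        flags, pct = classify_acceleration(treated, control)
        assert flags == [False, True]
        assert pct == pytest.approx(100.0)

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            classify_acceleration([self._metric(1.0)], [])

    def test_null_group_classified_near_chance(self):
        """A treated group drawn like the control lands near 50%."""
        rng = np.random.default_rng(0)
        control = [self._metric(r) for r in rng.normal(1.0, 0.2, 200)]
        treated = [self._metric(r) for r in rng.normal(1.0, 0.2, 200)]
        _, pct = classify_acceleration(treated, control)
        assert 35.0 < pct < 65.0
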