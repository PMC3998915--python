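import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devtempo.catalog import ANCHOR_END, ANCHOR_START
from devtempo.focus import best_planes
from devtempo.staging import (
    EventCall,
    EventCalls,
    ReferenceBank,
    apply_corrections,
    build_composite,
    call_all_events,
    call_event,
    normalize_frame,
    score_series,
    smooth_trace,
)
from devtempo.synthdata import (
    PRIMARY_PROPORTIONS,
    EventProportions,
    stage_template,
)


class TestNormalizeFrame:
    def test_idempotent_within_interpolation_tolerance(self):
        tpl = stage_template("germ_band_maxima")
        n1 = normalize_frame(tpl)
        n2 = normalize_frame(n1)
        assert np.corrcoef(n1.ravel(), n2.ravel())[0, 1] > 0.97
        assert np.abs(n1 - n2).mean() < 0.05

    def test_rotation_invariance(self):
        """A 90-degree-rotated embryo normalizes to (nearly) the same
        canonical frame as the original."""
        tpl = stage_template("heart_shaped_midgut")
        n0 = normalize_frame(tpl)
        n90 = normalize_frame(np.rot90(tpl))
        assert n0.shape == n90.shape
        assert np.corrcoef(n0.ravel(), n90.ravel())[0, 1] > 0.97

    def test_metadata_flips_override_heuristic(self):
        tpl = stage_template("dorsal_divot")
        a = normalize_frame(tpl, flip_lr=False, flip_ud=False)
        b = normalize_frame(tpl, flip_lr=True, flip_ud=False)
        assert np.corrcoef(a.ravel(), b[:, ::-1].ravel())[0, 1] > 0.999

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="no foreground"):
            normalize_frame(np.full((32, 48), 0.5))


class TestBuildComposite:
    def test_single_frame_is_identity(self):
        tpl = stage_template("convoluted_gut")
        assert np.array_equal(build_composite([tpl]), tpl)

    def test_identical_frames_unchanged(self):
        tpl = stage_template("anal_plate_forms")
        assert np.allclose(build_composite([tpl, tpl.copy()]), tpl)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(5)
        frames = [rng.random((16, 24)) for _ in range(7)]
        expected = sum(frames) / len(frames)
        assert np.allclose(build_composite(frames), expected)

    def test_mixed_geometries_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            build_composite([np.zeros((8, 8)), np.zeros((8, 9))])


class TestScoreSeries:
    def test_trivial_correlations(self):
        ref = stage_template("midgut_unified")
        frames = np.stack([ref, 1.0 - ref, 2.0 * ref + 10.0])
        trace = score_series(frames, ref)
        assert trace[0] == pytest.approx(1.0)
        assert trace[1] == pytest.approx(-1.0)
        assert trace[2] == pytest.approx(1.0)  # Pearson affine invariance

    def test_matches_scipy_pearsonr(self):
        rng = np.random.default_rng(6)
        ref = rng.random((12, 18))
        frames = rng.random((5, 12, 18))
        trace = score_series(frames, ref)
        for t in range(5):
            expected = stats.pearsonr(frames[t].ravel(),
                                      ref.ravel()).statistic
            assert trace[t] == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_frame_is_missing_not_zero(self):
        ref = stage_template("gnathal_lobes_pinch")
        frames = np.stack([ref, np.full_like(ref, 0.5)])
        trace = score_series(frames, ref)
        assert np.isnan(trace[1])


class TestSmoothTrace:
    def test_window_one_is_identity(self):
        t = np.array([0.1, 0.5, 0.2, 0.9])
        assert np.array_equal(smooth_trace(t, window=1, order=0), t)

    def test_reproduces_quadratic_exactly(self):
        x = np.arange(31, dtype=float)
        t = 0.02 * x**2 - 0.3 * x + 1.0
        assert np.allclose(smooth_trace(t, window=9, order=2), t)

    def test_reduces_variance_on_flat_noise(self):
        rng = np.random.default_rng(7)
        t = 0.5 + rng.normal(0, 0.05, 200)
        sm = smooth_trace(t, window=9, order=2)
        assert sm[20:-20].var() < t[20:-20].var()

    def test_missing_values_stay_missing(self):
        t = np.linspace(0, 1, 30)
        t[10] = np.nan
        sm = smooth_trace(t, window=5, order=2)
        assert np.isnan(sm[10])
        assert np.isfinite(sm[9]) and np.isfinite(sm[11])

    @pytest.mark.parametrize("window,order", [(4, 2), (9, 9), (-1, 0)])
    def test_rejects_bad_parameters(self, window, order):
        with pytest.raises(ValueError):
            smooth_trace(np.zeros(50), window=window, order=order)


def _brute_force_call(trace, lo, hi):
    """Independent enumeration of interior local maxima."""
    best, best_val = None, -np.inf
    for i in range(max(lo, 1), min(hi, len(trace) - 2) + 1):
        v = trace[i]
        if np.isnan(v):
            continue
        if v >= trace[i - 1] and v >= trace[i + 1] and v > best_val:
            best, best_val = i, v
    if best is None:
        seg = trace[lo:hi + 1]
        return lo + int(np.nanargmax(seg))
    return best


class TestCallEvent:
    def test_triangular_peak(self):
        t = np.concatenate([np.linspace(0, 1, 11), np.linspace(1, 0, 11)[1:]])
        assert call_event(t, (2, 18)) == 10

    def test_monotone_trace_falls_back_to_window_argmax(self):
        t = np.linspace(0, 1, 30)
        assert call_event(t, (5, 20)) == 20

    def test_two_peak_trace_matches_brute_force(self):
        rng = np.random.default_rng(8)
        x = np.arange(100)
        t = (np.exp(-((x - 30) ** 2) / 40) + 1.4 *
             np.exp(-((x - 70) ** 2) / 60) + rng.normal(0, 0.01, 100))
        for lo, hi in [(0, 99), (10, 50), (40, 90), (25, 35)]:
            assert call_event(t, (lo, hi)) == _brute_force_call(t, lo, hi)

    def test_all_missing_window_uncallable(self):
        t = np.full(20, np.nan)
        assert call_event(t, (5, 15)) is None

    def test_tie_breaks_earliest(self):
        t = np.zeros(20)
        t[[8, 12]] = 1.0
        assert call_event(t, (0, 19)) == 8


class TestCallAllEvents:
    def test_recovers_scheduled_events(self, small_movie, primary_bank):
        movie, schedule = small_movie
        frames, _ = best_planes(movie)
        calls = call_all_events(frames, primary_bank, (
            schedule[ANCHOR_START], schedule[ANCHOR_END]),
            PRIMARY_PROPORTIONS)
        assert not calls.uncallable
        for event, truth_frame in schedule.items():
            assert abs(calls.frame(event) - truth_frame) <= 2, event

    def test_full_window_equals_global_argmax(self, small_movie,
                                              primary_bank):
        """tol = 0.5 spans the whole movie; with smoothing disabled the
        caller must agree with the brute-force argmax of the raw
        correlation trace."""
        movie, schedule = small_movie
        frames, _ = best_planes(movie)
        anchors = (schedule[ANCHOR_START], schedule[ANCHOR_END])
        event = "amnioserosa_exposed"
        trace = score_series(frames, primary_bank.composites[event])
        span = anchors[1] - anchors[0]
        # tol chosen so the window covers every frame of this movie
        tol = max((anchors[0] + 1) / span,
                  (len(trace) - anchors[0]) / span)
        calls = call_all_events(frames, primary_bank, anchors,
                                PRIMARY_PROPORTIONS, tol=tol,
                                smooth_window=1, smooth_order=0)
        assert calls.frame(event) == int(np.nanargmax(trace))

    def test_zero_proportion_event_window_centered_on_anchor(self):
        """An event at p_e = 0 searches a window centered on the
        cellularization anchor."""
        ref = stage_template("pole_cells_migrate")
        n = 60
        frames = np.tile(ref, (n, 1, 1))
        frames += np.arange(n)[:, None, None] * 0.0  # constant movie
        props = EventProportions({ANCHOR_START: 0.0,
                                  "pole_cells_migrate": 1e-9,
                                  ANCHOR_END: 1.0})
        calls = call_all_events(frames, ReferenceBank(
            composites={"pole_cells_migrate": ref}), (20, 50), props,
            tol=0.1, smooth_window=1)
        # constant trace: earliest frame of the clipped window wins
        assert calls.frame("pole_cells_migrate") == 20 - int(0.1 * 30)

    def test_subsampling_equivariance(self, small_movie, primary_bank):
        """Temporal subsampling by 2 halves every call to within one
        frame."""
        movie, schedule = small_movie
        frames, _ = best_planes(movie)
        anchors = (schedule[ANCHOR_START], schedule[ANCHOR_END])
        full = call_all_events(frames, primary_bank, anchors,
                               PRIMARY_PROPORTIONS)
        sub = call_all_events(frames[::2], primary_bank,
                              (anchors[0] // 2, anchors[1] // 2),
                              PRIMARY_PROPORTIONS)
        for event in schedule:
            if event in (ANCHOR_START, ANCHOR_END):
                continue
            assert abs(sub.frame(event) - full.frame(event) / 2) <= 1.5

    def test_invalid_anchors_rejected(self, primary_bank):
        frames = np.zeros((30, 64, 96))
        with pytest.raises(ValueError, match="anchor"):
            call_all_events(frames, primary_bank, (25, 10),
                            PRIMARY_PROPORTIONS)


class TestApplyCorrections:
    def _calls(self):
        return EventCalls(embryo_id="e1", calls={
            ANCHOR_START: EventCall(10, "anchor"),
            "pole_cells_invaginate": EventCall(20, "auto", 0.9),
            "amnioserosa_exposed": EventCall(50, "auto", 0.8),
            ANCHOR_END: EventCall(90, "anchor"),
        })

    def test_empty_corrections_are_identity(self):
        calls = self._calls()
        out = apply_corrections(calls, pd.DataFrame(
            columns=["embryo_id", "event", "frame"]))
        assert {e: c.frame for e, c in out.calls.items()} == \
            {e: c.frame for e, c in calls.calls.items()}

    def test_single_correction_changes_only_that_record(self):
        out = apply_corrections(self._calls(), pd.DataFrame([
            {"embryo_id": "e1", "event": "amnioserosa_exposed",
             "frame": 55}]))
        assert out.calls["amnioserosa_exposed"].frame == 55
        assert out.calls["amnioserosa_exposed"].source == "corrected"
        assert out.calls["pole_cells_invaginate"].frame == 20
        assert out.calls["pole_cells_invaginate"].source == "auto"

    def test_other_embryo_rows_ignored(self):
        out = apply_corrections(self._calls(), pd.DataFrame([
            {"embryo_id": "e2", "event": "amnioserosa_exposed",
             "frame": 55}]))
        assert out.calls["amnioserosa_exposed"].frame == 50

    def test_order_violation_names_offending_pair(self):
        with pytest.raises(ValueError) as err:
            apply_corrections(self._calls(), pd.DataFrame([
                {"embryo_id": "e1", "event": "amnioserosa_exposed",
                 "frame": 15}]))
        assert "amnioserosa_exposed" in str(err.value)
        assert "pole_cells_invaginate" in str(err.value)


class TestReferenceBank:
    def test_round_trips_through_directory(self, tmp_path, primary_bank):
        primary_bank.save(tmp_path / "bank")
        loaded = ReferenceBank.load(tmp_path / "bank")
        assert loaded.events == primary_bank.events
        for e in primary_bank.events:
            assert np.allclose(loaded.composites[e],
                               primary_bank.composites[e], atol=1e-6)

    def test_unknown_event_rejected(self):
        with pytest.raises(ValueError, match="unknown event"):
            ReferenceBank(composites={"not_an_event": np.zeros((8, 8))})
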