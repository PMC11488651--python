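"""dF/F0 extraction, response classification, artifacts, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from ribbonquant.calcium import (
    CLASS_PARAMS,
    CalciumParams,
    RoiTrace,
    baseline_intensity,
    classify_response,
    extract_dff,
    flag_square_wave,
    preprocess_movie,
    summarize_responses,
)
from ribbonquant.synth import MovieSpec, generate_calcium_movie

PRE = CLASS_PARAMS["presynaptic"]
BUNDLE = CLASS_PARAMS["hair_bundle"]
POST = CLASS_PARAMS["postsynaptic"]


def _trace(dff, f0=100.0):
    dff = np.asarray(dff, dtype=float)
    return RoiTrace(center=(0, 0), raw=f0 * (1 + dff), f0=f0, dff=dff,
                    max_dff=float(dff.max()))


def _step_trace(n, onset, value):
    dff = np.zeros(n)
    dff[onset:] = value
    return dff


class TestPreprocess:
    def test_trims_ten_timepoints(self):
        spec = MovieSpec(n_timepoints=110, n_rois=4, noise_sd=0, seed=0)
        movie, _ = generate_calcium_movie(spec)
        frames, shifts = preprocess_movie(movie, PRE)
        assert frames.shape[0] == 100
        assert shifts.shape == (110, 2)

    def test_static_movie_has_zero_shifts(self):
        spec = MovieSpec(n_timepoints=40, n_rois=4, noise_sd=0,
                         planted_amplitudes=0.0, seed=1)
        movie, _ = generate_calcium_movie(spec)
        _frames, shifts = preprocess_movie(movie, PRE)
        assert np.abs(shifts).max() < 1e-6

    @pytest.mark.parametrize("shift", [(2.0, 3.0), (1.5, -0.5)])
    def test_constructed_shift_recovered(self, shift):
        spec = MovieSpec(n_timepoints=40, n_rois=4, noise_sd=0,
                         planted_amplitudes=0.0, seed=2)
        movie, _ = generate_calcium_movie(spec)
        # translate every frame from timepoint 20 on
        moved = movie.copy()
        for t in range(20, 40):
            for z in range(movie.shape[1]):
                moved[t, z] = ndi.shift(movie[t, z], shift, order=3, mode="nearest")
        _frames, shifts = preprocess_movie(moved, PRE)
        # registration reports the correction, i.e. minus the applied shift
        assert np.allclose(shifts[25:], [-shift[0], -shift[1]], atol=0.1)

    def test_too_short_movie_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            preprocess_movie(np.zeros((25, 2, 8, 8)), PRE)


class TestExtractDff:
    def test_constant_trace_is_zero(self):
        frames = np.full((40, 30, 30), 80.0)
        tr = extract_dff(frames, (15, 15), PRE)
        assert np.allclose(tr.dff, 0.0)
        assert tr.f0 == pytest.approx(80.0)

    def test_plateau_arithmetic(self):
        frames = np.full((40, 30, 30), 100.0)
        frames[25:] = 150.0
        tr = extract_dff(frames, (15, 15), PRE)
        assert tr.max_dff == pytest.approx(0.5)

    def test_baseline_window_normalizes_to_zero(self):
        rng = np.random.default_rng(0)
        frames = 100.0 + rng.normal(0, 5, (60, 30, 30))
        tr = extract_dff(frames, (15, 15), PRE)
        assert abs(tr.dff[: PRE.n_baseline].mean()) < 1e-12

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            extract_dff(np.full((10, 30, 30), 50.0), (15, 15), PRE)

    def test_out_of_bounds_roi_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            extract_dff(np.full((40, 30, 30), 50.0), (2, 15), PRE)

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ValueError, match="F0"):
            extract_dff(np.zeros((40, 30, 30)), (15, 15), PRE)


class TestClassify:
    # onset frame 20 in the trimmed trace, 0.1 s frames, 0.5 s stimulus
    def test_presynaptic_in_stimulus_threshold(self):
        dff = np.zeros(80)
        dff[22] = 0.12
        assert classify_response(_trace(dff), PRE, 20)

    def test_presynaptic_onset_window_or_clause(self):
        dff = np.zeros(80)
        dff[23] = 0.08  # below the 10% in-stimulus bar
        dff[29] = 0.25  # 0.9 s after onset, above the 20% bar
        assert classify_response(_trace(dff), PRE, 20)

    def test_presynaptic_below_both_bars(self):
        dff = np.zeros(80)
        dff[23] = 0.08
        dff[40] = 0.5  # outside both windows
        assert not classify_response(_trace(dff), PRE, 20)

    def test_postsynaptic_needs_500ms_duration(self):
        short = _trace(np.concatenate([np.zeros(30), np.full(3, 0.08), np.zeros(30)]))
        assert not classify_response(short, POST, 20)
        long = _trace(np.concatenate([np.zeros(30), np.full(5, 0.08), np.zeros(30)]))
        assert classify_response(long, POST, 20)

    def test_flat_trace_not_responsive(self):
        assert not classify_response(_trace(np.zeros(80)), PRE, 20)

    def test_bundle_requires_sustained_after_stimulus(self):
        dff = np.zeros(80)
        dff[21:26] = 0.2  # during stimulus only
        assert not classify_response(_trace(dff), BUNDLE, 20)
        dff[26:31] = 0.2  # and through the 500 ms after
        assert classify_response(_trace(dff), BUNDLE, 20)

    def test_bundle_both_directions_excluded(self):
        dff = np.zeros(80)
        dff[21:31] = 0.3
        assert classify_response(_trace(dff), BUNDLE, 20)
        assert not classify_response(
            _trace(dff), BUNDLE, 20, responds_both_directions=True
        )

    def test_artifact_never_responsive(self):
        tr = _trace(_step_trace(80, 22, 0.5))
        tr.artifact = True
        assert not classify_response(tr, PRE, 20)

    def test_unknown_class_rejected(self):
        bad = CalciumParams(signal_class="nonsense", roi_size=8)
        with pytest.raises(ValueError, match="unknown signal class"):
            classify_response(_trace(np.zeros(80)), bad, 20)

    @given(st.floats(1.0, 20.0), st.sampled_from(["presynaptic", "postsynaptic"]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scaling_up_preserves_responsiveness(self, scale, cls):
        params = CLASS_PARAMS[cls]
        dff = np.zeros(80)
        dff[21:27] = 0.11
        base = classify_response(_trace(dff), params, 20)
        assert base
        assert classify_response(_trace(dff * scale), params, 20)


class TestSquareWave:
    def test_instantaneous_sustained_step_flagged(self):
        assert flag_square_wave(_step_trace(80, 30, 0.5))

    def test_physiological_transient_not_flagged(self):
        t = np.arange(80) * 0.1
        dff = np.where(t > 2, (np.exp(-(t - 2) / 1.2) - np.exp(-(t - 2) / 0.18)), 0)
        assert not flag_square_wave(dff)

    def test_flat_trace_not_flagged(self):
        assert not flag_square_wave(np.zeros(80))

    def test_generator_artifact_is_caught_by_pipeline(self):
        from ribbonquant.experiments import process_movie

        spec = MovieSpec(n_rois=4, artifact_rois=(2,), seed=5)
        movie, table = generate_calcium_movie(spec)
        traces, organ = process_movie(spec, movie, table)
        assert traces[2].artifact and not traces[2].responsive
        assert all(not t.artifact for i, t in enumerate(traces) if i != 2)
        assert organ.n_active == 3


class TestSummarize:
    def test_mean_trace_peak(self):
        shape = np.zeros(50)
        shape[30:35] = 1.0
        a, b = _trace(0.3 * shape), _trace(0.5 * shape)
        a.responsive = b.responsive = True
        organ = summarize_responses([a, b])
        assert organ.max_dff == pytest.approx(0.4)
        assert organ.n_active == 2

    def test_no_responsive_rois(self):
        organ = summarize_responses([_trace(np.zeros(50))])
        assert organ.n_active == 0 and np.isnan(organ.max_dff)

    def test_direction_tally(self):
        traces = []
        for d in ("A-to-P", "A-to-P", "P-to-A"):
            tr = _trace(np.full(30, 0.2))
            tr.responsive, tr.direction = True, d
            traces.append(tr)
        organ = summarize_responses(traces)
        assert organ.n_active_by_direction == {"A-to-P": 2, "P-to-A": 1}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_responses([])


class TestBaselineIntensity:
    def test_bimodal_foreground_mean(self):
        frame = np.full((40, 40), 10.0)
        frame[10:30, 10:30] = 200.0
        value, degenerate = baseline_intensity(np.stack([frame] * 5), slice(0, 5))
        assert not degenerate
        assert value == pytest.approx(200.0)

    def test_two_frame_average(self):
        def frame(fg):
            f = np.full((40, 40), 10.0)
            f[10:30, 10:30] = fg
            return f

        value, _ = baseline_intensity(np.stack([frame(100), frame(120)]), slice(0, 2))
        assert value == pytest.approx(110.0)

    def test_uniform_frames_flagged(self):
        value, degenerate = baseline_intensity(np.full((3, 20, 20), 9.0), slice(0, 3))
        assert degenerate and value == pytest.approx(9.0)


def test_amplitude_recovery_across_rois():
    """Planted peaks recovered within 10% at 1% noise, >= 20 ROIs."""
    from ribbonquant.experiments import process_movie

    recovered, planted = [], []
    for seed in range(3):
        spec = MovieSpec(n_rois=8, planted_amplitudes=0.40, seed=seed)
        movie, table = generate_calcium_movie(spec)
        traces, _ = process_movie(spec, movie, table)
        recovered.extend(t.max_dff for t in traces)
        planted.extend(table.planted_amplitude)
    recovered, planted = np.array(recovered), np.array(planted)
    assert len(recovered) >= 20
    assert np.all(np.abs(recovered - planted) / planted < 0.10)


def test_zero_amplitude_movie_has_no_responders():
    from ribbonquant.experiments import process_movie

    spec = MovieSpec(n_rois=6, planted_amplitudes=0.0, seed=9)
    movie, table = generate_calcium_movie(spec)
    _traces, organ = process_movie(spec, movie, table)
    assert organ.n_active == 0
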