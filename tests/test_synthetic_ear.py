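"""Unit and property tests for the synthetic recording generator."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cisim
from cisim import (
    EarGroundTruth,
    TraumaProfile,
    cap_template,
    cohort_truths,
    stimulus_grid,
    synth_recording_set,
    tone_burst,
    trauma_shift,
)
from cisim.cap_pipeline import analyze_recording_set, bandpass_offline, polarity_average


class TestStimulusGrid:
    def test_default_lattice_size(self):
        g = stimulus_grid(2000, 32000, 4, 0, 90, 10)
        assert g.frequencies.size == 17  # 4 octaves x 4 steps + 1
        assert g.levels.size == 10

    def test_lattice_frequencies(self):
        g = stimulus_grid()
        assert g.frequencies[8] == pytest.approx(8000.0)  # two octaves up
        # the cell conventionally labelled "4.7 kHz": 2000 * 2^(5/4)
        assert g.frequencies[5] == pytest.approx(4756.83, abs=0.01)
        assert int(g.frequencies[5] / 100) / 10 == 4.7  # truncated display label

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(f_min=-1.0),
            dict(f_max=30000.0),  # not on the octave lattice
            dict(l_step=-10.0),
            dict(l_step=7.0),  # does not divide 90
            dict(steps_per_octave=0),
        ],
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            stimulus_grid(**kwargs)

    def test_ramps_must_fit_burst(self):
        with pytest.raises(ValueError):
            stimulus_grid(burst_duration=0.004, ramp_duration=0.0025)


class TestToneBurst:
    def test_polarity_symmetry(self, default_grid):
        for f in (2000.0, 8000.0, 32000.0):
            c = tone_burst(f, 1, default_grid)
            r = tone_burst(f, -1, default_grid)
            assert np.all(c + r == 0.0)

    def test_envelope_plateau(self, default_grid):
        """With a 5 ms burst and 2.5 ms ramps the envelope peaks exactly at
        the ramp end and the plateau has zero length."""
        g = default_grid
        burst = tone_burst(4000.0, 1, g)
        t = np.arange(burst.size) / g.sample_rate
        rising = t < g.ramp_duration
        env_rise = 0.5 * (1 - np.cos(np.pi * t[rising] / g.ramp_duration))
        assert np.all(np.diff(env_rise) >= 0)  # monotone rise
        assert np.max(np.abs(burst)) <= 1.0 + 1e-12
        # the envelope reaches its plateau value exactly at t = ramp end,
        # and with 2 * ramp == burst the plateau has zero length
        assert 0.5 * (1 - np.cos(np.pi * g.ramp_duration / g.ramp_duration)) == pytest.approx(1.0)
        assert g.burst_duration - 2 * g.ramp_duration == pytest.approx(0.0)

    def test_rms_matches_numeric_envelope_integration(self, default_grid):
        """RMS of the unit-amplitude burst agrees with trapezoidal
        integration of the squared ramped envelope (carrier averaged)."""
        g = default_grid
        f = 8000.0
        burst = tone_burst(f, 1, g)
        rms = np.sqrt(np.mean(burst**2))
        t = np.arange(burst.size) / g.sample_rate
        env = np.ones_like(t)
        ramp = g.ramp_duration
        env[t < ramp] = 0.5 * (1 - np.cos(np.pi * t[t < ramp] / ramp))
        fall = t > g.burst_duration - ramp
        env[fall] = 0.5 * (1 - np.cos(np.pi * (g.burst_duration - t[fall]) / ramp))
        expected = np.sqrt(np.trapezoid(env**2 * np.sin(2 * np.pi * f * t) ** 2, t) / g.burst_duration)
        assert rms == pytest.approx(expected, rel=0.01)

    def test_above_nyquist_rejected(self, default_grid):
        with pytest.raises(ValueError):
            tone_burst(60000.0, 1, default_grid)


class TestTraumaShift:
    def test_logistic_anchors(self):
        p = TraumaProfile(ts_max=20.0, f_edge=6700.0, slope_w=0.5)
        assert trauma_shift(6700.0, p) == pytest.approx(10.0)
        # >= 4 slope widths below the edge: < 2% of the maximum
        assert trauma_shift(6700.0 * 2 ** (-4 * 0.5), p) < 0.02 * 20.0
        # far above the edge: saturates at ts_max
        assert trauma_shift(32000.0, p) > 0.95 * 20.0
        assert trauma_shift(1e7, p) == pytest.approx(20.0, abs=1e-6)

    @given(st.floats(2000.0, 32000.0), st.floats(2001.0, 31999.0))
    def test_monotone_in_frequency_and_magnitude(self, f, f_edge):
        lo = TraumaProfile(ts_max=10.0, f_edge=f_edge, slope_w=0.4)
        hi = TraumaProfile(ts_max=25.0, f_edge=f_edge, slope_w=0.4)
        freqs = np.linspace(2000, 32000, 31)
        ts = trauma_shift(freqs, lo)
        assert np.all(np.diff(ts) >= -1e-12)  # non-decreasing in f
        assert np.all(trauma_shift(freqs, hi) >= ts - 1e-12)  # monotone in ts_max
        assert 0 <= trauma_shift(f, lo) <= 10.0

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            TraumaProfile(ts_max=-1.0, f_edge=6700.0, slope_w=0.5)
        with pytest.raises(ValueError):
            TraumaProfile(ts_max=1.0, f_edge=1000.0, slope_w=0.5)
        with pytest.raises(ValueError):
            TraumaProfile(ts_max=1.0, f_edge=6700.0, slope_w=0.0)


def _flat_truth(grid, **kw):
    defaults = dict(
        ear_id="earX",
        group="6Ch",
        baseline_thresholds=np.full(grid.frequencies.size, 30.0),
        trauma=TraumaProfile(ts_max=20.0, f_edge=6700.0, slope_w=0.35),
        seed=7,
    )
    defaults.update(kw)
    return EarGroundTruth(**defaults)


class TestSynthRecordingSet:
    def test_determinism_byte_identical(self, small_grid):
        truth = _flat_truth(small_grid)
        a = synth_recording_set(truth, "inserted", small_grid)
        b = synth_recording_set(truth, "inserted", small_grid)
        assert a.waveforms.tobytes() == b.waveforms.tobytes()

    def test_conditions_differ(self, small_grid):
        truth = _flat_truth(small_grid)
        a = synth_recording_set(truth, "initial", small_grid)
        b = synth_recording_set(truth, "inserted", small_grid)
        assert not np.array_equal(a.waveforms, b.waveforms)

    def test_unknown_condition_rejected(self, small_grid):
        with pytest.raises(ValueError):
            synth_recording_set(_flat_truth(small_grid), "postop", small_grid)

    def test_subthreshold_traces_are_noise_only(self, small_grid):
        """Below the effective threshold no CAP is injected: the filtered,
        polarity-averaged peak-to-peak stays within noise bounds."""
        g = small_grid
        truth = _flat_truth(g, baseline_thresholds=np.full(g.frequencies.size, 75.0), noise_sd=0.3)
        rs = synth_recording_set(truth, "initial", g)
        avg = rs.waveforms[:, :2].mean(axis=2)  # levels 20 and 40 dB only
        filt = bandpass_offline(avg.reshape(-1, avg.shape[-1]), g.sample_rate)
        post = filt[:, g.onset_index :]
        assert np.ptp(post, axis=-1).max() < 4 * truth.noise_sd

    def test_noise_free_p2p_matches_template_oracle(self, small_grid):
        """With zero noise, the measured p2p at threshold + 20 dB equals
        cap_gain * 20 times the (filtered) template p2p factor."""
        g = small_grid
        truth = _flat_truth(g, baseline_thresholds=np.full(g.frequencies.size, 40.0), noise_sd=0.0, cm_gain=0.0)
        rs = synth_recording_set(truth, "initial", g)
        ana = analyze_recording_set(rs)
        j = int(np.flatnonzero(g.levels == 60.0)[0])  # 20 dB above threshold
        from cisim.cap_pipeline import extract_cap

        tpl = cap_template(g, 60.0)  # unit p2p before filtering
        tpl_factor = extract_cap(
            bandpass_offline(tpl, g.sample_rate), g.onset_index, g.sample_rate
        ).p2p_amplitude_uv
        expected = truth.cap_gain * 20.0 * tpl_factor
        assert ana.p2p_uv[:, j] == pytest.approx(expected, rel=1e-6)

    def test_cm_cancellation_residual(self, small_grid):
        """CAP-free, noise-free ear: polarity averaging cancels the CM to
        below 1e-9 of its amplitude."""
        g = small_grid
        truth = _flat_truth(
            g,
            baseline_thresholds=np.full(g.frequencies.size, 80.0),
            noise_sd=0.0,
            cap_gain=0.0,
            cm_gain=5.0,
        )
        rs = synth_recording_set(truth, "initial", g)
        cm_amp = np.abs(rs.waveforms).max()
        assert cm_amp > 0
        avg = polarity_average(rs.waveforms[:, :, 0], rs.waveforms[:, :, 1])
        assert np.abs(avg).max() < 1e-9 * cm_amp


class TestCohort:
    def test_default_cohort_composition(self):
        truths = cohort_truths(master_seed=3)
        assert len(truths) == 24
        groups = [t.group for t in truths]
        assert groups.count("5Ch") == 12 and groups.count("6Ch") == 12
        assert len({t.ear_id for t in truths}) == 24

    def test_cohort_determinism(self):
        a = cohort_truths(master_seed=11)
        b = cohort_truths(master_seed=11)
        for ta, tb in zip(a, b):
            assert ta.to_dict() == tb.to_dict()
        c = cohort_truths(master_seed=12)
        assert any(ta.to_dict() != tc.to_dict() for ta, tc in zip(a, c))

    def test_cochleostomy_jitter_zero_mean(self):
        jitters = np.concatenate(
            [t.cochleostomy_jitter for s in range(40) for t in cohort_truths(master_seed=s)]
        )
        sem = jitters.std() / np.sqrt(jitters.size)
        assert abs(jitters.mean()) < 4 * sem + 1e-12

    def test_injected_max_ts_calibration(self, default_grid):
        """Over many cohorts the per-ear max injected TS averages to the
        calibrated group targets (23 dB deep, 10 dB shallow)."""
        m = {"5Ch": [], "6Ch": []}
        for s in range(150):
            for t in cohort_truths(master_seed=s):
                m[t.group].append(trauma_shift(default_grid.frequencies, t.trauma).max())
        assert np.mean(m["6Ch"]) == pytest.approx(23.0, abs=0.7)
        assert np.mean(m["5Ch"]) == pytest.approx(10.0, abs=0.9)

    def test_effective_threshold_monotone_in_trauma(self, default_grid):
        g = default_grid
        base = np.full(g.frequencies.size, 30.0)
        for ts_hi in (5.0, 15.0, 40.0):
            lo = _flat_truth(g, baseline_thresholds=base, trauma=TraumaProfile(ts_max=ts_hi / 2, f_edge=6700.0, slope_w=0.35))
            hi = _flat_truth(g, baseline_thresholds=base, trauma=TraumaProfile(ts_max=ts_hi, f_edge=6700.0, slope_w=0.35))
            assert np.all(
                hi.effective_thresholds("inserted", g) >= lo.effective_thresholds("inserted", g) - 1e-12
            )

    def test_n_ears_validation(self):
        with pytest.raises(ValueError):
            cisim.CohortConfig(n_ears=0)


class TestBundleIO:
    def test_csv_round_trip(self, tmp_path, small_grid):
        from cisim import read_bundle, write_bundle

        truth = _flat_truth(small_grid)
        recs = {c: synth_recording_set(truth, c, small_grid) for c in cisim.CONDITIONS}
        write_bundle(tmp_path / "earX", recs, truth=truth, config_hash="abc", fmt="csv")
        back = read_bundle(tmp_path / "earX")
        assert set(back) == set(cisim.CONDITIONS)
        for c in cisim.CONDITIONS:
            assert back[c].grid.to_dict() == recs[c].grid.to_dict()  # metadata exact
            np.testing.assert_allclose(back[c].waveforms, recs[c].waveforms, atol=1e-6)

    def test_npz_round_trip(self, tmp_path, small_grid):
        from cisim import read_bundle, write_bundle

        truth = _flat_truth(small_grid)
        recs = {"initial": synth_recording_set(truth, "initial", small_grid)}
        write_bundle(tmp_path / "earY", recs, fmt="npz")
        back = read_bundle(tmp_path / "earY")
        np.testing.assert_array_equal(back["initial"].waveforms, recs["initial"].waveforms)
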