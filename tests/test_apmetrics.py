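"""Per-beat metrics: capture rule, durations vs oracle, EAD detector."""

import math

import numpy as np
import pytest

from cardiomap import apmetrics
from cardiomap.apmetrics import (
    Beat,
    apd_levels,
    apd_tri,
    detect_beats,
    detect_ead,
    excitability,
    summarize_tissue,
    upstroke_metrics,
)
from cardiomap.synthetic.waveform import (
    EADSpec,
    WaveformParams,
    make_ap_waveform,
    random_waveform_params,
    waveform_train_values,
)
from cardiomap.types import APTrace, StimProtocol


FS = 979.0
DT = 1000.0 / FS


def train_trace(params: WaveformParams, protocol: StimProtocol, skip=()) -> APTrace:
    """Paced trace with one waveform per pulse, optionally skipping beats."""
    t = np.arange(int(protocol.recording_duration_ms / DT)) * DT
    pulses = [p for i, p in enumerate(protocol.pulse_times_ms) if i not in skip]
    return APTrace(samples=waveform_train_values(params, t, np.array(pulses)),
                   frame_rate_hz=FS)


@pytest.fixture(scope="module")
def protocol():
    return StimProtocol.from_cycle_length(2000.0, 500.0, 10000.0)  # 5 pulses


class TestDetectBeats:
    def test_capture_flags_with_one_missed_beat(self, protocol):
        trace = train_trace(WaveformParams(), protocol, skip=(4,))
        beats = detect_beats(trace, protocol)
        assert [b.captured for b in beats] == [True, True, True, True, False]

    def test_late_upstroke_not_captured(self, protocol):
        late = WaveformParams(t_activation_ms=350.0, t_repol_ms=700.0)
        trace = train_trace(late, protocol)
        beats = detect_beats(trace, protocol, capture_window_ms=300.0)
        assert not any(b.captured for b in beats)

    def test_ead_beat_is_single_beat(self, protocol):
        p = WaveformParams(ead=EADSpec(t_onset_ms=250.0, amplitude_frac=0.2))
        trace = train_trace(p, protocol)
        beats = detect_beats(trace, protocol)
        assert len(beats) == protocol.n_stimuli
        assert all(b.captured for b in beats)

    def test_empty_protocol_rejected(self):
        with pytest.raises(ValueError):
            StimProtocol(pulse_times_ms=())


class TestExcitability:
    @pytest.mark.parametrize("n_captured,expected", [(4, 80.0), (5, 100.0), (0, 0.0)])
    def test_percentage(self, protocol, n_captured, expected):
        skip = tuple(range(n_captured, 5))
        trace = train_trace(WaveformParams(), protocol, skip=skip)
        beats = detect_beats(trace, protocol)
        if n_captured == 0:
            # a fully flat trace: force flags (median-amplitude rule needs signal)
            for b in beats:
                b.captured = False
        assert excitability(beats) == pytest.approx(expected)

    def test_non_excitable_tissue_has_no_metric_summaries(self, protocol):
        bms = [apmetrics.BeatMetrics(captured=False) for _ in range(5)]
        tm = summarize_tissue(bms, n_stimuli=5)
        assert tm.excitability_pct == 0.0
        assert all(math.isnan(v) for v in tm.means.values())


class TestUpstroke:
    def test_linear_ramp_rise_time(self):
        """10-90% crossing of a 20 ms linear ramp is exactly 16 ms."""
        fs = 1000.0
        t = np.arange(0, 1000.0, 1.0)
        y = np.clip((t - 100.0) / 20.0, 0.0, 1.0)
        y[t > 400] = 0.0
        beat = Beat(stimulus_time_ms=90.0, t_start_ms=0, t_end_ms=1000,
                    captured=True, amplitude=1.0, baseline=0.0, times_ms=t, samples=y)
        _, rise, _ = upstroke_metrics(beat, fs)
        assert rise == pytest.approx(16.0, abs=1e-9)

    def test_stim_delay_matches_activation_offset(self, protocol):
        p = WaveformParams(t_activation_ms=30.0)
        trace = train_trace(p, protocol)
        beats = detect_beats(trace, protocol)
        delay, _, _ = upstroke_metrics(beats[0], FS)
        assert delay == pytest.approx(30.0, abs=DT)

    def test_sigmoid_t_act_at_midpoint(self):
        """Max derivative of a logistic upstroke sits at its midpoint."""
        fs = 1000.0
        t = np.arange(0, 600.0, 1.0)
        y = 1 / (1 + np.exp(-(t - 100.0) / 5.0)) * 1 / (1 + np.exp((t - 400.0) / 10.0))
        beat = Beat(stimulus_time_ms=50.0, t_start_ms=0, t_end_ms=600,
                    captured=True, amplitude=1.0, baseline=0.0, times_ms=t, samples=y)
        _, _, t_act = upstroke_metrics(beat, fs)
        assert t_act == pytest.approx(100.0, abs=1.0)


class TestAPD:
    def test_square_pulse_all_levels_equal_width(self):
        fs = 1000.0
        t = np.arange(0, 600.0, 1.0)
        y = ((t >= 100) & (t < 300)).astype(float)
        beat = Beat(stimulus_time_ms=95.0, t_start_ms=0, t_end_ms=600,
                    captured=True, amplitude=1.0, baseline=0.0, times_ms=t, samples=y)
        _, _, t_act = upstroke_metrics(beat, fs, smooth_window_ms=0.0)
        levels = apd_levels(beat, t_act)
        for x in (30, 50, 80):
            assert levels[x] == pytest.approx(200.0, abs=2.0)

    def test_oracle_equivalence_over_seeded_waveforms(self, protocol):
        """APD30/50/80 within 1 sample, APD_MxR within 2, of brute force."""
        rng = np.random.default_rng(3)
        for _ in range(15):
            p = random_waveform_params(rng)
            trace = train_trace(p, protocol)
            beats = detect_beats(trace, protocol)
            m = apmetrics.measure_beat(beats[0], FS)
            _, _, truth = make_ap_waveform(p)
            assert m.apd30_ms == pytest.approx(truth.apd30_ms, abs=DT)
            assert m.apd50_ms == pytest.approx(truth.apd50_ms, abs=DT)
            assert m.apd80_ms == pytest.approx(truth.apd80_ms, abs=DT)
            assert m.apd_mxr_ms == pytest.approx(truth.apd_mxr_ms, abs=2 * DT)

    def test_monotone_levels(self, protocol):
        trace = train_trace(WaveformParams(), protocol)
        m = apmetrics.measure_beat(detect_beats(trace, protocol)[0], FS)
        assert m.apd30_ms <= m.apd50_ms <= m.apd80_ms

    def test_triangulation_identity(self):
        assert apd_tri(300.0, 250.0) == 50.0
        assert apd_tri(250.0, 250.0) == 0.0

    def test_slow_terminal_tail_gives_mxr_below_apd80(self, protocol):
        """Late slowing of repolarization makes APD_MxR diverge below APD80."""
        p = WaveformParams(tau_repol_ms=60.0, plateau_decay_per_ms=0.0,
                           t_repol_ms=300.0)
        trace = train_trace(p, protocol)
        m = apmetrics.measure_beat(detect_beats(trace, protocol)[0], FS)
        assert m.apd_mxr_ms < m.apd80_ms

    def test_sampling_rate_robustness(self):
        """Metrics at 979 Hz vs 2 kHz sampling agree within 1.5 ms."""
        proto = StimProtocol.from_cycle_length(2000.0, 500.0, 10000.0)
        p979 = WaveformParams(sampling_rate_hz=979.0)
        p2k = WaveformParams(sampling_rate_hz=2000.0)
        out = {}
        for p in (p979, p2k):
            dt = 1000.0 / p.sampling_rate_hz
            t = np.arange(int(10000.0 / dt)) * dt
            y = waveform_train_values(p, t, np.array(proto.pulse_times_ms))
            trace = APTrace(samples=y, frame_rate_hz=p.sampling_rate_hz)
            m = apmetrics.measure_beat(detect_beats(trace, proto)[0], p.sampling_rate_hz)
            out[p.sampling_rate_hz] = m
        for name in ("apd30_ms", "apd50_ms", "apd80_ms", "apd_mxr_ms"):
            assert getattr(out[979.0], name) == pytest.approx(
                getattr(out[2000.0], name), abs=1.5
            ), name


class TestEAD:
    def beat_from_params(self, p: WaveformParams, protocol) -> Beat:
        trace = train_trace(p, protocol)
        return detect_beats(trace, protocol)[0]

    def test_detects_inserted_bump(self, protocol):
        p = WaveformParams(ead=EADSpec(t_onset_ms=250.0, amplitude_frac=0.10))
        assert detect_ead(self.beat_from_params(p, protocol), FS)

    def test_clean_beat_negative(self, protocol):
        assert not detect_ead(self.beat_from_params(WaveformParams(), protocol), FS)

    def test_sensitivity_one_at_twice_threshold(self, protocol):
        """Noiseless bumps of amplitude >= 2x min_amp_frac are always caught."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = random_waveform_params(rng, apd_range_ms=(250.0, 500.0), with_ead=True)
            beat = self.beat_from_params(p, protocol)
            if p.ead.amplitude_frac >= 0.10:
                assert detect_ead(beat, FS, min_amp_frac=0.05)

    def test_false_positive_rate_under_noise(self, protocol):
        """<= 5% false positives on clean beats with 2% amplitude noise."""
        rng = np.random.default_rng(9)
        p = WaveformParams()
        fp = 0
        n_beats = 200
        for _ in range(n_beats):
            trace = train_trace(p, protocol)
            noisy = APTrace(
                samples=trace.samples + rng.normal(0, 0.02, size=len(trace.samples)),
                frame_rate_hz=FS,
            )
            beat = detect_beats(noisy, protocol)[0]
            fp += detect_ead(beat, FS)
        assert fp / n_beats <= 0.05


class TestSummaries:
    def test_mean_and_sd(self):
        bms = [apmetrics.BeatMetrics(apd80_ms=v) for v in (200.0, 202.0, 198.0)]
        tm = summarize_tissue(bms, n_stimuli=3)
        assert tm.means["apd80_ms"] == pytest.approx(200.0)
        assert tm.sds["apd80_ms"] == pytest.approx(2.0)

    def test_single_beat_sd_unavailable(self):
        tm = summarize_tissue([apmetrics.BeatMetrics(apd80_ms=200.0)], n_stimuli=1)
        assert tm.means["apd80_ms"] == 200.0
        assert math.isnan(tm.sds["apd80_ms"])

    def test_any_ead_beat_marks_tissue(self):
        bms = [apmetrics.BeatMetrics() for _ in range(4)]
        bms.append(apmetrics.BeatMetrics(ead=True))
        assert summarize_tissue(bms, n_stimuli=5).ead_present
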