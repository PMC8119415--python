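"""Per-beat pro-arrhythmia metrics from a per-tissue voltage-proxy trace.

Eight metrics per paced recording, following optical-mapping conventions
for uncalibrated dye signals (all durations referenced to the per-beat
amplitude and diastolic baseline, never to absolute voltage):

- excitability: percentage of delivered stimuli that evoke a captured AP;
- stimulation delay: stimulus onset to AP upstroke (time of max dF/dt);
- rise time: 10-90% upstroke duration;
- APD30/50/80: upstroke to 30/50/80% repolarization, linearly
  interpolated at the level crossings;
- APD_MxR: upstroke to the end of rapid repolarization, located at the
  maximum of the second time-derivative of the smoothed trace in the
  window after the APD50 crossing;
- APD triangulation: APD_MxR - APD50 (elevated triangulation is a
  delayed-phase-3 / hERG-block signature);
- EAD flag: a secondary depolarization between the beat peak and 90%
  repolarization.

Derivatives are taken on a Savitzky-Golay-smoothed trace (zero-phase
polynomial filter) because raw second differences of photon-limited
signals are noise-dominated; window lengths are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from cardiomap.types import APTrace, StimProtocol

__all__ = [
    "Beat",
    "BeatMetrics",
    "TissueMetrics",
    "detect_beats",
    "excitability",
    "upstroke_metrics",
    "apd_levels",
    "apd_mxr",
    "apd_tri",
    "detect_ead",
    "measure_beat",
    "analyze_trace",
    "summarize_tissue",
]

METRIC_NAMES = (
    "stim_delay_ms",
    "rise_time_ms",
    "apd30_ms",
    "apd50_ms",
    "apd80_ms",
    "apd_mxr_ms",
    "apd_tri_ms",
)


@dataclass
class Beat:
    """One stimulus window of a trace."""

    stimulus_time_ms: float
    t_start_ms: float
    t_end_ms: float
    captured: bool
    amplitude: float
    baseline: float
    times_ms: np.ndarray  # samples within [t_start, t_end)
    samples: np.ndarray


@dataclass
class BeatMetrics:
    """The per-beat metric record; NaN marks unavailable values."""

    stim_delay_ms: float = math.nan
    rise_time_ms: float = math.nan
    apd30_ms: float = math.nan
    apd50_ms: float = math.nan
    apd80_ms: float = math.nan
    apd_mxr_ms: float = math.nan
    apd_tri_ms: float = math.nan
    ead: bool = False
    captured: bool = True


@dataclass
class TissueMetrics:
    """Per-tissue summary over the captured beats of one recording."""

    excitability_pct: float
    beats: list[BeatMetrics]
    means: dict[str, float]
    sds: dict[str, float]
    ead_present: bool
    n_captured: int
    n_stimuli: int


def _smooth(y: np.ndarray, fs_hz: float, window_ms: float, order: int = 3) -> np.ndarray:
    win = max(order + 2, int(round(window_ms * fs_hz / 1000.0)))
    if win % 2 == 0:
        win += 1
    if win >= len(y):
        win = len(y) - 1 if (len(y) - 1) % 2 == 1 else len(y) - 2
    if win <= order:
        return y.astype(float)
    return savgol_filter(y, window_length=win, polyorder=order)


def detect_beats(
    trace: APTrace,
    protocol: StimProtocol,
    capture_window_ms: float = 300.0,
    capture_amp_frac: float = 0.5,
    min_amplitude: float = 0.0,
    smooth_window_ms: float = 5.0,
) -> list[Beat]:
    """Split a trace into one Beat per stimulus and flag captured beats.

    Each beat window spans from its pulse onset to the next pulse onset
    (or the trace end). A beat is captured when a positive deflection of
    amplitude at least ``capture_amp_frac`` times the median candidate
    amplitude (and at least ``min_amplitude``, for screening non-excitable
    tissues) reaches its maximum dF/dt within ``capture_window_ms`` of the
    pulse onset. Spontaneous, non-stimulus-locked activity is not
    assigned a beat.
    """
    if protocol.n_stimuli == 0:
        raise ValueError("protocol contains no stimuli")
    t = trace.times_ms
    y = trace.samples
    pulses = list(protocol.pulse_times_ms)
    edges = pulses[1:] + [t[-1] + (t[1] - t[0])]

    records = []
    prev_start = t[0]
    for pulse, nxt in zip(pulses, edges):
        sel = (t >= pulse) & (t < nxt)
        tw, yw = t[sel], y[sel]
        # diastolic baseline: median of the last 10% of the preceding window
        base_sel = (t >= prev_start) & (t < pulse)
        tb, yb = t[base_sel], y[base_sel]
        if len(yb) >= 2:
            span = tb[-1] - tb[0]
            tail = yb[tb >= tb[-1] - 0.1 * span]
            baseline = float(np.median(tail))
        elif len(yw):
            baseline = float(yw[0])
        else:
            baseline = 0.0
        amp = float(yw.max() - baseline) if len(yw) else 0.0

        t_dvmax = math.nan
        if len(yw) >= 5:
            ys = _smooth(yw, trace.frame_rate_hz, smooth_window_ms)
            dv = np.gradient(ys, tw)
            t_dvmax = float(tw[int(np.argmax(dv))])
        records.append((pulse, tw, yw, baseline, amp, t_dvmax))
        prev_start = pulse

    med_amp = float(np.median([r[4] for r in records]))
    beats = []
    for pulse, tw, yw, baseline, amp, t_dvmax in records:
        captured = (
            len(yw) >= 5
            and amp > 0
            and amp >= capture_amp_frac * med_amp
            and amp >= min_amplitude
            and not math.isnan(t_dvmax)
            and (t_dvmax - pulse) <= capture_window_ms
        )
        beats.append(
            Beat(
                stimulus_time_ms=pulse,
                t_start_ms=pulse,
                t_end_ms=float(tw[-1]) if len(tw) else pulse,
                captured=captured,
                amplitude=amp,
                baseline=baseline,
                times_ms=tw,
                samples=yw,
            )
        )
    return beats


def excitability(beats: list[Beat]) -> float:
    """Percentage of delivered stimuli that evoked a captured AP."""
    if not beats:
        raise ValueError("no beats")
    return 100.0 * sum(b.captured for b in beats) / len(beats)


def _interp_crossing_down(t, y, level, start_idx):
    """First downward crossing of ``level`` after ``start_idx`` (interp)."""
    seg = y[start_idx:]
    below = np.nonzero(seg <= level)[0]
    if below.size == 0:
        return math.nan
    j = below[0] + start_idx
    if j == start_idx or y[j - 1] == y[j]:
        return float(t[j])
    return float(t[j - 1] + (y[j - 1] - level) / (y[j - 1] - y[j]) * (t[j] - t[j - 1]))


def _interp_crossing_up(t, y, level, stop_idx):
    """First upward crossing of ``level`` at or before ``stop_idx`` (interp)."""
    seg = y[: stop_idx + 1]
    above = np.nonzero(seg >= level)[0]
    if above.size == 0:
        return math.nan
    j = above[0]
    if j == 0 or y[j] == y[j - 1]:
        return float(t[j])
    return float(t[j - 1] + (level - y[j - 1]) / (y[j] - y[j - 1]) * (t[j] - t[j - 1]))


def upstroke_metrics(
    beat: Beat,
    fs_hz: float,
    capture_window_ms: float = 300.0,
    smooth_window_ms: float = 5.0,
) -> tuple[float, float, float]:
    """(stim_delay_ms, rise_time_ms, t_act_ms) of a captured beat.

    t_act is the time of maximum first derivative of the smoothed trace
    within the capture window; rise time is the 10-90% amplitude crossing
    interval on the upstroke, linearly interpolated between samples.
    """
    if not beat.captured:
        return math.nan, math.nan, math.nan
    tw, yw = beat.times_ms, beat.samples
    ys = _smooth(yw, fs_hz, smooth_window_ms)
    dv = np.gradient(ys, tw)
    win = tw - beat.stimulus_time_ms <= capture_window_ms
    i_act = int(np.argmax(np.where(win, dv, -np.inf)))
    t_act = float(tw[i_act])
    stim_delay = t_act - beat.stimulus_time_ms

    i_peak = int(np.argmax(yw))
    lo = beat.baseline + 0.10 * beat.amplitude
    hi = beat.baseline + 0.90 * beat.amplitude
    t10 = _interp_crossing_up(tw, yw, lo, i_peak)
    t90 = _interp_crossing_up(tw, yw, hi, i_peak)
    rise = t90 - t10 if not (math.isnan(t10) or math.isnan(t90)) else math.nan
    return stim_delay, rise, t_act


def apd_levels(
    beat: Beat, t_act: float, levels: tuple[int, ...] = (30, 50, 80)
) -> dict[int, float]:
    """APD to each repolarization level, from t_act, interpolated.

    APD_x is the first time after the beat peak at which the trace falls
    to (1 - x/100) of the amplitude above the diastolic baseline, minus
    t_act. Levels never crossed within the window (e.g. an EAD holding
    the potential up) come back NaN.
    """
    if beat.amplitude <= 0:
        raise ValueError("apd_levels requires a positive beat amplitude")
    tw, yw = beat.times_ms, beat.samples
    i_peak = int(np.argmax(yw))
    out: dict[int, float] = {}
    for x in levels:
        level = beat.baseline + (1.0 - x / 100.0) * beat.amplitude
        t_cross = _interp_crossing_down(tw, yw, level, i_peak)
        out[x] = t_cross - t_act if not math.isnan(t_cross) else math.nan
    return out


def apd_mxr(
    beat: Beat,
    t_act: float,
    apd50_ms: float,
    fs_hz: float,
    smooth_window_ms: float = 11.0,
    end_level_frac: float = 0.05,
    end_margin_ms: float = 20.0,
) -> float:
    """APD to the end of rapid repolarization (max d2F/dt2 after APD50).

    The second derivative is taken on the smoothed trace and searched
    from the APD50 crossing to shortly after the trace has essentially
    reached baseline (the ``end_level_frac`` amplitude crossing plus
    ``end_margin_ms``; the beat window end when that level is never
    reached, e.g. under a sustained EAD). Bounding the search there
    matters on noisy recordings: once repolarization is complete the
    true curvature is ~0 and an unbounded arg-max would lock onto
    diastolic noise. A parabolic fit around the discrete arg-max gives
    sub-sample timing.
    """
    if math.isnan(apd50_ms):
        return math.nan
    tw, yw = beat.times_ms, beat.samples
    ys = _smooth(yw, fs_hz, smooth_window_ms)
    dv = np.gradient(ys, tw)
    d2v = np.gradient(dv, tw)
    start = int(np.searchsorted(tw, t_act + apd50_ms))
    if start >= len(tw) - 1:
        return math.nan
    level = beat.baseline + end_level_frac * beat.amplitude
    t_end = _interp_crossing_down(tw, ys, level, start)
    if math.isnan(t_end):
        stop = len(tw)
    else:
        stop = min(len(tw), int(np.searchsorted(tw, t_end + end_margin_ms)) + 1)
    if stop - start < 2:
        stop = min(len(tw), start + 2)
    i_rel = int(np.argmax(d2v[start:stop]))
    i = start + i_rel
    # parabolic sub-sample refinement
    t_mxr = float(tw[i])
    if 0 < i < len(tw) - 1:
        denom = d2v[i - 1] - 2 * d2v[i] + d2v[i + 1]
        if denom != 0:
            delta = 0.5 * (d2v[i - 1] - d2v[i + 1]) / denom
            dt = tw[i] - tw[i - 1]
            t_mxr += float(np.clip(delta, -0.5, 0.5)) * dt
    return t_mxr - t_act


def apd_tri(apd_mxr_ms: float, apd50_ms: float) -> float:
    """Triangulation: APD_MxR - APD50, exactly."""
    return apd_mxr_ms - apd50_ms


def detect_ead(
    beat: Beat,
    fs_hz: float,
    min_amp_frac: float = 0.05,
    min_duration_ms: float = 20.0,
    smooth_window_ms: float = 21.0,
) -> bool:
    """Flag an early afterdepolarization within a captured beat.

    Between the beat peak and the 90% repolarization crossing, the
    smoothed derivative must change sign from negative to positive, and
    the subsequent re-depolarization must rise at least
    ``min_amp_frac`` of the beat amplitude above its local minimum and
    persist (stay above the local-minimum level) for at least
    ``min_duration_ms``. The smoothing window is wider here than for the
    duration metrics: EADs evolve over tens of ms, and the wider window
    suppresses noise wiggles that mimic small re-depolarizations.
    """
    if not beat.captured or beat.amplitude <= 0:
        return False
    tw, yw = beat.times_ms, beat.samples
    ys = _smooth(yw, fs_hz, smooth_window_ms)
    dv = np.gradient(ys, tw)
    # anchor at the end of the upstroke (first derivative zero after max
    # dF/dt), not the global max: a large EAD can itself be the global max
    i_up = int(np.argmax(dv))
    down = np.nonzero(dv[i_up:] <= 0)[0]
    i_peak = i_up + int(down[0]) if down.size else int(np.argmax(ys))
    level90 = beat.baseline + 0.10 * beat.amplitude
    t90 = _interp_crossing_down(tw, ys, level90, i_peak)
    i_end = len(tw) - 1 if math.isnan(t90) else int(np.searchsorted(tw, t90))

    seg = slice(i_peak, i_end + 1)
    d = dv[seg]
    sign_flip = np.nonzero((d[:-1] < 0) & (d[1:] >= 0))[0]
    for k in sign_flip:
        i_min = i_peak + k + 1
        v_min = ys[i_min]
        after = ys[i_min : i_end + 1]
        if len(after) < 2:
            continue
        # rebound ends at the next local max of the smoothed trace
        d_after = dv[i_min : i_end + 1]
        turns = np.nonzero((d_after[:-1] > 0) & (d_after[1:] <= 0))[0]
        i_rebound = i_min + (int(turns[0]) + 1 if turns.size else len(after) - 1)
        # bump height against the extrapolated falling base, so a
        # re-depolarization riding a declining plateau is not under-read
        pre = dv[max(i_peak, i_min - int(round(0.03 * fs_hz))) : i_min]
        base_slope = min(0.0, float(np.median(pre))) if pre.size else 0.0
        bump = float(
            ys[i_rebound] - v_min - base_slope * (tw[i_rebound] - tw[i_min])
        )
        if bump < min_amp_frac * beat.amplitude:
            continue
        # persistence: time spent back above the local-minimum level
        above = np.nonzero(ys[i_min:] < v_min)[0]
        t_fall = tw[i_min + above[0]] if above.size else tw[-1]
        if t_fall - tw[i_min] >= min_duration_ms:
            return True
    return False


def measure_beat(
    beat: Beat,
    fs_hz: float,
    capture_window_ms: float = 300.0,
    smooth_window_ms: float = 5.0,
    mxr_smooth_window_ms: float = 11.0,
    ead_min_amp_frac: float = 0.05,
    ead_min_duration_ms: float = 20.0,
    ead_smooth_window_ms: float = 21.0,
) -> BeatMetrics:
    """All eight per-beat metrics; non-captured beats yield NaNs."""
    if not beat.captured:
        return BeatMetrics(captured=False)
    stim_delay, rise, t_act = upstroke_metrics(
        beat, fs_hz, capture_window_ms=capture_window_ms, smooth_window_ms=smooth_window_ms
    )
    levels = apd_levels(beat, t_act)
    mxr = apd_mxr(beat, t_act, levels[50], fs_hz, smooth_window_ms=mxr_smooth_window_ms)
    tri = apd_tri(mxr, levels[50]) if not math.isnan(mxr) else math.nan
    ead = detect_ead(
        beat,
        fs_hz,
        min_amp_frac=ead_min_amp_frac,
        min_duration_ms=ead_min_duration_ms,
        smooth_window_ms=ead_smooth_window_ms,
    )
    return BeatMetrics(
        stim_delay_ms=stim_delay,
        rise_time_ms=rise,
        apd30_ms=levels[30],
        apd50_ms=levels[50],
        apd80_ms=levels[80],
        apd_mxr_ms=mxr,
        apd_tri_ms=tri,
        ead=ead,
        captured=True,
    )


def summarize_tissue(beat_metrics: list[BeatMetrics], n_stimuli: int) -> TissueMetrics:
    """Per-tissue summary: excitability, metric means and beat-to-beat SDs.

    EAD beats keep their APD values and feed the summaries. A tissue
    with no captured beats has all metric summaries unavailable (NaN);
    SDs require at least two captured beats with a defined value.
    """
    if n_stimuli < 1:
        raise ValueError("n_stimuli must be >= 1")
    captured = [bm for bm in beat_metrics if bm.captured]
    exc = 100.0 * len(captured) / n_stimuli
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = np.array(
            [getattr(bm, name) for bm in captured if not math.isnan(getattr(bm, name))]
        )
        means[name] = float(vals.mean()) if vals.size else math.nan
        sds[name] = float(vals.std(ddof=1)) if vals.size >= 2 else math.nan
    return TissueMetrics(
        excitability_pct=exc,
        beats=beat_metrics,
        means=means,
        sds=sds,
        ead_present=any(bm.ead for bm in captured),
        n_captured=len(captured),
        n_stimuli=n_stimuli,
    )


def analyze_trace(
    trace: APTrace,
    protocol: StimProtocol,
    capture_window_ms: float = 300.0,
    capture_amp_frac: float = 0.5,
    min_amplitude: float = 0.0,
    smooth_window_ms: float = 5.0,
    mxr_smooth_window_ms: float = 11.0,
    ead_min_amp_frac: float = 0.05,
    ead_min_duration_ms: float = 20.0,
) -> TissueMetrics:
    """Full per-tissue analysis: beats -> per-beat metrics -> summary."""
    beats = detect_beats(
        trace,
        protocol,
        capture_window_ms=capture_window_ms,
        capture_amp_frac=capture_amp_frac,
        min_amplitude=min_amplitude,
        smooth_window_ms=smooth_window_ms,
    )
    bms = [
        measure_beat(
            b,
            trace.frame_rate_hz,
            capture_window_ms=capture_window_ms,
            smooth_window_ms=smooth_window_ms,
            mxr_smooth_window_ms=mxr_smooth_window_ms,
            ead_min_amp_frac=ead_min_amp_frac,
            ead_min_duration_ms=ead_min_duration_ms,
        )
        for b in beats
    ]
    return summarize_tissue(bms, n_stimuli=len(beats))
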