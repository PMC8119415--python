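"""Parametric action-potential waveforms with brute-force metric oracles.

The waveform family is the product of two logistic sigmoids (upstroke and
phase-3 repolarization) and an exponential plateau decay:

    V(t) = A * s((t - t_act) / tau_up) * s((t_repol - t) / tau_repol)
             * exp(-plateau_decay * max(t - t_act, 0))            [+ EAD bump]

with ``s`` the standard logistic. The family was chosen because APD30/50/80,
APD_MxR and triangulation can be steered independently through
``t_repol``, ``tau_repol`` and ``plateau_decay``. An optional early
afterdepolarization is a Gaussian bump added during the plateau/phase-3
window.

Truth values (``WaveformTruth``) are computed on a dense time grid
(>= 10 kHz) by direct definition scan — level crossings from the upstroke
time with linear interpolation, APD_MxR from the arg-max of the second
difference in the repolarization window with parabolic refinement — and
are independent of the pipeline's measurement code in
:mod:`cardiomap.apmetrics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EADSpec",
    "WaveformParams",
    "WaveformTruth",
    "waveform_values",
    "make_ap_waveform",
]


@dataclass(frozen=True)
class EADSpec:
    """An early-afterdepolarization bump riding on the plateau/phase 3.

    Parameters
    ----------
    t_onset_ms
        Center of the bump, in ms on the waveform's time axis. Must lie
        between the AP peak and the phase-3 midpoint ``t_repol``.
    amplitude_frac
        Bump height as a fraction of the AP amplitude.
    width_ms
        Full width of the bump (the Gaussian sigma is ``width_ms / 4`` so
        that ~95% of the bump mass lies inside the stated width).
    """

    t_onset_ms: float
    amplitude_frac: float = 0.10
    width_ms: float = 60.0


@dataclass(frozen=True)
class WaveformParams:
    """Shape parameters of one synthetic action potential.

    Defaults give an APD80 of roughly 350 ms at unit amplitude, matching
    the order of magnitude seen in paced human cardiac microtissues at
    0.5 Hz.
    """

    amplitude: float = 1.0  # dimensionless dF/F
    t_activation_ms: float = 50.0
    tau_up_ms: float = 2.0  # upstroke steepness
    t_repol_ms: float = 400.0  # phase-3 midpoint
    tau_repol_ms: float = 15.0  # phase-3 steepness
    plateau_decay_per_ms: float = 0.0005
    ead: EADSpec | None = None
    sampling_rate_hz: float = 979.0
    duration_ms: float | None = None  # default: t_repol + 8 * tau_repol

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.tau_up_ms <= 0 or self.tau_repol_ms <= 0:
            raise ValueError("time constants must be > 0")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be > 0")
        if self.plateau_decay_per_ms < 0:
            raise ValueError("plateau_decay_per_ms must be >= 0")
        # upstroke must be complete well before the phase-3 midpoint
        if self.t_activation_ms + 5 * self.tau_up_ms >= self.t_repol_ms:
            raise ValueError(
                "upstroke does not complete before t_repol: require "
                "t_activation + 5*tau_up < t_repol"
            )
        if self.ead is not None:
            t_peak = self.t_activation_ms + 5 * self.tau_up_ms
            if not (t_peak < self.ead.t_onset_ms < self.t_repol_ms):
                raise ValueError(
                    "EAD onset must lie between the AP peak and t_repol"
                )
            if not (0 < self.ead.amplitude_frac < 1):
                raise ValueError("EAD amplitude_frac must be in (0, 1)")
            if self.ead.width_ms <= 0:
                raise ValueError("EAD width_ms must be > 0")

    @property
    def total_duration_ms(self) -> float:
        if self.duration_ms is not None:
            return self.duration_ms
        return self.t_repol_ms + 8.0 * self.tau_repol_ms


@dataclass(frozen=True)
class WaveformTruth:
    """Oracle metric values for a synthetic waveform (all in ms)."""

    apd30_ms: float
    apd50_ms: float
    apd80_ms: float
    apd_mxr_ms: float
    rise_time_ms: float
    t_act_ms: float
    amplitude: float
    has_ead: bool

    def __post_init__(self) -> None:
        if not (self.apd30_ms <= self.apd50_ms <= self.apd80_ms):
            raise ValueError("APD ordering violated: apd30 <= apd50 <= apd80")

    @property
    def apd_tri_ms(self) -> float:
        return self.apd_mxr_ms - self.apd50_ms


def waveform_values(params: WaveformParams, t_ms: np.ndarray) -> np.ndarray:
    """Evaluate the analytic waveform at times ``t_ms`` (ms)."""
    t = np.asarray(t_ms, dtype=float)
    up = _logistic((t - params.t_activation_ms) / params.tau_up_ms)
    down = _logistic((params.t_repol_ms - t) / params.tau_repol_ms)
    decay = np.exp(
        -params.plateau_decay_per_ms * np.maximum(t - params.t_activation_ms, 0.0)
    )
    v = params.amplitude * up * down * decay
    if params.ead is not None:
        sigma = params.ead.width_ms / 4.0
        bump = (
            params.ead.amplitude_frac
            * params.amplitude
            * np.exp(-0.5 * ((t - params.ead.t_onset_ms) / sigma) ** 2)
        )
        # the bump only exists while the cell is depolarized
        v = v + bump * down
    return v


def waveform_train_values(
    params: WaveformParams, t_ms: np.ndarray, pulse_times_ms: np.ndarray
) -> np.ndarray:
    """Evaluate a paced train: one waveform per stimulus pulse.

    The waveform's own time axis is interpreted relative to each pulse, so
    ``t_activation_ms`` acts as the stimulation delay of every beat.
    Beats superpose additively; with physiologic parameters each beat has
    decayed to ~0 before the next pulse.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.zeros_like(t)
    for pulse in np.asarray(pulse_times_ms, dtype=float):
        v += waveform_values(params, t - pulse)
    return v


def _logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _refine_argmax(
    func, t_coarse: float, dt: float, order: int, params: WaveformParams
) -> float:
    """Grid-independent sub-sample arg-max of a waveform derivative.

    Maximizes the ``order``-th derivative of the analytic waveform,
    estimated by central differences with a fixed step (independent of
    the sampling grid), inside the bracket around the coarse arg-max.
    This makes the oracle insensitive to the grid rate used to bracket.
    """
    from scipy.optimize import minimize_scalar

    h = 0.05  # ms; fixed finite-difference step

    def deriv(t: float) -> float:
        if order == 1:
            pts = np.array([t - h, t + h])
            f = func(params, pts)
            return (f[1] - f[0]) / (2 * h)
        pts = np.array([t - h, t, t + h])
        f = func(params, pts)
        return (f[0] - 2 * f[1] + f[2]) / h**2

    res = minimize_scalar(
        lambda t: -deriv(t),
        bounds=(t_coarse - dt, t_coarse + dt),
        method="bounded",
        options={"xatol": 1e-4},
    )
    return float(res.x)


def _first_downward_crossing(
    t: np.ndarray, v: np.ndarray, level: float, start_idx: int
) -> float:
    """First time after ``start_idx`` at which v falls to ``level``."""
    seg = v[start_idx:]
    below = np.nonzero(seg <= level)[0]
    if below.size == 0:
        raise ValueError(f"waveform never repolarizes to level {level!r}")
    j = below[0] + start_idx
    if j == start_idx:
        return t[j]
    # linear interpolation between the bracketing samples
    t0, t1 = t[j - 1], t[j]
    v0, v1 = v[j - 1], v[j]
    if v1 == v0:
        return t1
    return t0 + (v0 - level) / (v0 - v1) * (t1 - t0)


def _upward_crossing(t: np.ndarray, v: np.ndarray, level: float, stop_idx: int) -> float:
    """Last upward crossing of ``level`` before ``stop_idx`` (on the upstroke)."""
    seg = v[: stop_idx + 1]
    above = np.nonzero(seg >= level)[0]
    if above.size == 0:
        raise ValueError("level never reached on upstroke")
    j = above[0]
    if j == 0:
        return t[0]
    t0, t1 = t[j - 1], t[j]
    v0, v1 = v[j - 1], v[j]
    if v1 == v0:
        return t1
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def compute_truth(params: WaveformParams, oracle_rate_hz: float = 10_000.0) -> WaveformTruth:
    """Brute-force metric oracle on a dense (>= 10 kHz) grid.

    The definitions scanned here mirror the field conventions: durations
    are measured from the time of maximum dV/dt; APD_x is the first fall
    to (1 - x/100) of the amplitude; APD_MxR is the arg-max of the second
    difference restricted to the window after the APD50 crossing.
    """
    if oracle_rate_hz < 10_000.0:
        raise ValueError("oracle grid must be at least 10 kHz")
    dt = 1000.0 / oracle_rate_hz  # ms
    n = int(np.ceil(params.total_duration_ms / dt)) + 1
    t = np.arange(n) * dt
    v = waveform_values(params, t)

    dv = np.gradient(v, dt)
    i_up = int(np.argmax(dv))
    t_act = _refine_argmax(waveform_values, t[i_up], dt, order=1, params=params)

    i_peak = int(np.argmax(v))
    amp = float(v[i_peak])  # diastole is exactly 0 for this family

    apd = {}
    for level_pct in (30, 50, 80):
        level = (1.0 - level_pct / 100.0) * amp
        t_cross = _first_downward_crossing(t, v, level, i_peak)
        apd[level_pct] = t_cross - t_act

    # APD_MxR: max curvature after the APD50 crossing
    d2v = np.gradient(dv, dt)
    i50 = int(np.searchsorted(t, t_act + apd[50]))
    i_mxr = int(np.argmax(d2v[i50:])) + i50
    t_mxr = _refine_argmax(waveform_values, t[i_mxr], dt, order=2, params=params)
    apd_mxr = t_mxr - t_act

    t10 = _upward_crossing(t, v, 0.10 * amp, i_peak)
    t90 = _upward_crossing(t, v, 0.90 * amp, i_peak)
    rise = t90 - t10

    return WaveformTruth(
        apd30_ms=float(apd[30]),
        apd50_ms=float(apd[50]),
        apd80_ms=float(apd[80]),
        apd_mxr_ms=float(apd_mxr),
        rise_time_ms=float(rise),
        t_act_ms=float(t_act),
        amplitude=amp,
        has_ead=params.ead is not None,
    )


def make_ap_waveform(
    params: WaveformParams, oracle_rate_hz: float = 10_000.0
) -> tuple[np.ndarray, np.ndarray, WaveformTruth]:
    """Sample a waveform at its stated rate and compute its oracle truth.

    Returns
    -------
    t_ms : ndarray
        Sample times in ms (starting at 0).
    values : ndarray
        The waveform sampled at ``params.sampling_rate_hz``; depolarization
        positive, diastole 0.
    truth : WaveformTruth
        Brute-force metric values from the dense oracle grid.
    """
    dt = 1000.0 / params.sampling_rate_hz
    n = int(np.ceil(params.total_duration_ms / dt)) + 1
    t = np.arange(n) * dt
    v = waveform_values(params, t)
    truth = compute_truth(params, oracle_rate_hz=oracle_rate_hz)
    return t, v, truth


def random_waveform_params(
    rng: np.random.Generator,
    sampling_rate_hz: float = 979.0,
    apd_range_ms: tuple[float, float] = (100.0, 600.0),
    with_ead: bool = False,
) -> WaveformParams:
    """Draw a random but physiologic parameter set spanning an APD range.

    Used by the oracle-equivalence tests: ``t_repol`` is drawn so the
    resulting APD80 spans roughly ``apd_range_ms``.
    """
    lo, hi = apd_range_ms
    t_act = 50.0
    t_repol = t_act + rng.uniform(lo, hi)
    tau_up = rng.uniform(1.0, 4.0)
    tau_repol = rng.uniform(8.0, min(40.0, (t_repol - t_act) / 8.0))
    ead = None
    plateau_decay = rng.uniform(0.0, 0.001)
    if with_ead:
        # a distinct EAD: it must rise off a declining plateau, clear of
        # the upstroke crest (else it merges into the peak) and of the
        # steep phase-3 drop (else it only slows the descent without
        # reversing it)
        plateau_decay = rng.uniform(0.0005, 0.0015)
        width = rng.uniform(40.0, 80.0)
        t_peak = t_act + 5 * tau_up
        lo = t_peak + 1.5 * width
        hi = t_repol - 3.5 * tau_repol - width / 2.0
        if hi <= lo:
            width = 40.0
            lo = t_peak + 1.5 * width
            hi = t_repol - 3.5 * tau_repol - width / 2.0
        t_onset = rng.uniform(lo, hi) if hi > lo else (t_peak + t_repol) / 2.0
        ead = EADSpec(
            t_onset_ms=t_onset,
            amplitude_frac=rng.uniform(0.08, 0.25),
            width_ms=width,
        )
    return WaveformParams(
        amplitude=rng.uniform(0.5, 2.0),
        t_activation_ms=50.0,
        tau_up_ms=tau_up,
        t_repol_ms=t_repol,
        tau_repol_ms=tau_repol,
        plateau_decay_per_ms=plateau_decay,
        ead=ead,
        sampling_rate_hz=sampling_rate_hz,
    )
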