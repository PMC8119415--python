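"""Minimal phenomenological ventricular AP model with conductance scaling.

Implements the four-variable minimal ventricular model of Bueno-Orovio,
Cherry and Fenton (epicardial parameter set): a normalized voltage ``u``
and three gates ``v, w, s`` generate fast-inward, slow-outward and
slow-inward currents that reproduce human ventricular AP morphology and
restitution. Three dimensionless multipliers act as ion-channel-block
surrogates:

- ``g_kr_scale`` scales the high-voltage slow-outward current (the
  plateau/phase-3 repolarizing current; reduction emulates I_Kr/hERG
  block and prolongs APD),
- ``g_to_scale`` scales the low-voltage outward current (terminal
  repolarization; reduction emulates I_to-class block),
- ``g_cal_scale`` scales the slow-inward current (plateau depolarizing
  current; increase emulates enhanced I_CaL).

The model is a morphology/direction surrogate: direction and slope
properties (APD prolongation and triangulation under repolarization
block, positive restitution) are claimed, never quantitative agreement
with any particular myocyte model.

Integration is forward Euler (default 0.05 ms step), vectorized over a
population of cells so that a whole dose series integrates in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np

from cardiomap.types import APTrace, StimProtocol

__all__ = ["IonicScales", "simulate_ionic_ap", "simulate_population"]

# Epicardial parameter set of the minimal ventricular model.
P = dict(
    u_o=0.0,
    u_u=1.55,
    theta_v=0.3,
    theta_w=0.13,
    theta_vm=0.006,
    theta_o=0.006,
    tau_v1m=60.0,
    tau_v2m=1150.0,
    tau_vp=1.4506,
    tau_w1m=60.0,
    tau_w2m=15.0,
    k_wm=65.0,
    u_wm=0.03,
    tau_wp=200.0,
    tau_fi=0.11,
    tau_o1=400.0,
    tau_o2=6.0,
    tau_so1=30.0181,
    tau_so2=0.9957,
    k_so=2.0458,
    u_so=0.65,
    tau_s1=2.7342,
    tau_s2=16.0,
    k_s=2.0994,
    u_s=0.9087,
    tau_si=1.8875,
    tau_winf=0.07,
    w_infstar=0.94,
)

STIM_AMPLITUDE = 0.66  # added to du/dt during the stimulus
STIM_DURATION_MS = 2.0


@dataclass(frozen=True)
class IonicScales:
    """Conductance multipliers and pacing parameters for one simulation."""

    g_kr_scale: float = 1.0
    g_to_scale: float = 1.0
    g_cal_scale: float = 1.0
    pacing_cl_ms: float = 2000.0
    n_beats_to_steady: int = 8

    def __post_init__(self) -> None:
        for name in ("g_kr_scale", "g_to_scale", "g_cal_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pacing_cl_ms < 400:
            raise ValueError("pacing_cl_ms must be >= 400 ms")
        if self.n_beats_to_steady < 1:
            raise ValueError("n_beats_to_steady must be >= 1")


@numba.njit(cache=True)
def _integrate_kernel(
    g_kr, g_to, g_cal, dt_ms, n_steps_cycle, total_steps, record_start,
    sample_every, stim_start_ms, stim_dur_ms, stim_amp,
    u_o, u_u, theta_v, theta_w, theta_vm, theta_o,
    tau_v1m, tau_v2m, tau_vp, tau_w1m, tau_w2m, k_wm, u_wm, tau_wp,
    tau_fi, tau_o1, tau_o2, tau_so1, tau_so2, k_so, u_so,
    tau_s1, tau_s2, k_s, u_s, tau_si, tau_winf, w_infstar,
):  # pragma: no cover - exercised through simulate_population
    n_cells = g_kr.shape[0]
    n_rec = (total_steps - record_start) // sample_every
    u_rec = np.empty((n_cells, n_rec))
    u = np.zeros(n_cells)
    v = np.ones(n_cells)
    w = np.ones(n_cells)
    s = np.zeros(n_cells)
    rec_i = 0
    for step in range(total_steps):
        t_in_cycle = (step % n_steps_cycle) * dt_ms
        stim = stim_amp if stim_start_ms <= t_in_cycle < stim_start_ms + stim_dur_ms else 0.0
        for c in range(n_cells):
            uc = u[c]
            h_v = 1.0 if uc >= theta_v else 0.0
            h_w = 1.0 if uc >= theta_w else 0.0
            h_o = 1.0 if uc >= theta_o else 0.0
            h_vm = 1.0 if uc >= theta_vm else 0.0

            tau_vm = (1.0 - h_vm) * tau_v1m + h_vm * tau_v2m
            tau_wm = tau_w1m + (tau_w2m - tau_w1m) * (1.0 + np.tanh(k_wm * (uc - u_wm))) / 2.0
            tau_so = tau_so1 + (tau_so2 - tau_so1) * (1.0 + np.tanh(k_so * (uc - u_so))) / 2.0
            tau_s = (1.0 - h_w) * tau_s1 + h_w * tau_s2
            tau_o = (1.0 - h_o) * tau_o1 + h_o * tau_o2

            v_inf = 1.0 if uc < theta_vm else 0.0
            w_inf = (1.0 - h_o) * (1.0 - uc / tau_winf) + h_o * w_infstar

            j_fi = -v[c] * h_v * (uc - theta_v) * (u_u - uc) / tau_fi
            j_so = g_to[c] * (uc - u_o) * (1.0 - h_w) / tau_o + g_kr[c] * h_w / tau_so
            j_si = -g_cal[c] * h_w * w[c] * s[c] / tau_si

            u[c] = uc + dt_ms * (-(j_fi + j_so + j_si) + stim)
            v[c] = v[c] + dt_ms * ((1.0 - h_v) * (v_inf - v[c]) / tau_vm - h_v * v[c] / tau_vp)
            w[c] = w[c] + dt_ms * ((1.0 - h_w) * (w_inf - w[c]) / tau_wm - h_w * w[c] / tau_wp)
            s[c] = s[c] + dt_ms * (((1.0 + np.tanh(k_s * (uc - u_s))) / 2.0 - s[c]) / tau_s)

        if step >= record_start and (step - record_start) % sample_every == 0:
            for c in range(n_cells):
                u_rec[c, rec_i] = u[c]
            rec_i += 1
    return u_rec[:, :rec_i], rec_i


def simulate_population(
    g_kr: np.ndarray,
    g_to: np.ndarray,
    g_cal: np.ndarray,
    pacing_cl_ms: float = 2000.0,
    n_beats: int = 8,
    record_last_n_beats: int = 2,
    dt_ms: float = 0.05,
    sample_every: int = 20,
    first_pulse_ms: float = 50.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate a population of cells, one conductance triple per cell.

    Returns ``(t_ms, u, pulse_times_ms)`` where ``t_ms`` covers the last
    ``record_last_n_beats`` paced cycles (time restarts at 0), ``u`` has
    shape (n_cells, n_samples), and ``pulse_times_ms`` are the stimulus
    onsets within the recorded window.

    Raises
    ------
    RuntimeError
        If the integration produces non-finite state (non-convergent),
        with the offending cell indices in the message.
    """
    g_kr = np.atleast_1d(np.asarray(g_kr, dtype=float))
    g_to = np.broadcast_to(np.asarray(g_to, dtype=float), g_kr.shape).copy()
    g_cal = np.broadcast_to(np.asarray(g_cal, dtype=float), g_kr.shape).copy()
    n_cells = g_kr.shape[0]

    n_steps_cycle = int(round(pacing_cl_ms / dt_ms))
    total_steps = n_steps_cycle * n_beats
    record_start = n_steps_cycle * (n_beats - record_last_n_beats)

    u_rec, rec_i = _integrate_kernel(
        g_kr, g_to, g_cal, dt_ms, n_steps_cycle, total_steps, record_start,
        sample_every, first_pulse_ms, STIM_DURATION_MS, STIM_AMPLITUDE,
        P["u_o"], P["u_u"], P["theta_v"], P["theta_w"], P["theta_vm"], P["theta_o"],
        P["tau_v1m"], P["tau_v2m"], P["tau_vp"], P["tau_w1m"], P["tau_w2m"],
        P["k_wm"], P["u_wm"], P["tau_wp"],
        P["tau_fi"], P["tau_o1"], P["tau_o2"], P["tau_so1"], P["tau_so2"],
        P["k_so"], P["u_so"],
        P["tau_s1"], P["tau_s2"], P["k_s"], P["u_s"], P["tau_si"],
        P["tau_winf"], P["w_infstar"],
    )

    if not np.all(np.isfinite(u_rec)):
        bad = np.nonzero(~np.all(np.isfinite(u_rec), axis=1))[0]
        raise RuntimeError(
            f"ionic integration diverged for cells {bad.tolist()} "
            f"(dt={dt_ms} ms, CL={pacing_cl_ms} ms)"
        )

    t_rec = np.arange(rec_i) * (dt_ms * sample_every)
    pulses = np.array(
        [first_pulse_ms + k * pacing_cl_ms for k in range(record_last_n_beats)]
    )
    return t_rec, u_rec[:, :rec_i], pulses


def ionic_dose_series(
    series: dict[str, list[tuple[float, float, float]]] | None = None,
    n_tissues: int = 12,
    conductance_cv: float = 0.10,
    pacing_cl_ms: float = 2000.0,
    n_beats: int = 8,
    seed: int | None = None,
):
    """Simulate (APD_MxR, APD_tri) clouds for graded conductance-block series.

    Each series is a list of (g_kr, g_to, g_cal) dose levels; a shared
    control (1, 1, 1) is always included. Tissue-to-tissue variability is
    emulated by independent lognormal jitter (CV ``conductance_cv``) on
    every conductance — the channel-density spread seen across real
    microtissues. Default series: graded block of the plateau
    repolarizing current (hERG surrogate, 0.8/0.6/0.4), graded block of
    the low-voltage outward current (I_to surrogate), and moderate
    enhancement of the slow inward current (I_CaL surrogate,
    1.1/1.2/1.3).

    Returns a DataFrame with columns ``series``, ``dose_index``,
    ``g_kr``, ``g_to``, ``g_cal``, ``tissue`` and the per-tissue last-beat
    metrics (apd30/50/80, apd_mxr, apd_tri, all ms). The control rows
    carry series ``"control"`` and dose_index 0.
    """
    import pandas as pd

    from cardiomap import apmetrics

    if series is None:
        series = {
            "gkr_block": [(0.8, 1, 1), (0.6, 1, 1), (0.4, 1, 1)],
            "gto_block": [(1, 0.8, 1), (1, 0.6, 1), (1, 0.4, 1)],
            "gcal_increase": [(1, 1, 1.1), (1, 1, 1.2), (1, 1, 1.3)],
        }
    rng = np.random.default_rng(seed)

    conditions = [("control", 0, (1.0, 1.0, 1.0))]
    for name, doses in series.items():
        conditions += [(name, i + 1, d) for i, d in enumerate(doses)]

    # one batched integration across all conditions and tissues
    gk, gt, gc = [], [], []
    for _name, _idx, (a, b, c) in conditions:
        jit = rng.lognormal(0.0, conductance_cv, size=(n_tissues, 3))
        gk.append(a * jit[:, 0])
        gt.append(b * jit[:, 1])
        gc.append(c * jit[:, 2])
    gk, gt, gc = np.concatenate(gk), np.concatenate(gt), np.concatenate(gc)

    t, u, pulses = simulate_population(
        gk, gt, gc, pacing_cl_ms=pacing_cl_ms, n_beats=n_beats, record_last_n_beats=2
    )
    fs_hz = 1000.0 / (t[1] - t[0])
    protocol = StimProtocol(
        pulse_times_ms=tuple(pulses.tolist()),
        cycle_length_ms=pacing_cl_ms,
        recording_duration_ms=t[-1] + 1.0,
    )

    rows = []
    for j, (name, idx, _) in enumerate(conditions):
        for k in range(n_tissues):
            c = j * n_tissues + k
            trace = APTrace(samples=u[c], frame_rate_hz=fs_hz)
            beats = apmetrics.detect_beats(trace, protocol)
            m = apmetrics.measure_beat(beats[-1], fs_hz)
            rows.append(
                dict(
                    series=name,
                    dose_index=idx,
                    g_kr=gk[c],
                    g_to=gt[c],
                    g_cal=gc[c],
                    tissue=k,
                    apd30_ms=m.apd30_ms,
                    apd50_ms=m.apd50_ms,
                    apd80_ms=m.apd80_ms,
                    apd_mxr_ms=m.apd_mxr_ms,
                    apd_tri_ms=m.apd_tri_ms,
                )
            )
    return pd.DataFrame(rows)


def simulate_ionic_ap(
    scales: IonicScales, dt_ms: float = 0.05, sample_every: int = 20
):
    """Pace a single cell to steady state and measure the last beat.

    Returns ``(trace, metrics)``: an :class:`~cardiomap.types.APTrace`
    covering the last two paced cycles (in normalized voltage units,
    diastole ~ 0), and the last beat's
    :class:`~cardiomap.apmetrics.BeatMetrics` measured by the same code
    path as experimental traces.
    """
    from cardiomap import apmetrics

    t, u, pulses = simulate_population(
        np.array([scales.g_kr_scale]),
        np.array([scales.g_to_scale]),
        np.array([scales.g_cal_scale]),
        pacing_cl_ms=scales.pacing_cl_ms,
        n_beats=scales.n_beats_to_steady,
        record_last_n_beats=2,
        dt_ms=dt_ms,
        sample_every=sample_every,
    )
    fs_hz = 1000.0 / (t[1] - t[0])
    trace = APTrace(samples=u[0], frame_rate_hz=fs_hz, tissue_label=1)
    protocol = StimProtocol(
        pulse_times_ms=tuple(pulses.tolist()),
        cycle_length_ms=scales.pacing_cl_ms,
        recording_duration_ms=trace.duration_ms,
    )
    beats = apmetrics.detect_beats(trace, protocol)
    metrics = apmetrics.measure_beat(beats[-1], fs_hz)
    return trace, metrics
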