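"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MovieStack", "ActivityMap", "TissueROI", "APTrace", "StimProtocol"]


@dataclass
class MovieStack:
    """A fluorescence time-lapse stack: frames (T, H, W) in camera counts."""

    frames: np.ndarray
    frame_rate_hz: float = 979.0
    pixel_size_um: float = 18.7
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.frames.shape[0] < 2:
            raise ValueError("movie must have at least 2 frames")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(self.n_frames) * (1000.0 / self.frame_rate_hz)

    @property
    def duration_ms(self) -> float:
        return self.n_frames * 1000.0 / self.frame_rate_hz


@dataclass
class ActivityMap:
    """Per-pixel pacing-band spectral score in [0, 1]."""

    scores: np.ndarray
    pacing_freq_hz: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D map")
        if np.any(self.scores < 0) or not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite and >= 0")


@dataclass
class TissueROI:
    """One segmented microtissue region (8-connected pixel set)."""

    label: int
    mask: np.ndarray  # boolean (H, W)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or not self.mask.any():
            raise ValueError("ROI mask must be a non-empty 2-D boolean image")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return float(rr.mean()), float(cc.mean())

    @property
    def pixels(self) -> set[tuple[int, int]]:
        rr, cc = np.nonzero(self.mask)
        return set(zip(rr.tolist(), cc.tolist()))


@dataclass
class APTrace:
    """A per-tissue dF/F trace: depolarization positive, diastole ~ 0."""

    samples: np.ndarray
    frame_rate_hz: float
    tissue_label: int = 0
    n_pixels: int = 1
    t0_ms: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_ms + np.arange(len(self.samples)) * (1000.0 / self.frame_rate_hz)

    @property
    def duration_ms(self) -> float:
        return len(self.samples) * 1000.0 / self.frame_rate_hz


@dataclass(frozen=True)
class StimProtocol:
    """Pacing protocol: pulse onsets within the recording window.

    The study convention is 0.5 Hz field stimulation (2000 ms basic cycle
    length) recorded for 8-10 s, i.e. 4-5 stimuli per recording.
    """

    pulse_times_ms: tuple[float, ...]
    cycle_length_ms: float = 2000.0
    pulse_duration_ms: float = 4.0
    recording_duration_ms: float = 10000.0

    def __post_init__(self) -> None:
        if self.cycle_length_ms <= 0:
            raise ValueError("cycle_length_ms must be > 0")
        if len(self.pulse_times_ms) == 0:
            raise ValueError("protocol must contain at least one pulse")
        pulses = tuple(float(p) for p in self.pulse_times_ms)
        if any(b <= a for a, b in zip(pulses, pulses[1:])):
            raise ValueError("pulse times must be strictly increasing")
        if pulses[-1] >= self.recording_duration_ms:
            raise ValueError("pulses must lie within the recording window")

    @classmethod
    def from_cycle_length(
        cls,
        cycle_length_ms: float = 2000.0,
        first_pulse_ms: float = 500.0,
        recording_duration_ms: float = 10000.0,
        pulse_duration_ms: float = 4.0,
    ) -> "StimProtocol":
        """Derive pulse times from cycle length and first-pulse offset."""
        if cycle_length_ms <= 0:
            raise ValueError("cycle_length_ms must be > 0")
        pulses = tuple(
            np.arange(first_pulse_ms, recording_duration_ms, cycle_length_ms).tolist()
        )
        return cls(
            pulse_times_ms=pulses,
            cycle_length_ms=cycle_length_ms,
            pulse_duration_ms=pulse_duration_ms,
            recording_duration_ms=recording_duration_ms,
        )

    @property
    def n_stimuli(self) -> int:
        return len(self.pulse_times_ms)
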