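"""Deterministic readers and writers for every pipeline artifact.

Conventions: multi-page TIFF for movies with a JSON sidecar carrying
acquisition metadata; CSV for all tabular outputs (traces, beat metrics,
tissue summaries, dose tables, slope tables) with fixed column order and
fixed float formatting so identical inputs give byte-identical files;
JSON for protocols and variance components; YAML for run configuration.
Times are serialized in ms, frequencies in Hz. Every output embeds the
schema version and a hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from cardiomap import SCHEMA_VERSION
from cardiomap.types import APTrace, MovieStack, StimProtocol

__all__ = [
    "config_hash",
    "write_movie",
    "read_movie",
    "write_traces",
    "read_traces",
    "read_protocol",
    "write_protocol",
    "load_config",
]

FLOAT_FMT = "%.10g"


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(config: dict | None) -> str:
    h = config_hash(config or {})
    return f"# schema_version={SCHEMA_VERSION} config_hash={h}\n"


# --------------------------------------------------------------------------
# movies
# --------------------------------------------------------------------------


def write_movie(path, movie: MovieStack, config: dict | None = None) -> None:
    """Write frames as a multi-page TIFF plus a `.json` metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames)
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config_hash(config or {}),
        "frame_rate_hz": movie.frame_rate_hz,
        "pixel_size_um": movie.pixel_size_um,
        "t0_ms": movie.t0_ms,
        "n_frames": int(movie.n_frames),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_movie(path, sidecar_path=None) -> MovieStack:
    """Read a multi-page TIFF with its JSON sidecar.

    Accepts 8/16-bit integer and 32-bit float pages. The sidecar must
    name ``frame_rate_hz``; all pages must share one shape.
    """
    path = Path(path)
    sidecar_path = Path(sidecar_path) if sidecar_path else path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    if "frame_rate_hz" not in meta:
        raise ValueError("sidecar is missing required field 'frame_rate_hz'")

    frames = tifffile.imread(path)
    if frames.ndim == 2:
        raise ValueError("movie must have at least 2 pages")
    if frames.ndim != 3:
        raise ValueError(f"unexpected page shapes: stack has ndim={frames.ndim}")
    if frames.dtype not in (np.uint8, np.uint16, np.int16, np.float32, np.float64):
        raise ValueError(f"unsupported pixel type {frames.dtype}")
    return MovieStack(
        frames=frames,
        frame_rate_hz=float(meta["frame_rate_hz"]),
        pixel_size_um=float(meta.get("pixel_size_um", 18.7)),
        t0_ms=float(meta.get("t0_ms", 0.0)),
    )


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------


def write_traces(path, traces: list[APTrace], config: dict | None = None) -> None:
    """Write traces as CSV: time_ms plus one column per tissue."""
    if not traces:
        raise ValueError("no traces to write")
    labels = [t.tissue_label for t in traces]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tissue labels")
    df = pd.DataFrame({"time_ms": traces[0].times_ms})
    for tr in traces:
        if len(tr.samples) != len(df):
            raise ValueError("traces have unequal lengths")
        df[f"tissue_{tr.tissue_label}"] = tr.samples
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_traces(path) -> list[APTrace]:
    """Read a trace CSV back into APTrace objects.

    The time column must be strictly increasing; duplicate tissue
    columns are rejected. An empty table returns an empty list with a
    warning.
    """
    df = pd.read_csv(path, comment="#")
    if "time_ms" not in df.columns:
        raise ValueError("trace CSV must have a 'time_ms' column")
    cols = [c for c in df.columns if c != "time_ms"]
    if len(set(cols)) != len(cols):
        raise ValueError("duplicate tissue columns")
    if len(df) == 0 or not cols:
        warnings.warn("empty trace table", stacklevel=2)
        return []
    t = df["time_ms"].to_numpy()
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time_ms must be strictly increasing")
    fs = 1000.0 / float(np.median(dt))
    out = []
    for c in cols:
        label = int(c.split("_")[-1]) if c.split("_")[-1].isdigit() else 0
        out.append(
            APTrace(
                samples=df[c].to_numpy(),
                frame_rate_hz=fs,
                tissue_label=label,
                t0_ms=float(t[0]),
            )
        )
    return out


# --------------------------------------------------------------------------
# protocol and config
# --------------------------------------------------------------------------


def read_protocol(path) -> StimProtocol:
    """Read a stimulation protocol from JSON.

    Either an explicit ``pulse_times_ms`` list (which wins when present)
    or ``cycle_length_ms`` + ``first_pulse_ms`` from which the pulse
    train is derived across ``recording_duration_ms``.
    """
    meta = json.loads(Path(path).read_text())
    cl = float(meta.get("cycle_length_ms", 2000.0))
    rec = float(meta.get("recording_duration_ms", 10000.0))
    dur = float(meta.get("pulse_duration_ms", 4.0))
    if "pulse_times_ms" in meta:
        return StimProtocol(
            pulse_times_ms=tuple(float(p) for p in meta["pulse_times_ms"]),
            cycle_length_ms=cl,
            pulse_duration_ms=dur,
            recording_duration_ms=rec,
        )
    first = float(meta.get("first_pulse_ms", 500.0))
    return StimProtocol.from_cycle_length(
        cycle_length_ms=cl,
        first_pulse_ms=first,
        recording_duration_ms=rec,
        pulse_duration_ms=dur,
    )


def write_protocol(path, protocol: StimProtocol) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "cycle_length_ms": protocol.cycle_length_ms,
        "pulse_duration_ms": protocol.pulse_duration_ms,
        "recording_duration_ms": protocol.recording_duration_ms,
        "pulse_times_ms": list(protocol.pulse_times_ms),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


KNOWN_CONFIG_KEYS = {
    "pacing_freq_hz",
    "min_pixels",
    "threshold",
    "dye_polarity",
    "capture_window_ms",
    "capture_amp_frac",
    "min_amplitude",
    "smooth_window_ms",
    "mxr_smooth_window_ms",
    "ead_min_amp_frac",
    "ead_min_duration_ms",
    "seed",
}


def load_config(path) -> dict:
    """Load a YAML run configuration; unknown keys are rejected."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def write_table(path, df: pd.DataFrame, config: dict | None = None) -> None:
    """Write any tabular result deterministically with the standard header."""
    with open(Path(path), "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
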