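import numpy as np
import pytest

from cardiomap.synthetic import SceneSpec, TissueSpec, WaveformParams, render_movie
from cardiomap.types import StimProtocol


@pytest.fixture(scope="session")
def protocol_8s() -> StimProtocol:
    """0.5 Hz pacing over an 8 s recording: pulses at 500..6500 ms."""
    return StimProtocol.from_cycle_length(
        cycle_length_ms=2000.0, first_pulse_ms=500.0, recording_duration_ms=8000.0
    )


@pytest.fixture(scope="session")
def four_tissue_scene(protocol_8s) -> SceneSpec:
    """Four ~170 px microtissues paced at 0.5 Hz, SNR 10."""
    wf = WaveformParams()
    tissues = tuple(
        TissueSpec(center=c, radius_px=7.4, waveform=wf)
        for c in [(16.0, 16.0), (16.0, 48.0), (48.0, 16.0), (48.0, 48.0)]
    )
    return SceneSpec(
        tissues=tissues,
        baseline_intensity=1000.0,
        noise_sd=100.0,
        n_frames=7832,
        pulse_times_ms=tuple(protocol_8s.pulse_times_ms),
    )


@pytest.fixture(scope="session")
def four_tissue_movie(four_tissue_scene):
    return render_movie(four_tissue_scene, seed=11)
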