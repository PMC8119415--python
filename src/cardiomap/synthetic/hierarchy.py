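"""Nested APD datasets with known variance structure.

Emulates the replication hierarchy of a microtissue study: stem-cell
differentiation batches, agarose molds within a batch, microtissues
within a mold, and repeated paced beats within a microtissue. Each level
contributes an independent normal random effect:

    APD(b, m, t, k) = mu + B_b + M_bm + T_bmt + eps_bmtk

Defaults are the component magnitudes and nesting sizes of the
cardiomyocyte + fibroblast microtissue configuration studied at 0.5 Hz
pacing: beat / tissue / mold / batch SDs of 6.4 / 36.1 / 31.8 / 19.3 ms
with 4 batches, 3 molds per batch, 35 tissues per mold and 5 beats per
tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VarianceSpec", "sample_hierarchical_apds"]


@dataclass(frozen=True)
class VarianceSpec:
    """Variance structure and nesting sizes of a hierarchical APD dataset."""

    grand_mean_apd_ms: float = 400.0
    sd_beat_ms: float = 6.4
    sd_tissue_ms: float = 36.1
    sd_mold_ms: float = 31.8
    sd_batch_ms: float = 19.3
    n_batches: int = 4
    n_molds_per_batch: int = 3
    n_tissues_per_mold: int = 35
    n_beats_per_tissue: int = 5

    def __post_init__(self) -> None:
        for name in ("sd_beat_ms", "sd_tissue_ms", "sd_mold_ms", "sd_batch_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "n_batches",
            "n_molds_per_batch",
            "n_tissues_per_mold",
            "n_beats_per_tissue",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def sample_hierarchical_apds(spec: VarianceSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw one dataset from the nested random-effects model.

    Returns a long-form frame with columns ``batch``, ``mold``, ``tissue``,
    ``beat`` (integer ids, unique within their parent) and ``apd_ms``.
    Reproducible: the same spec and seed give an identical frame.
    """
    rng = np.random.default_rng(seed)
    nb, nm, nt, nk = (
        spec.n_batches,
        spec.n_molds_per_batch,
        spec.n_tissues_per_mold,
        spec.n_beats_per_tissue,
    )
    batch_eff = rng.normal(0.0, spec.sd_batch_ms, size=nb)
    mold_eff = rng.normal(0.0, spec.sd_mold_ms, size=(nb, nm))
    tissue_eff = rng.normal(0.0, spec.sd_tissue_ms, size=(nb, nm, nt))
    beat_eff = rng.normal(0.0, spec.sd_beat_ms, size=(nb, nm, nt, nk))

    apd = (
        spec.grand_mean_apd_ms
        + batch_eff[:, None, None, None]
        + mold_eff[:, :, None, None]
        + tissue_eff[:, :, :, None]
        + beat_eff
    )

    b, m, t, k = np.meshgrid(
        np.arange(nb), np.arange(nm), np.arange(nt), np.arange(nk), indexing="ij"
    )
    return pd.DataFrame(
        {
            "batch": b.ravel(),
            "mold": m.ravel(),
            "tissue": t.ravel(),
            "beat": k.ravel(),
            "apd_ms": apd.ravel(),
        }
    )
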