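"""Rendered figure outputs: heatmaps for shift and signature maps, labels."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from cardiomap.stats import ShiftMap, SignatureMap

__all__ = ["render_shift_map", "render_signature_map", "save_label_image"]


def render_shift_map(shift: ShiftMap, path, vmax: float = 4.0) -> None:
    """Heatmap of per-tissue sigma shifts.

    Warm colors mark positive shifts, cool negative; unavailable cells
    (non-excitable tissues) render black.
    """
    vals = shift.values.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(max(4, vals.shape[1] * 0.35), max(3, vals.shape[0] * 0.25)))
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("black")
    im = ax.imshow(np.ma.masked_invalid(vals), cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(vals.shape[1]))
    ax.set_xticklabels(
        [f"{m}\n{d}" for m, d in shift.values.columns], fontsize=5, rotation=90
    )
    ax.set_ylabel("tissue")
    fig.colorbar(im, ax=ax, label="shift (control SD units)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_signature_map(sig: SignatureMap, path, vmax: float = 3.0) -> None:
    """Metric x dose signature heatmap; significant cells outlined."""
    vals = sig.values.to_numpy(dtype=float)
    fig, ax = plt.subplots(figsize=(max(4, vals.shape[1] * 0.7), max(3, vals.shape[0] * 0.45)))
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("0.7")
    im = ax.imshow(np.ma.masked_invalid(vals), cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
    sigmask = sig.significant.to_numpy(dtype=bool)
    for (i, j), flag in np.ndenumerate(sigmask):
        if flag:
            ax.text(j, i, "*", ha="center", va="center", fontsize=10)
    ax.set_xticks(range(vals.shape[1]))
    ax.set_xticklabels([str(d) for d in sig.values.columns], rotation=45, fontsize=7)
    ax.set_yticks(range(vals.shape[0]))
    ax.set_yticklabels(list(sig.values.index), fontsize=7)
    fig.colorbar(im, ax=ax, label="mean difference / control SD")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_label_image(labels: np.ndarray, path) -> None:
    """Save a ROI label image as PNG (tab10 colors, background black)."""
    fig, ax = plt.subplots(figsize=(4, 4))
    cmap = plt.get_cmap("tab10").copy()
    masked = np.ma.masked_equal(labels, 0)
    cmap.set_bad("black")
    ax.imshow(masked, cmap=cmap, interpolation="nearest")
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
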