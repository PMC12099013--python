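"""Optional QC overlays. Never required for the numeric path."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .metrics import SliceLandmarks

__all__ = ["plot_landmarks"]

_SEGMENTS = [("a", "a_prime"), ("b", "b_prime"), ("c", "c_prime")]


def plot_landmarks(
    slice2d: np.ndarray,
    landmarks: SliceLandmarks,
    spacing,
    origin=(0.0, 0.0),
    out_path: str | Path | None = None,
    title: str | None = None,
):
    """Render a slice with the six landmarks and thickness segments.

    Returns the matplotlib figure; saves a PNG when ``out_path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spacing = np.asarray(spacing, float)
    origin = np.asarray(origin, float)
    mask = np.asarray(slice2d) > 0.5
    ny, nz = mask.shape
    extent = [
        origin[0] - spacing[0] / 2,
        origin[0] + (ny - 0.5) * spacing[0],
        origin[1] - spacing[1] / 2,
        origin[1] + (nz - 0.5) * spacing[1],
    ]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.imshow(mask.T, origin="lower", extent=extent, cmap="gray")
    for p, q in _SEGMENTS:
        pp, qq = getattr(landmarks, p), getattr(landmarks, q)
        ax.plot([pp[0], qq[0]], [pp[1], qq[1]], "r-", lw=1.5)
    a, b = landmarks.a, landmarks.b
    ax.plot([a[0], b[0]], [a[1], b[1]], "c--", lw=1.0)
    for name in ("a", "b", "c", "a_prime", "b_prime", "c_prime"):
        pt = getattr(landmarks, name)
        ax.plot(pt[0], pt[1], "yo", ms=4)
        ax.annotate(name.replace("_prime", "'"), pt, color="y", fontsize=8)
    ax.set_xlabel("Y (anterior, mm)")
    ax.set_ylabel("Z (superior, mm)")
    if title:
        ax.set_title(title)
    if out_path is not None:
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
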