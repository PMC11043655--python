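"""Presentation helpers: comodulogram heat maps and polar phase plots."""

from __future__ import annotations

import numpy as np

from .comodulogram import GridSpec, PacGrid

__all__ = ["plot_comodulogram", "plot_phase_polar"]


def plot_comodulogram(grid: PacGrid, ax=None, **imshow_kwargs):
    """Heat map of M_norm over the phase x amplitude grid.

    Phase frequency runs along x, amplitude frequency along y, matching the
    usual comodulogram orientation.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    spec: GridSpec = grid.spec
    extent = (
        spec.phase_edges[0],
        spec.phase_edges[-1],
        spec.amp_edges[0],
        spec.amp_edges[-1],
    )
    kwargs = {"origin": "lower", "aspect": "auto", "extent": extent, "cmap": "viridis"}
    kwargs.update(imshow_kwargs)
    im = ax.imshow(grid.m_norm.T, **kwargs)
    ax.set_xlabel("phase frequency (Hz)")
    ax.set_ylabel("amplitude frequency (Hz)")
    title = " ".join(s for s in (grid.subject_id, grid.region) if s)
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, label="M_norm")
    return ax


def plot_phase_polar(angles_deg, ax=None, mean_angle_deg: float | None = None, **kwargs):
    """Polar scatter of per-subject preferred phase angles, with optional mean ray."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    angles = np.radians(np.asarray(angles_deg, dtype=float))
    kwargs.setdefault("s", 30)
    ax.scatter(angles, np.ones_like(angles), **kwargs)
    if mean_angle_deg is not None:
        ax.plot(
            [np.radians(mean_angle_deg)] * 2, [0, 1.1], linestyle="--", linewidth=2
        )
    ax.set_yticks([])
    return ax
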