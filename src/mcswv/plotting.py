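"""Display helpers (pseudocolor rendering).  Display-only: nothing here
feeds back into analysis."""

from __future__ import annotations

import numpy as np

from .extraction import ColorPlot


def render_pseudocolor(
    plot: ColorPlot,
    ax=None,
    orientation: str = "phase-rows",
    cmap: str = "RdBu_r",
    vlim: float | None = None,
):
    """Render a ColorPlot as a pseudocolor image.

    ``orientation="phase-rows"`` shows the stored layout (anodic block on
    top, staircase sweep on x); ``"sweep-rows"`` transposes, putting the
    staircase sweep on y for the alternative display convention.  Returns
    the matplotlib AxesImage.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    img = plot.current
    if orientation == "sweep-rows":
        img = img.T
    elif orientation != "phase-rows":
        raise ValueError("orientation must be 'phase-rows' or 'sweep-rows'")
    if vlim is None:
        vlim = float(np.abs(img).max()) or 1.0
    im = ax.imshow(img, cmap=cmap, vmin=-vlim, vmax=vlim, aspect="auto")
    ax.set_xlabel("staircase step" if orientation == "phase-rows" else "sample")
    ax.set_ylabel("sample" if orientation == "phase-rows" else "staircase step")
    label = "filtered" if plot.filtered else "raw"
    ax.set_title(f"scan {plot.scan_index} ({label})")
    return im
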