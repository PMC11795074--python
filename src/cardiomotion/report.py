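"""AHA 17-segment bull's-eye polar maps.

Standard layout: three rings of 6 (basal, outer), 6 (mid) and 4 (apical)
sectors around a central cap (segment 17).  Anterior is at the top, the
septum on the left, angles increase counter-clockwise.  Rendering goes
through the Agg canvas directly (no pyplot state), so identical inputs give
identical image bytes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from matplotlib import colormaps
from matplotlib.backends.backend_agg import FigureCanvasAgg
from matplotlib.cm import ScalarMappable
from matplotlib.colors import Normalize
from matplotlib.figure import Figure
from matplotlib.patches import Circle, Wedge

__all__ = ["segment_sector", "bullseye_map"]

_RINGS = {"basal": (0.75, 1.0), "mid": (0.5, 0.75), "apical": (0.25, 0.5), "cap": (0.0, 0.25)}


def segment_sector(segment: int) -> tuple[float, float, float, float]:
    """(r_inner, r_outer, theta1_deg, theta2_deg) of one segment's sector.

    Display angles are counter-clockwise from the positive x-axis; segments 1
    (basal anterior) and 13 (apical anterior) are centered at the top (90
    degrees), so basal/mid sectors start at 60 degrees and apical sectors at
    45 degrees.
    """
    if not 1 <= segment <= 17:
        raise ValueError(f"segment must be 1..17, got {segment}")
    if segment == 17:
        r0, r1 = _RINGS["cap"]
        return r0, r1, 0.0, 360.0
    if segment <= 6:
        ring, start, span, index = "basal", 60.0, 60.0, segment - 1
    elif segment <= 12:
        ring, start, span, index = "mid", 60.0, 60.0, segment - 7
    else:
        ring, start, span, index = "apical", 45.0, 90.0, segment - 13
    r0, r1 = _RINGS[ring]
    theta1 = start + index * span
    return r0, r1, theta1, theta1 + span


def bullseye_map(
    values,
    path: Path | str | None = None,
    title: str | None = None,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
    ctv_segments: tuple[int, ...] = (),
    icd_segment: int | None = None,
    show_numbers: bool = True,
    colorbar_label: str | None = None,
) -> Figure:
    """Render a value-colored 17-segment bull's-eye map.

    ``ctv_segments`` get a thick orange border (CTV location), and
    ``icd_segment`` a red dot (ICD lead tip location).  Returns the figure;
    writes PNG/SVG when ``path`` is given.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.shape != (17,):
        raise ValueError(f"expected 17 segment values, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError("segment values must be finite")

    norm = Normalize(
        vmin=float(values.min()) if vmin is None else vmin,
        vmax=float(values.max()) if vmax is None else vmax,
    )
    if norm.vmin == norm.vmax:  # uniform map: avoid a degenerate colour scale
        norm = Normalize(norm.vmin - 0.5, norm.vmax + 0.5)
    colormap = colormaps[cmap]

    fig = Figure(figsize=(5.2, 4.6))
    FigureCanvasAgg(fig)
    ax = fig.add_axes([0.02, 0.02, 0.78, 0.88])
    ax.set_aspect("equal")
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.axis("off")

    for seg in range(1, 18):
        r0, r1, t1, t2 = segment_sector(seg)
        face = colormap(norm(values[seg - 1]))
        if seg == 17:
            patch = Circle((0, 0), r1, facecolor=face, edgecolor="black", linewidth=0.8)
        else:
            patch = Wedge((0, 0), r1, t1, t2, width=r1 - r0, facecolor=face,
                          edgecolor="black", linewidth=0.8)
        ax.add_patch(patch)
        mid_t = np.deg2rad(0.5 * (t1 + t2))
        mid_r = 0.5 * (r0 + r1) if seg != 17 else 0.0
        if show_numbers:
            ax.text(mid_r * np.cos(mid_t), mid_r * np.sin(mid_t), str(seg),
                    ha="center", va="center", fontsize=8, color="white",
                    path_effects=None)
        if icd_segment == seg:
            ax.plot(mid_r * np.cos(mid_t) + 0.08, mid_r * np.sin(mid_t) + 0.08,
                    "o", color="red", markersize=8, zorder=5)

    for seg in ctv_segments:
        r0, r1, t1, t2 = segment_sector(int(seg))
        if seg == 17:
            outline = Circle((0, 0), r1, facecolor="none", edgecolor="darkorange",
                             linewidth=2.5, zorder=4)
        else:
            outline = Wedge((0, 0), r1, t1, t2, width=r1 - r0, facecolor="none",
                            edgecolor="darkorange", linewidth=2.5, zorder=4)
        ax.add_patch(outline)

    if title:
        ax.set_title(title)
    cax = fig.add_axes([0.84, 0.15, 0.04, 0.65])
    cbar = fig.colorbar(ScalarMappable(norm=norm, cmap=colormap), cax=cax)
    if colorbar_label:
        cbar.set_label(colorbar_label)

    if path is not None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        fig.savefig(path, dpi=150, metadata={"Software": "cardiomotion"} if path.suffix == ".png" else None)
    return fig
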