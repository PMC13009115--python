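"""Bullseye (polar segmental) displays of activation times and delays."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Wedge

from ewimap.compare import SegmentBullseye

#: ring radii per level: apical inner, basal outer
_LEVEL_RING = {"apical": (0.2, 0.5), "mid": (0.5, 0.75), "basal": (0.75, 1.0)}


def plot_bullseye(bullseye: SegmentBullseye, path=None, title: str | None = None, cmap="viridis"):
    """Render a 24-segment bullseye: LV on the left disc, RV on the right.

    Segments are wedges grouped by level ring; uncovered (masked) segments
    are hatched grey.
    """
    model = bullseye.model
    vals = bullseye.values
    finite = np.isfinite(vals)
    vmin = float(np.nanmin(vals)) if finite.any() else 0.0
    vmax = float(np.nanmax(vals)) if finite.any() else 1.0
    norm = plt.Normalize(vmin, vmax if vmax > vmin else vmin + 1)
    cm = plt.get_cmap(cmap)

    fig, axes = plt.subplots(1, 2, figsize=(9, 4.5))
    for ax, chamber in zip(axes, ("LV", "RV")):
        segs = [s for s in model if s.chamber == chamber]
        by_level: dict[str, list] = {}
        for s in segs:
            by_level.setdefault(s.level, []).append(s)
        for level, group in by_level.items():
            r0, r1 = _LEVEL_RING[level]
            step = 360.0 / len(group)
            for i, s in enumerate(group):
                a0 = 90.0 - (i + 1) * step
                if np.isfinite(vals[s.segment_id]):
                    face = cm(norm(vals[s.segment_id]))
                    hatch = None
                else:
                    face, hatch = "0.85", "//"
                ax.add_patch(Wedge((0, 0), r1, a0, a0 + step, width=r1 - r0,
                                   facecolor=face, edgecolor="k", hatch=hatch, lw=0.5))
        ax.set_xlim(-1.05, 1.05)
        ax.set_ylim(-1.05, 1.05)
        ax.set_aspect("equal")
        ax.axis("off")
        ax.set_title(chamber)
    sm = plt.cm.ScalarMappable(norm=norm, cmap=cm)
    fig.colorbar(sm, ax=axes, shrink=0.8, label=f"{bullseye.modality} activation time (ms)")
    if title:
        fig.suptitle(title)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
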