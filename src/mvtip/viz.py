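"""QC renderings: RIS maps and segmentation overlays."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .segmentation import SegmentationMap, ZONE_CODES

__all__ = ["save_ris_png", "save_overlay_png"]

#: zone display colors loosely following the published segmented maps
_ZONE_COLORS = {
    "OutBG": (0, 0, 0),
    "InBG": (0.15, 0.15, 0.15),
    "CB": (1.0, 0.55, 0.0),
    "MVcol": (0.0, 0.8, 0.8),
    "MVtip": (1.0, 1.0, 0.0),
    "JunctionExcluded": (0.5, 0.5, 0.5),
}


def save_ris_png(path, ris: np.ndarray) -> None:
    """Render a RIS map with the -1..+1 color convention (yellow=-1, blue=+1)."""
    fig, ax = plt.subplots(figsize=(5, 5), dpi=120)
    im = ax.imshow(ris, cmap="viridis_r", vmin=-1, vmax=1)
    fig.colorbar(im, ax=ax, label="RIS")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def save_overlay_png(path, segmap: SegmentationMap) -> None:
    """Zone map with accepted tip positions marked."""
    rgb = np.zeros((*segmap.labels.shape, 3))
    for zone, code in ZONE_CODES.items():
        rgb[segmap.labels == code] = _ZONE_COLORS[zone]
    fig, ax = plt.subplots(figsize=(5, 5), dpi=120)
    ax.imshow(rgb)
    px = segmap.pixel_size_nm
    for x, y in segmap.tips_nm:
        ax.plot(x / px, y / px, "r+", markersize=6)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
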