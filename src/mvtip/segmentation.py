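"""Microvilli-tip segmentation of two-channel super-resolution images.

The pipeline follows the original area-segmentation procedure:

1. ``compute_outbg`` — outside-cell background from per-channel multi-Otsu
   masks plus an adaptive local threshold on the channel sum; the cell is
   the largest 8-connected component, everything else is OutBG.
2. ``compute_inbg`` — the low-signal lumen/nucleus region strictly inside
   the cell, refined with a morphological geodesic active contour
   (25 iterations, edge stopping).
3. ``compute_segbw`` — per-channel global Otsu union minus both backgrounds:
   the entire-cell analysis mask (SegBW).
4. ``detect_tips`` — convex-hull tip detection on the microvilli mask.
5. ``measure_mv_length`` / ``filter_tips`` — MV length from the tip to the
   inner cell boundary; tips with length outside [50 nm, 1.5 um] or closer
   than 50 nm to a longer MV's tip are discarded.
6. ``assign_areas`` — MV-tip (<150 nm from a tip) / MV-column / cell-body
   zoning with 75 nm junction bands excluded.

All nm thresholds are converted to pixels by rounding to the nearest
integer at the image's pixel size (12.5 nm by default, i.e. 50 nm
acquisition pixels corrected for 4x expansion, where 24 px = 300 nm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import filters, measure, morphology, segmentation as sks

from .image import CellImage

__all__ = [
    "ZONE_CODES",
    "SegmentationMap",
    "compute_outbg",
    "compute_inbg",
    "compute_segbw",
    "split_mv_cb",
    "detect_tips",
    "measure_mv_length",
    "filter_tips",
    "assign_areas",
    "segment_cell",
]

#: uint8 codes for the zone label raster
ZONE_CODES = {
    "OutBG": 0,
    "InBG": 1,
    "CB": 2,
    "MVcol": 3,
    "MVtip": 4,
    "JunctionExcluded": 5,
}


@dataclass
class SegmentationMap:
    """Zone labels, accepted tips, MV lengths, and the intermediate masks."""

    labels: np.ndarray  # uint8 raster of ZONE_CODES
    tips_nm: list[tuple[float, float]]  # accepted tip (x, y), nm, subpixel
    mv_lengths_nm: list[float]
    masks: dict[str, np.ndarray]  # OutBG, InBG, SegBW, MV-BW, CB-BW, TipBW
    pixel_size_nm: float

    def zone_mask(self, zone: str) -> np.ndarray:
        return self.labels == ZONE_CODES[zone]


def _px(nm: float, pixel_size_nm: float) -> int:
    """Convert an nm threshold to whole pixels (nearest integer, min 1)."""
    return max(int(round(nm / pixel_size_nm)), 1)


def _odd_px(nm: float, pixel_size_nm: float) -> int:
    """Nearest odd pixel width for a structuring element of physical size ``nm``."""
    return 2 * int(round((nm / pixel_size_nm - 1) / 2)) + 1


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab = measure.label(mask, connectivity=2)
    if lab.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def _first_multiotsu(channel: np.ndarray) -> float:
    """Lower level of a 2-level multi-Otsu threshold, with degenerate fallbacks."""
    vals = np.unique(channel)
    if len(vals) < 2:
        return float(vals[0])
    if len(vals) < 4:
        return float(filters.threshold_otsu(channel))
    try:
        return float(filters.threshold_multiotsu(channel, classes=3)[0])
    except ValueError:
        return float(filters.threshold_otsu(channel))


def compute_outbg(image: CellImage) -> np.ndarray:
    """Outside-cell background mask.

    Per-channel masks at the first multi-Otsu level are combined with an
    adaptive local-mean threshold (maximum sensitivity) of the channel sum;
    holes are filled and the complement of the largest 8-connected
    component is returned as OutBG.
    """
    if len(image.channels) < 2:
        raise ValueError("compute_outbg needs >=2 channels")
    stack = image.stack()
    if not np.any(stack):
        raise ValueError("no foreground")
    union = np.zeros(image.shape, dtype=bool)
    for ch in image.channels.values():
        union |= ch > _first_multiotsu(ch)
    s = stack.sum(axis=0)
    block = max(min(image.shape) // 8, 3)
    if block % 2 == 0:
        block += 1
    local = filters.threshold_local(s, block_size=block, method="gaussian")
    union |= s > local
    union = ndi.binary_fill_holes(union)
    cell = _largest_component(union)
    if not cell.any():
        raise ValueError("no foreground")
    return ~cell


def compute_inbg(
    image: CellImage, outbg: np.ndarray, iterations: int = 25
) -> np.ndarray:
    """Inside-cell background (lumen/nucleus): one region strictly inside the cell.

    A seed is taken from the largest low-intensity component that does not
    touch the cell boundary, grown with a morphological geodesic active
    contour (edge stopping, ``iterations`` steps) to the inner membrane
    edge, then dilated by a 5 px disk and hole-filled. If no interior seed
    exists or the contour escapes the cell, the fallback is an erosion of
    the cell mask by a 24 px disk (with a warning).
    """
    cell = ~outbg
    s = image.stack().sum(axis=0)
    interior = morphology.erosion(cell, morphology.disk(3))

    def _fallback() -> np.ndarray:
        warnings.warn("interior contour collapsed; using eroded-cell fallback")
        return morphology.erosion(cell, morphology.disk(24))

    if not interior.any():
        return _fallback()
    s_sm = ndi.gaussian_filter(s, 1.0)
    vals = s_sm[interior]
    if np.ptp(vals) == 0:
        return _fallback()
    # first multi-Otsu level: separates the dark lumen from the membrane
    # even when a third, much brighter class (MV tips) dominates the contrast
    dark_raw = interior & (s_sm < _first_multiotsu(vals))
    # open to cut thin dark corridors (e.g. the unstained MV interiors) and
    # keep clear of the cell boundary so the seed is strictly interior
    dark = morphology.opening(dark_raw, morphology.disk(4))
    rim = cell & ~interior
    dark &= ~morphology.dilation(rim, morphology.disk(4))
    seed = _largest_component(dark)
    if not seed.any():
        return _fallback()

    smax = s.max()
    g = sks.inverse_gaussian_gradient(s / smax if smax > 0 else s)
    ls = sks.morphological_geodesic_active_contour(
        g, num_iter=iterations, init_level_set=seed, smoothing=1, balloon=1,
        threshold="auto",
    ).astype(bool)
    # the lumen is low-signal by definition: forbid the contour from
    # crossing the bright membrane, then drop corridor fingers
    ls = morphology.opening(ls & dark_raw, morphology.disk(4))
    if not ls.any() or ls.sum() > 0.95 * cell.sum():
        ls = seed
    inbg = morphology.dilation(_largest_component(ls), morphology.disk(5))
    # the dilation must not swallow the bright membrane itself
    inbg &= s_sm < _first_multiotsu(vals)
    inbg = ndi.binary_fill_holes(inbg) & cell
    return _largest_component(inbg)


def compute_segbw(
    image: CellImage, outbg: np.ndarray, inbg: np.ndarray
) -> np.ndarray:
    """Entire-cell analysis mask: per-channel global Otsu union minus backgrounds."""
    if np.any(outbg & inbg):
        raise ValueError("OutBG and InBG overlap")
    union = np.zeros(image.shape, dtype=bool)
    for ch in image.channels.values():
        if np.ptp(ch) == 0:
            continue
        union |= ch > filters.threshold_otsu(ch)
    return union & ~outbg & ~inbg


def split_mv_cb(
    segbw: np.ndarray,
    inbg: np.ndarray,
    pixel_size_nm: float,
    min_component_px: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clean SegBW and split it into microvilli (MV-BW) and cell-body (CB-BW) masks.

    SegBW components are bridged with a 62.5 nm (5 px) disk closing,
    components below ``min_component_px`` (default 2000 px at 12.5 nm/px,
    scaled by area for other pixel sizes: disconnected debris) are dropped,
    and CB-BW is the SegBW overlap with the 300 nm (24 px) dilation of
    InBG; the rest is MV-BW. Returns (cleaned SegBW, MV-BW, CB-BW).
    """
    if min_component_px is None:
        min_component_px = int(round(2000 * (12.5 / pixel_size_nm) ** 2))
    closed = morphology.closing(segbw, morphology.disk(_px(62.5, pixel_size_nm)))
    cleaned = morphology.remove_small_objects(
        closed, max_size=min_component_px - 1, connectivity=2
    )
    cb_zone = morphology.dilation(
        inbg, morphology.disk(_px(300.0, pixel_size_nm))
    )
    cbbw = cleaned & cb_zone
    mvbw = cleaned & ~cb_zone
    return cleaned, mvbw, cbbw


def detect_tips(
    segbw: np.ndarray,
    inbg: np.ndarray,
    pixel_size_nm: float,
    min_component_px: int = 2000,
) -> tuple[list[tuple[float, float]], dict[str, np.ndarray]]:
    """Convex-hull candidate tip detection.

    The MV mask is closed (10 px disk) and eroded (5 px square); the convex
    hull of the result is eroded (5 px square) and MV pixels falling outside
    the eroded hull form TipBW. TipBW is dilated (3 px square), labelled
    with 8-connectivity, and each candidate tip is the mean (x, y) of the
    label's overlap with the original TipBW, in nm.

    Returns (candidates, masks) where masks holds SegBW/MV-BW/CB-BW/TipBW.
    """
    if not segbw.any():
        raise ValueError("SegBW is empty")
    cleaned, mvbw, cbbw = split_mv_cb(segbw, inbg, pixel_size_nm, min_component_px)
    masks = {"SegBW": cleaned, "MV-BW": mvbw, "CB-BW": cbbw}
    sq5 = _odd_px(62.5, pixel_size_nm)  # 5 px square at 12.5 nm/px
    sq3 = _odd_px(37.5, pixel_size_nm)  # 3 px square at 12.5 nm/px
    mv2 = morphology.closing(mvbw, morphology.disk(_px(125.0, pixel_size_nm)))
    mv2 = morphology.erosion(mv2, morphology.footprint_rectangle((sq5, sq5)))
    tipbw = np.zeros_like(segbw)
    candidates: list[tuple[float, float]] = []
    if mv2.any():
        hull = morphology.convex_hull_image(mv2)
        hull_er = morphology.erosion(hull, morphology.footprint_rectangle((sq5, sq5)))
        tipbw = mv2 & ~hull_er
        dil = morphology.dilation(tipbw, morphology.footprint_rectangle((sq3, sq3)))
        lab = measure.label(dil, connectivity=2)
        for li in range(1, lab.max() + 1):
            rows, cols = np.nonzero((lab == li) & tipbw)
            if len(rows) == 0:
                continue
            candidates.append(
                (float(cols.mean()) * pixel_size_nm, float(rows.mean()) * pixel_size_nm)
            )
    masks["TipBW"] = tipbw
    return candidates, masks


def _inbg_edge_pixels(inbg: np.ndarray) -> np.ndarray:
    """Outer-edge pixel set of a mask: Sobel magnitude > 0 (no thinning), outside it."""
    grad = filters.sobel(inbg.astype(float))
    return np.column_stack(np.nonzero((grad > 0) & ~inbg))


def measure_mv_length(
    tip_nm: tuple[float, float],
    inbg: np.ndarray,
    pixel_size_nm: float,
    cbbw: np.ndarray | None = None,
) -> float:
    """MV length: closest distance from the tip to the inner cell boundary (nm)."""
    if inbg.any():
        edge = _inbg_edge_pixels(inbg)
    else:
        warnings.warn("InBG empty; measuring length to the CB-BW boundary")
        if cbbw is None or not cbbw.any():
            raise ValueError("InBG empty and no CB-BW fallback available")
        edge = _inbg_edge_pixels(cbbw)
    ex = edge[:, 1] * pixel_size_nm
    ey = edge[:, 0] * pixel_size_nm
    return float(np.hypot(ex - tip_nm[0], ey - tip_nm[1]).min())


def filter_tips(
    candidates: list[tuple[float, float]],
    lengths_nm: list[float],
    min_length_nm: float = 50.0,
    max_length_nm: float = 1500.0,
    merge_nm: float = 50.0,
) -> tuple[list[tuple[float, float]], list[float]]:
    """Apply the MV length and tip-proximity filters.

    Tips of MV shorter than 50 nm or longer than 1.5 um are dropped; of any
    surviving pair of tips closer than 50 nm, the tip of the shorter MV is
    dropped (ties keep the lower index), repeated until stable.
    """
    if len(candidates) != len(lengths_nm):
        raise ValueError("candidates and lengths must align")
    keep = [
        i
        for i, ln in enumerate(lengths_nm)
        if min_length_nm <= ln <= max_length_nm
    ]
    changed = True
    while changed:
        changed = False
        drop: int | None = None
        for a in range(len(keep)):
            for b in range(a + 1, len(keep)):
                i, j = keep[a], keep[b]
                d = np.hypot(
                    candidates[i][0] - candidates[j][0],
                    candidates[i][1] - candidates[j][1],
                )
                if d < merge_nm:
                    # drop the shorter MV's tip; tie keeps the lower index
                    drop = j if lengths_nm[j] <= lengths_nm[i] else i
                    break
            if drop is not None:
                break
        if drop is not None:
            keep.remove(drop)
            changed = True
    return [candidates[i] for i in keep], [lengths_nm[i] for i in keep]


def _distance_to_tips_nm(
    shape: tuple[int, int],
    tips_nm: list[tuple[float, float]],
    pixel_size_nm: float,
) -> np.ndarray:
    """Per-pixel Euclidean distance (nm) from the pixel center to the nearest tip."""
    ny, nx = shape
    if not tips_nm:
        return np.full(shape, np.inf)
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    centers = np.column_stack([xx.ravel() * pixel_size_nm, yy.ravel() * pixel_size_nm])
    tree = cKDTree(np.asarray(tips_nm, dtype=float))
    d, _ = tree.query(centers, k=1)
    return d.reshape(shape)


def assign_areas(
    segbw: np.ndarray,
    mvbw: np.ndarray,
    cbbw: np.ndarray,
    outbg: np.ndarray,
    inbg: np.ndarray,
    tips_nm: list[tuple[float, float]],
    mv_lengths_nm: list[float],
    pixel_size_nm: float,
    tip_radius_nm: float = 150.0,
    junction_nm: float = 75.0,
) -> SegmentationMap:
    """MV-tip / MV-col / CB zoning with junction bands removed.

    MV-tip area: MV-BW pixels closer than ``tip_radius_nm`` to a tip.
    The next ``junction_nm`` band of MV-BW is excluded from MV-col; the CB
    area likewise loses its junction band against the MV-tip area.
    Sub-threshold pixels inside the cell carry the InBG label so that zone
    labels partition the raster.
    """
    d = _distance_to_tips_nm(segbw.shape, tips_nm, pixel_size_nm)
    labels = np.full(segbw.shape, ZONE_CODES["OutBG"], dtype=np.uint8)
    cell_side = ~outbg
    labels[cell_side] = ZONE_CODES["InBG"]
    labels[cbbw] = ZONE_CODES["CB"]
    labels[cbbw & (d < tip_radius_nm + junction_nm)] = ZONE_CODES["JunctionExcluded"]
    labels[mvbw] = ZONE_CODES["MVcol"]
    labels[mvbw & (d < tip_radius_nm + junction_nm)] = ZONE_CODES["JunctionExcluded"]
    labels[mvbw & (d < tip_radius_nm)] = ZONE_CODES["MVtip"]
    masks = {
        "OutBG": outbg,
        "InBG": inbg,
        "SegBW": segbw,
        "MV-BW": mvbw,
        "CB-BW": cbbw,
    }
    return SegmentationMap(
        labels=labels,
        tips_nm=list(tips_nm),
        mv_lengths_nm=list(mv_lengths_nm),
        masks=masks,
        pixel_size_nm=pixel_size_nm,
    )


def segment_cell(
    image: CellImage,
    min_component_px: int = 2000,
    min_length_nm: float = 50.0,
    max_length_nm: float = 1500.0,
    merge_nm: float = 50.0,
    tip_radius_nm: float = 150.0,
    junction_nm: float = 75.0,
) -> SegmentationMap:
    """Run the full segmentation pipeline on one two-channel plane."""
    px = image.pixel_size_nm
    outbg = compute_outbg(image)
    inbg = compute_inbg(image, outbg)
    segbw = compute_segbw(image, outbg, inbg)
    candidates, masks = detect_tips(segbw, inbg, px, min_component_px)
    lengths = [
        measure_mv_length(t, inbg, px, cbbw=masks["CB-BW"]) for t in candidates
    ]
    tips, tip_lengths = filter_tips(
        candidates, lengths, min_length_nm, max_length_nm, merge_nm
    )
    segmap = assign_areas(
        masks["SegBW"], masks["MV-BW"], masks["CB-BW"], outbg, inbg,
        tips, tip_lengths, px, tip_radius_nm, junction_nm,
    )
    segmap.masks["TipBW"] = masks["TipBW"]
    return segmap
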