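"""Two-channel colocalization statistics over segmented cell zones.

Implements the ratiometric intensity score (RIS), Pearson correlation R',
the segment-correlation coefficient SR', Manders coefficients, the 0-1
intensity normalization, and distance-binned profiles from the MV tips.

RIS is the generalized-polarization-style per-pixel score
``(X - Yn) / (X + Yn)`` where ``Yn`` is channel Y rescaled so the two
channel means match over the cell mask: +1 where only X is present, -1
where only Y is present, 0 where the mean-matched intensities are equal.

SR' evaluates the Pearson cross-product over a *segment* of pixels while
keeping the means (and hence the deviations) anchored to the whole cell:

    SR' = sum_seg (X - Xbar_cell)(Y - Ybar_cell)
          / sqrt( sum_seg (X - Xbar_cell)^2 * sum_seg (Y - Ybar_cell)^2 )

so a segment where X is constantly below and Y constantly above their cell
means scores exactly -1 (ordinary Pearson is blind to such constant
anticorrelation), and the segment equal to the whole cell recovers R'.

RIS and SR' operate on raw intensities; intensity summaries use the
normalized channels. Both conventions are kept as separate code paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import filters

from .segmentation import SegmentationMap, _distance_to_tips_nm

__all__ = [
    "ZoneStats",
    "normalize_intensity",
    "ris_map",
    "pearson",
    "sr_prime",
    "manders",
    "distance_profile",
    "zone_summary",
]


@dataclass
class ZoneStats:
    zone: str
    median_intensity_X: float
    median_intensity_Y: float
    median_RIS: float
    mean_SRprime: float
    n_pixels: int
    z_index: int | None = None


def normalize_intensity(channel: np.ndarray, cell_mask: np.ndarray) -> np.ndarray:
    """Normalize a channel to [0, 1] after background subtraction.

    The global Otsu level is subtracted (clamped at zero), values above the
    99th percentile of the positive in-mask pixels are saturated, and the
    result is scaled linearly to [0, 1].
    """
    if np.any(channel < 0):
        raise ValueError("intensities must be non-negative")
    if np.ptp(channel) == 0:
        warnings.warn("constant channel; normalization returns zeros")
        return np.zeros_like(channel, dtype=float)
    bg = filters.threshold_otsu(channel)
    sub = np.clip(channel.astype(float) - bg, 0.0, None)
    pos = sub[cell_mask & (sub > 0)]
    if pos.size == 0:
        warnings.warn("no positive in-mask pixels after background subtraction")
        return np.zeros_like(sub)
    cap = np.percentile(pos, 99.0)
    if cap <= 0:
        cap = pos.max()
    return np.clip(sub, 0.0, cap) / cap


def ris_map(
    X: np.ndarray, Y: np.ndarray, cell_mask: np.ndarray
) -> np.ndarray:
    """Per-pixel ratiometric intensity score on raw intensities.

    Y is scaled so its mean over ``cell_mask`` matches X's; pixels where
    ``X + Yn == 0`` are undefined and returned as NaN.
    """
    my = Y[cell_mask].mean()
    if my == 0:
        raise ValueError("channel Y empty")
    mx = X[cell_mask].mean()
    yn = Y * (mx / my)
    denom = X + yn
    with np.errstate(divide="ignore", invalid="ignore"):
        ris = np.where(denom > 0, (X - yn) / denom, np.nan)
    return ris


def pearson(X: np.ndarray, Y: np.ndarray, pixels: np.ndarray) -> float:
    """Pearson correlation R' over a pixel index set.

    ``pixels`` may be a boolean mask or an integer index array into the
    flattened rasters. Returns 0 when either channel has zero variance over
    the set (the degenerate-segment convention).
    """
    x = np.asarray(X).ravel()[_flat_index(X, pixels)]
    y = np.asarray(Y).ravel()[_flat_index(Y, pixels)]
    if x.size < 2:
        raise ValueError("need at least 2 pixels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _flat_index(arr: np.ndarray, pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.dtype == bool:
        return np.nonzero(pixels.ravel())[0]
    return pixels.ravel()


def sr_prime(
    X: np.ndarray, Y: np.ndarray, segment: np.ndarray, cell: np.ndarray
) -> float:
    """Segment-correlation coefficient SR' (see module docstring).

    ``segment`` must index a subset of ``cell``; means are taken over the
    cell set, sums over the segment. Degenerate segments (a zero
    squared-deviation sum) return 0 -- the numerator is necessarily zero
    in that case.
    """
    xf, yf = np.asarray(X, float).ravel(), np.asarray(Y, float).ravel()
    seg = _flat_index(X, segment)
    cel = _flat_index(X, cell)
    if seg.size == 0:
        raise ValueError("segment is empty")
    if not np.isin(seg, cel).all():
        raise ValueError("segment must be a subset of the cell set")
    xbar, ybar = xf[cel].mean(), yf[cel].mean()
    dx, dy = xf[seg] - xbar, yf[seg] - ybar
    num = float(np.dot(dx, dy))
    sxx, syy = float(np.dot(dx, dx)), float(np.dot(dy, dy))
    if sxx == 0.0 or syy == 0.0:
        return 0.0 if num == 0.0 else float(np.sign(num))
    # |SR'| <= 1 by Cauchy-Schwarz; clip floating-point overshoot
    return float(np.clip(num / np.sqrt(sxx * syy), -1.0, 1.0))


def manders(
    X: np.ndarray, Y: np.ndarray, pixels: np.ndarray
) -> tuple[float, float, float]:
    """Manders' overlap coefficient and the two thresholded fractions.

    MOC = sum(XY) / sqrt(sum(X^2) sum(Y^2)); MCC1 is the fraction of X mass
    on pixels where Y exceeds its first 2-level multi-Otsu threshold, MCC2
    symmetric. Raises on an all-zero channel (MOC undefined).
    """
    from .segmentation import _first_multiotsu

    x = np.asarray(X, float).ravel()[_flat_index(X, pixels)]
    y = np.asarray(Y, float).ravel()[_flat_index(Y, pixels)]
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("intensities must be non-negative")
    sx2, sy2 = np.dot(x, x), np.dot(y, y)
    if sx2 == 0 or sy2 == 0:
        raise ValueError("MOC undefined for an all-zero channel")
    moc = float(np.dot(x, y) / np.sqrt(sx2 * sy2))
    tx, ty = _first_multiotsu(x), _first_multiotsu(y)
    mcc1 = float(x[y > ty].sum() / x.sum())
    mcc2 = float(y[x > tx].sum() / y.sum())
    return moc, mcc1, mcc2


def _median(values: np.ndarray) -> float:
    """Median with the even-count convention (mean of central order stats)."""
    values = values[np.isfinite(values)]
    return float(np.median(values)) if values.size else float("nan")


def distance_profile(
    X_raw: np.ndarray,
    Y_raw: np.ndarray,
    X_norm: np.ndarray,
    Y_norm: np.ndarray,
    ris: np.ndarray,
    tips_nm: list[tuple[float, float]],
    mask: np.ndarray,
    pixel_size_nm: float,
    bin_nm: float = 12.5,
    max_nm: float | None = None,
) -> pd.DataFrame:
    """Profiles of median intensity, median RIS, and SR' versus tip distance.

    Each in-mask pixel is assigned its Euclidean distance to the nearest
    accepted tip and binned in contiguous ``bin_nm`` bins from 0; SR' is
    evaluated per bin against the whole in-mask pixel set.
    """
    if not tips_nm:
        raise ValueError("tips must be non-empty")
    d = _distance_to_tips_nm(mask.shape, tips_nm, pixel_size_nm)
    flat_mask = mask.ravel()
    din = d.ravel()[flat_mask]
    if max_nm is None:
        max_nm = float(din.max())
    n_bins = int(np.ceil(max_nm / bin_nm)) or 1
    idx = np.nonzero(flat_mask)[0]
    which = np.minimum((din / bin_nm).astype(int), n_bins - 1)
    rows = []
    for k in range(n_bins):
        sel = idx[which == k]
        if sel.size == 0:
            continue
        rows.append(
            {
                "bin_left_nm": k * bin_nm,
                "n_pixels": sel.size,
                "median_X": _median(X_norm.ravel()[sel]),
                "median_Y": _median(Y_norm.ravel()[sel]),
                "median_RIS": _median(ris.ravel()[sel]),
                "mean_SRprime": sr_prime(X_raw, Y_raw, sel, idx),
            }
        )
    return pd.DataFrame(rows)


def zone_summary(
    X_raw: np.ndarray,
    Y_raw: np.ndarray,
    X_norm: np.ndarray,
    Y_norm: np.ndarray,
    ris: np.ndarray,
    segmap: SegmentationMap,
    z_index: int | None = None,
) -> list[ZoneStats]:
    """Per-zone medians and SR' for Tip, Col, CB, and the entire cell.

    The Cell zone is SegBW, so its SR' equals the ordinary Pearson R' over
    the cell. Empty zones are omitted with a warning.
    """
    segbw = segmap.masks["SegBW"]
    cell_idx = np.nonzero(segbw.ravel())[0]
    zones = {
        "Tip": segmap.zone_mask("MVtip"),
        "Col": segmap.zone_mask("MVcol"),
        "CB": segmap.zone_mask("CB"),
        "Cell": segbw,
    }
    out = []
    for name, zmask in zones.items():
        sel = np.nonzero((zmask & segbw).ravel())[0]
        if sel.size == 0:
            warnings.warn(f"zone {name} is empty; omitted")
            continue
        out.append(
            ZoneStats(
                zone=name,
                median_intensity_X=_median(X_norm.ravel()[sel]),
                median_intensity_Y=_median(Y_norm.ravel()[sel]),
                median_RIS=_median(ris.ravel()[sel]),
                mean_SRprime=sr_prime(X_raw, Y_raw, sel, cell_idx),
                n_pixels=int(sel.size),
                z_index=z_index,
            )
        )
    return out
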