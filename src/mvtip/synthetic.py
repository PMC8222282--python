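"""Synthetic super-resolution phantoms with ground truth.

Every downstream stage of the package (segmentation, colocalization
statistics, pair correlation, calcium traces) is exercised on data produced
here, so the generators emit exact ground truth alongside each phantom.

The cell phantom emulates a lymphocyte cross-section: a round cell body
carrying thin radial microvilli (MV). Channel A plays the role of a
tip-resident molecule (L-selectin / CD3-like): its labelling density is
multiplied by ``enrich_factor_A`` within ``tip_cap_radius_nm`` of each tip
apex. Channel B plays the CD45 role: its density is multiplied by
``1 - exclusion_strength_B`` within ``exclusion_radius_nm`` of each apex.
Labelling is membrane-contour (line) density, not filled area, mimicking
surface staining; the raster is blurred with a Gaussian PSF and corrupted
with Poisson shot noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .image import CellImage

__all__ = [
    "SyntheticCellParams",
    "SyntheticGroundTruth",
    "generate_cell_image",
    "generate_storm_localizations",
    "generate_correlation_phantom",
    "generate_calcium_movie",
    "write_ground_truth_json",
    "write_localizations_csv",
    "read_localizations_csv",
]

LOC_COLUMNS = [
    "x_nm", "y_nm", "z_nm", "precision_nm", "photons", "background",
    "sigma_x_px", "sigma_y_px", "channel",
]


@dataclass
class SyntheticCellParams:
    """Geometry and imaging parameters of the two-channel MV cell phantom.

    Defaults describe a resting-lymphocyte-like cross-section: a 1.5 µm
    body radius with 20 microvilli of ~100 nm width and 600-750 nm length,
    strong channel-A tip enrichment and 90 % channel-B depletion within
    150 nm of each tip, imaged at 12.5 nm pixels (50 nm acquisition pixels
    divided by the 4x expansion factor) with a 15 nm PSF sigma.
    """

    body_radius_nm: float = 2000.0
    n_mv: int = 20
    mv_length_range_nm: tuple[float, float] = (650.0, 750.0)
    mv_width_nm: float = 100.0
    tip_cap_radius_nm: float = 50.0
    enrich_factor_A: float = 6.0
    enrich_col_factor_A: float = 2.0  # channel-A density on MV vs cell body
    exclusion_radius_nm: float = 150.0
    exclusion_strength_B: float = 0.9
    psf_sigma_nm: float = 15.0
    pixel_size_nm: float = 12.5
    photon_scale: float = 40.0
    seed: int = 0
    canvas_px: int | None = None  # auto-sized when None
    angle_jitter_deg: float = 1.5

    def __post_init__(self) -> None:
        lo, hi = self.mv_length_range_nm
        if not (0 < lo <= hi <= 5000):
            raise ValueError("mv_length_range_nm must lie within (0, 5000] nm")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if not 0.0 <= self.exclusion_strength_B <= 1.0:
            raise ValueError("exclusion_strength_B must be in [0, 1]")
        if self.n_mv < 0:
            raise ValueError("n_mv must be non-negative")
        if self.enrich_factor_A < 0:
            raise ValueError("enrich_factor_A must be >= 0")

    def auto_canvas_px(self) -> int:
        reach = (
            self.body_radius_nm
            + self.mv_length_range_nm[1]
            + self.tip_cap_radius_nm
            + 4 * self.psf_sigma_nm
            + 8 * self.pixel_size_nm
        )
        return int(np.ceil(2 * reach / self.pixel_size_nm))


@dataclass
class SyntheticGroundTruth:
    """Exact tip apices (nm, image coordinates) and MV lengths of a phantom."""

    tip_positions_nm: list[tuple[float, float]]
    mv_lengths_nm: list[float]
    params: SyntheticCellParams

    def __post_init__(self) -> None:
        if len(self.tip_positions_nm) != len(self.mv_lengths_nm):
            raise ValueError("tips and lengths must align")
        if len(self.tip_positions_nm) != self.params.n_mv:
            raise ValueError("ground truth must list exactly n_mv tips")


def _mv_geometry(params: SyntheticCellParams, rng: np.random.Generator):
    """Per-MV unit direction, length, and apex position relative to the center."""
    n = params.n_mv
    lo, hi = params.mv_length_range_nm
    base = np.linspace(0.0, 2 * np.pi, n, endpoint=False) if n else np.empty(0)
    jitter = np.deg2rad(params.angle_jitter_deg)
    angles = base + rng.uniform(-jitter, jitter, size=n)
    lengths = rng.uniform(lo, hi, size=n)
    ux, uy = np.cos(angles), np.sin(angles)
    apex_r = params.body_radius_nm + lengths
    return ux, uy, lengths, apex_r


def _contour_points(params: SyntheticCellParams, rng: np.random.Generator):
    """Sample the membrane contour as weighted points (weight = arc length).

    Returns (points[N,2] relative to cell center in nm, weights[N],
    on_mv[N] flags, apex positions[n_mv,2], lengths[n_mv]).
    """
    step = params.pixel_size_nm / 3.0
    pts, wts, on_mv = [], [], []

    # cell body circle
    circ = 2 * np.pi * params.body_radius_nm
    n_body = max(int(np.ceil(circ / step)), 8)
    th = np.linspace(0, 2 * np.pi, n_body, endpoint=False)
    pts.append(np.column_stack([np.cos(th), np.sin(th)]) * params.body_radius_nm)
    wts.append(np.full(n_body, circ / n_body))
    on_mv.append(np.zeros(n_body, dtype=bool))

    ux, uy, lengths, apex_r = _mv_geometry(params, rng)
    half_w = params.mv_width_nm / 2.0
    apices = np.column_stack([ux * apex_r, uy * apex_r]) if params.n_mv else np.empty((0, 2))

    for i in range(params.n_mv):
        u = np.array([ux[i], uy[i]])
        nvec = np.array([-uy[i], ux[i]])  # wall normal
        # walls run from the body edge to the start of the half-disk cap
        start_r = params.body_radius_nm
        cap_center_r = apex_r[i] - half_w
        wlen = max(cap_center_r - start_r, 0.0)
        n_w = max(int(np.ceil(wlen / step)), 2)
        t = np.linspace(0.0, wlen, n_w)
        for sgn in (+1.0, -1.0):
            wall = (start_r + t)[:, None] * u[None, :] + sgn * half_w * nvec[None, :]
            pts.append(wall)
            wts.append(np.full(n_w, wlen / n_w if n_w else 0.0))
            on_mv.append(np.ones(n_w, dtype=bool))
        # half-circular cap of radius half_w; its pole is the tip apex
        cap_center = u * cap_center_r
        arc = np.pi * half_w
        n_c = max(int(np.ceil(arc / step)), 4)
        phi = np.linspace(-np.pi / 2, np.pi / 2, n_c)
        cap = (
            cap_center[None, :]
            + (np.cos(phi)[:, None] * u[None, :] + np.sin(phi)[:, None] * nvec[None, :])
            * half_w
        )
        pts.append(cap)
        wts.append(np.full(n_c, arc / n_c))
        on_mv.append(np.ones(n_c, dtype=bool))

    return np.vstack(pts), np.concatenate(wts), np.concatenate(on_mv), apices, lengths


def generate_cell_image(
    params: SyntheticCellParams,
) -> tuple[CellImage, SyntheticGroundTruth]:
    """Render the two-channel MV cell phantom.

    Deterministic given ``params.seed``. Raises ``ValueError`` ("cell
    exceeds canvas") when a protrusion would leave the image border.
    """
    rng = np.random.default_rng(params.seed)
    canvas = params.canvas_px or params.auto_canvas_px()
    px = params.pixel_size_nm
    center = (canvas - 1) / 2.0 * px

    pts, wts, on_mv, apices, lengths = _contour_points(params, rng)
    margin = 2 * params.psf_sigma_nm
    reach = np.abs(pts).max() if len(pts) else 0.0
    if reach + margin > center:
        raise ValueError("cell exceeds canvas")

    tip_xy = apices + center  # image coordinates, nm
    dist_to_tip = (
        np.linalg.norm(pts[:, None, :] - apices[None, :, :], axis=2).min(axis=1)
        if params.n_mv
        else np.full(len(pts), np.inf)
    )

    w_a = wts * np.where(on_mv, params.enrich_col_factor_A, 1.0)
    w_a = w_a * np.where(dist_to_tip <= params.tip_cap_radius_nm, params.enrich_factor_A, 1.0)
    w_b = wts * np.where(
        dist_to_tip <= params.exclusion_radius_nm, 1.0 - params.exclusion_strength_B, 1.0
    )

    cols = np.round((pts[:, 0] + center) / px).astype(int)
    rows = np.round((pts[:, 1] + center) / px).astype(int)
    ok = (rows >= 0) & (rows < canvas) & (cols >= 0) & (cols < canvas)

    channels = {}
    for name, w in (("A", w_a), ("B", w_b)):
        img = np.zeros((canvas, canvas))
        np.add.at(img, (rows[ok], cols[ok]), w[ok] / px)  # density per pixel
        img = gaussian_filter(img, params.psf_sigma_nm / px)
        img = rng.poisson(img * params.photon_scale).astype(float)
        channels[name] = img

    gt = SyntheticGroundTruth(
        tip_positions_nm=[tuple(map(float, xy)) for xy in tip_xy],
        mv_lengths_nm=[float(v) for v in lengths],
        params=params,
    )
    return CellImage(channels=channels, pixel_size_nm=px), gt


# ---------------------------------------------------------------------------
# STORM-like localization tables
# ---------------------------------------------------------------------------

def generate_storm_localizations(
    geometry: SyntheticCellParams,
    density_A: float,
    density_B: float,
    loc_noise_sigma_nm: float = 0.0,
    seed: int = 0,
    quality_ranges: dict | None = None,
) -> pd.DataFrame:
    """Sample molecule positions on the MV surface geometry.

    Channel A is drawn uniformly on the hemispherical tip caps; channel B on
    the cylindrical MV walls and the body circle, rejecting any point within
    ``geometry.exclusion_radius_nm`` of a tip apex. Densities are molecules
    per nm^2 of surface. Isotropic Gaussian localization noise of
    ``loc_noise_sigma_nm`` is added per axis. Quality columns are drawn
    uniformly from ``quality_ranges`` (defaults pass the standard filters).
    """
    if density_A <= 0 or density_B <= 0:
        raise ValueError("densities must be positive")
    rng = np.random.default_rng(seed)
    q = {
        "precision_nm": (3.0, 12.0),
        "photons": (500.0, 5000.0),
        "background": (5.0, 60.0),
        "sigma_px": (1.0, 1.8),
        "sigma_ratio": (0.85, 1.15),  # sigma_y drawn as sigma_x / ratio
    }
    if quality_ranges:
        q.update(quality_ranges)

    ux, uy, lengths, apex_r = _mv_geometry(geometry, rng)
    cap_r = geometry.tip_cap_radius_nm
    half_w = geometry.mv_width_nm / 2.0
    apices = np.column_stack([ux * apex_r, uy * apex_r, np.zeros_like(apex_r)])

    rows = []

    # channel A: uniform on hemispherical caps (radius cap_r, axis u, pole at apex)
    cap_area = 2 * np.pi * cap_r ** 2
    for i in range(geometry.n_mv):
        n_pts = rng.poisson(density_A * cap_area)
        u3 = np.array([ux[i], uy[i], 0.0])
        n3 = np.array([-uy[i], ux[i], 0.0])
        z3 = np.array([0.0, 0.0, 1.0])
        cos_t = rng.uniform(0.0, 1.0, n_pts)  # hemisphere toward +u
        sin_t = np.sqrt(1 - cos_t ** 2)
        phi = rng.uniform(0, 2 * np.pi, n_pts)
        local = (
            cos_t[:, None] * u3[None, :]
            + (sin_t * np.cos(phi))[:, None] * n3[None, :]
            + (sin_t * np.sin(phi))[:, None] * z3[None, :]
        ) * cap_r
        center = apices[i] - cap_r * u3
        rows.append(("A", center[None, :] + local))

    # channel B: cylinder walls + body circle (as a circle in z=0 cross-section
    # swept +-half_w in z), outside the exclusion zone
    for i in range(geometry.n_mv):
        u3 = np.array([ux[i], uy[i], 0.0])
        n3 = np.array([-uy[i], ux[i], 0.0])
        z3 = np.array([0.0, 0.0, 1.0])
        wall_len = max(apex_r[i] - cap_r - geometry.body_radius_nm, 0.0)
        area = 2 * np.pi * half_w * wall_len
        n_pts = rng.poisson(density_B * area)
        t = rng.uniform(0, wall_len, n_pts)
        phi = rng.uniform(0, 2 * np.pi, n_pts)
        pos = (
            (geometry.body_radius_nm + t)[:, None] * u3[None, :]
            + (half_w * np.cos(phi))[:, None] * n3[None, :]
            + (half_w * np.sin(phi))[:, None] * z3[None, :]
        )
        rows.append(("B", pos))
    body_area = 2 * np.pi * geometry.body_radius_nm * (2 * half_w)
    n_body = rng.poisson(density_B * body_area)
    th = rng.uniform(0, 2 * np.pi, n_body)
    zz = rng.uniform(-half_w, half_w, n_body)
    body = np.column_stack(
        [np.cos(th) * geometry.body_radius_nm, np.sin(th) * geometry.body_radius_nm, zz]
    )
    rows.append(("B", body))

    recs = []
    for chan, pos in rows:
        if len(pos) == 0:
            continue
        if chan == "B" and geometry.n_mv:
            d = np.linalg.norm(pos[:, None, :] - apices[None, :, :], axis=2).min(axis=1)
            pos = pos[d > geometry.exclusion_radius_nm]
        if loc_noise_sigma_nm > 0:
            pos = pos + rng.normal(0.0, loc_noise_sigma_nm, pos.shape)
        n = len(pos)
        sigma_x = rng.uniform(*q["sigma_px"], n)
        sigma_y = sigma_x / rng.uniform(*q["sigma_ratio"], n)
        recs.append(
            pd.DataFrame(
                {
                    "x_nm": pos[:, 0],
                    "y_nm": pos[:, 1],
                    "z_nm": pos[:, 2],
                    "precision_nm": rng.uniform(*q["precision_nm"], n),
                    "photons": rng.uniform(*q["photons"], n),
                    "background": rng.uniform(*q["background"], n),
                    "sigma_x_px": sigma_x,
                    "sigma_y_px": sigma_y,
                    "channel": chan,
                }
            )
        )
    if not recs:
        return pd.DataFrame(columns=LOC_COLUMNS)
    return pd.concat(recs, ignore_index=True)[LOC_COLUMNS]


# ---------------------------------------------------------------------------
# Correlation-validation phantom
# ---------------------------------------------------------------------------

def generate_correlation_phantom(
    n_pixels: int, mix: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired intensity vectors with correlation controlled by ``mix``.

    ``mix=+1`` gives identical channels, ``mix=-1`` complementary channels
    (Y = 1 - X), ``mix=0`` independent channels; intermediate values blend
    linearly with an independent component. Returns (X, Y, segment_indices)
    where the segment covers all pixels (segment == cell), so the segment
    correlation equals ordinary Pearson correlation.
    """
    if abs(mix) > 1:
        raise ValueError("|mix| must be <= 1")
    if n_pixels < 4:
        raise ValueError("n_pixels < 4: correlation undefined")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.0, 1.0, n_pixels)
    z = rng.uniform(0.0, 1.0, n_pixels)
    a = abs(mix)
    target = x if mix >= 0 else 1.0 - x
    y = a * target + (1.0 - a) * z
    return x, y, np.arange(n_pixels)


# ---------------------------------------------------------------------------
# Calcium step movies
# ---------------------------------------------------------------------------

def generate_calcium_movie(
    n_frames: int,
    baseline: float = 20.0,
    step_frame: int = 10,
    amplitude: float = 30.0,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    main_radius_px: int = 12,
    distractor_radius_px: int = 5,
) -> np.ndarray:
    """A movie of one bright cell blob whose interior intensity steps up.

    The main blob steps from ``baseline`` to ``baseline + amplitude`` at
    ``step_frame``; a smaller distractor blob stays at baseline. Poisson
    noise is applied per frame. Returns an (n_frames, H, W) float array.
    """
    if not 0 <= step_frame < n_frames:
        raise ValueError("step_frame must satisfy 0 <= step_frame < n_frames")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    main_c = (h // 2, w // 2 - w // 8)
    dist_c = (h // 4, 3 * w // 4)
    main = (yy - main_c[0]) ** 2 + (xx - main_c[1]) ** 2 <= main_radius_px ** 2
    dist = (yy - dist_c[0]) ** 2 + (xx - dist_c[1]) ** 2 <= distractor_radius_px ** 2
    frames = np.empty((n_frames, h, w))
    for f in range(n_frames):
        lam = np.full((h, w), 1.0)  # dim background
        lam[dist] = baseline
        lam[main] = baseline + (amplitude if f >= step_frame else 0.0)
        frames[f] = rng.poisson(lam)
    return frames


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def write_ground_truth_json(path, gt: SyntheticGroundTruth) -> None:
    payload = {
        "tip_positions_nm": gt.tip_positions_nm,
        "mv_lengths_nm": gt.mv_lengths_nm,
        "params": asdict(gt.params),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def write_localizations_csv(path, table: pd.DataFrame) -> None:
    table[LOC_COLUMNS].to_csv(path, index=False)


def read_localizations_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
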