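"""End-to-end runs: simulate -> segment -> statistics -> report bundle."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import RunConfig, save_config
from .coloc import distance_profile, normalize_intensity, ris_map, zone_summary
from .image import CellImage, write_ome_tiff
from .segmentation import segment_cell
from .storm import (
    filter_localizations,
    pair_correlation_3d,
    select_tip_neighborhood,
)
from .synthetic import (
    SyntheticCellParams,
    generate_cell_image,
    generate_storm_localizations,
    write_ground_truth_json,
)
from .viz import save_overlay_png, save_ris_png

log = logging.getLogger(__name__)

__all__ = ["run_cell_analysis", "run_storm_analysis"]


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_manifest(out_dir: Path, config: RunConfig, artifacts: list[str]) -> Path:
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "artifacts": sorted(artifacts),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path


def run_cell_analysis(
    config: RunConfig,
    out_dir,
    params: SyntheticCellParams | None = None,
    image: CellImage | None = None,
) -> dict:
    """Generate (or accept) a cell image, segment it, and write the report bundle.

    Writes six artifacts: the zone stats CSV, the distance-profile CSV, the
    RIS map TIFF, the zone-label TIFF, a QC overlay PNG, and either the
    ground-truth JSON (synthetic input) or the input OME-TIFF copy.
    Returns a dict with the in-memory results and the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt = None
    if image is None:
        if params is None:
            params = SyntheticCellParams(
                pixel_size_nm=config.pixel_size_nm, seed=config.seed
            )
        image, gt = generate_cell_image(params)

    segmap = segment_cell(
        image,
        min_component_px=config.min_component_px,
        min_length_nm=config.mv_min_nm,
        max_length_nm=config.mv_max_nm,
        merge_nm=config.tip_merge_nm,
        tip_radius_nm=config.tip_radius_nm,
        junction_nm=config.junction_nm,
    )
    log.info("accepted %d MV tips", len(segmap.tips_nm))

    names = image.channel_names
    x_name, y_name = names[1], names[0]  # X = excluded channel (B), Y = tip channel (A)
    if "B" in names and "A" in names:
        x_name, y_name = "B", "A"
    X, Y = image.channels[x_name], image.channels[y_name]
    segbw = segmap.masks["SegBW"]
    xn = normalize_intensity(X, segbw)
    yn = normalize_intensity(Y, segbw)
    ris = ris_map(X, Y, segbw)

    zones = zone_summary(X, Y, xn, yn, ris, segmap, z_index=image.z_index)
    zone_df = pd.DataFrame(
        [
            {
                "z_index": z.z_index if z.z_index is not None else 0,
                "zone": z.zone,
                "n_pixels": z.n_pixels,
                "median_X": z.median_intensity_X,
                "median_Y": z.median_intensity_Y,
                "median_RIS": z.median_RIS,
                "mean_SRprime": z.mean_SRprime,
            }
            for z in zones
        ]
    )
    profile = (
        distance_profile(
            X, Y, xn, yn, ris, segmap.tips_nm, segbw,
            image.pixel_size_nm, bin_nm=config.bin_nm,
        )
        if segmap.tips_nm
        else pd.DataFrame()
    )

    artifacts = []
    zone_path = out_dir / "zone_stats.csv"
    zone_df.to_csv(zone_path, index=False)
    artifacts.append(zone_path.name)
    prof_path = out_dir / "distance_profile.csv"
    profile.to_csv(prof_path, index=False)
    artifacts.append(prof_path.name)
    tifffile.imwrite(out_dir / "ris_map.tif", ris.astype(np.float32))
    artifacts.append("ris_map.tif")
    tifffile.imwrite(out_dir / "zone_labels.tif", segmap.labels)
    artifacts.append("zone_labels.tif")
    save_overlay_png(out_dir / "qc_overlay.png", segmap)
    artifacts.append("qc_overlay.png")
    save_ris_png(out_dir / "ris_map.png", ris)
    if gt is not None:
        write_ground_truth_json(out_dir / "ground_truth.json", gt)
        artifacts.append("ground_truth.json")
    else:
        write_ome_tiff(out_dir / "input.ome.tif", image)
        artifacts.append("input.ome.tif")

    tips_df = pd.DataFrame(
        {
            "tip_id": range(len(segmap.tips_nm)),
            "x_nm": [t[0] for t in segmap.tips_nm],
            "y_nm": [t[1] for t in segmap.tips_nm],
            "length_nm": segmap.mv_lengths_nm,
            "z_index": image.z_index if image.z_index is not None else 0,
        }
    )
    tips_df.to_csv(out_dir / "tips.csv", index=False)
    save_config(config, out_dir / "config.yaml")
    manifest = _write_manifest(out_dir, config, artifacts)
    return {
        "segmap": segmap,
        "zones": zone_df,
        "profile": profile,
        "ground_truth": gt,
        "manifest": manifest,
    }


def run_storm_analysis(
    config: RunConfig,
    out_dir,
    table: pd.DataFrame | None = None,
    tips_nm: list[tuple[float, float]] | None = None,
    geometry: SyntheticCellParams | None = None,
) -> dict:
    """Filter localizations, select tip neighborhoods, and compute g(r)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if table is None:
        if geometry is None:
            geometry = SyntheticCellParams(seed=config.seed)
        table = generate_storm_localizations(
            geometry, density_A=2e-3, density_B=2e-3, loc_noise_sigma_nm=5.0,
            seed=config.seed,
        )
        if tips_nm is None:
            ux = np.cos(np.linspace(0, 2 * np.pi, geometry.n_mv, endpoint=False))
            uy = np.sin(np.linspace(0, 2 * np.pi, geometry.n_mv, endpoint=False))
            r = geometry.body_radius_nm + np.mean(geometry.mv_length_range_nm)
            tips_nm = list(zip(ux * r, uy * r))
    if tips_nm is None:
        raise ValueError("tips_nm required when a table is supplied")

    thresholds = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in config.storm_thresholds.items()
    }
    filtered, counts = filter_localizations(table, thresholds)
    report = {"input_rows": int(len(table)), "removed": counts,
              "retained": int(len(filtered))}
    with open(out_dir / "filter_report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)

    if filtered.empty:
        log.warning("no localizations survive the filters; refusing to compute g(r)")
        return {"filter_report": report, "pair_correlation": None}

    sub, volume = select_tip_neighborhood(filtered, tips_nm)
    ref = sub[sub["channel"] == "A"][["x_nm", "y_nm", "z_nm"]].to_numpy()
    target = sub[sub["channel"] == "B"][["x_nm", "y_nm", "z_nm"]].to_numpy()
    if len(ref) == 0 or len(target) == 0:
        log.warning("a channel is empty near the tips; refusing to compute g(r)")
        return {"filter_report": report, "pair_correlation": None}
    pc = pair_correlation_3d(
        ref, target, volume, dr_nm=config.storm_dr_nm, r_max_nm=config.storm_rmax_nm
    )
    pc.to_frame().to_csv(out_dir / "pair_correlation.csv", index=False)
    peak = {"peak_r_left_nm": pc.peak_r_nm(), "g_max": float(pc.g.max())}
    with open(out_dir / "peak_summary.json", "w") as fh:
        json.dump(peak, fh, indent=1, sort_keys=True)
    _write_manifest(
        out_dir, config,
        ["filter_report.json", "pair_correlation.csv", "peak_summary.json"],
    )
    return {"filter_report": report, "pair_correlation": pc, "peak": peak}
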