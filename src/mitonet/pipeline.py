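"""End-to-end per-cell analysis: images in, metric row + artifacts out.

Stages: segmentation (tubeness + global threshold) -> skeleton graph ->
spot detection -> network assignment -> pcf / nndist with IRP normalization
-> entropy, peak distance and window averages -> optional perinuclear /
peripheral region analysis. Deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .curve_metrics import (
    EntropyConfig,
    WINDOW_R1,
    WINDOW_R2,
    pcf_entropy,
    peak_distance,
    region_average,
)
from .image_pipeline import BinaryMask, ImageSet, global_threshold, load_image_set, remove_nucleus, to_8bit, tubeness_filter
from .linear_pcf import NetworkPointPattern, PcfConfig, nndist, normalize_to_irp, pooled_pcf
from .network_distances import GeodesicStructure
from .network_graph import build_network, length_metrics, skeletonize
from .spatial_partition import assign_regions, label_clusters, partition_perinuclear, size_ratio
from .spot_detection import (
    DEFAULT_ASSIGN_DIST_PX,
    DEFAULT_SPOT_RADIUS_PX,
    assign_to_network,
    detect_spots,
    match_sizes_to_spots,
    measure_nucleoid_sizes,
)

logger = logging.getLogger("mitonet")

__all__ = ["RunConfig", "CellReport", "run_cell", "run_cell_images", "run_batch", "REPORT_COLUMNS"]

REPORT_COLUMNS = [
    "cell_id",
    "total_length_um",
    "J",
    "E",
    "connectivity",
    "n_clusters",
    "inv_short",
    "n_nucleoids",
    "density_per_um",
    "nndist_um",
    "nndist_ratio",
    "pcf_R1",
    "pcf_R2",
    "peak_um",
    "entropy_bits",
    "mean_size_P_um",
    "mean_size_N_um",
    "size_ratio",
]


@dataclass
class RunConfig:
    """Configuration of one per-cell run; round-trips through YAML."""

    mito_path: str | None = None
    nucleoid_path: str | None = None
    nucleus_mask_path: str | None = None
    cell_mask_path: str | None = None
    cell_id: str = "cell"
    pixel_size: float = 0.06
    tubeness_scale_px: float = 2.0
    threshold_method: str = "otsu"
    spot_radius_px: float = DEFAULT_SPOT_RADIUS_PX
    spot_quality: float | None = None
    assign_dist_px: float = DEFAULT_ASSIGN_DIST_PX
    bandwidth_px: float = 5.0
    r_max_px: float = 300.0
    irp_replicates: int = 6
    region_fraction: float = 1.0 / 3.0
    seed: int = 0
    out_dir: str | None = None

    def pcf_config(self) -> PcfConfig:
        return PcfConfig(
            bandwidth_px=self.bandwidth_px,
            r_max_px=self.r_max_px,
            irp_replicates=self.irp_replicates,
            rng_seed=self.seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class CellReport:
    """One per-cell summary row (see REPORT_COLUMNS)."""

    values: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{c: self.values.get(c, np.nan) for c in REPORT_COLUMNS}])


def run_cell_images(images: ImageSet, config: RunConfig):
    """Run the full pipeline on in-memory images.

    Returns (CellReport, artifacts dict) with the network, records, pattern
    and curves for further use or export.
    """
    nucleoid = images.nucleoid_channel
    if images.nucleus_mask is not None:
        nucleoid = remove_nucleus(nucleoid, images.nucleus_mask)

    resp = tubeness_filter(images.mito_channel, scale=config.tubeness_scale_px)
    mask = global_threshold(resp, method=config.threshold_method, pixel_size=images.pixel_size)
    if images.cell_mask is not None:
        mask = BinaryMask(mask.grid & images.cell_mask.grid, images.pixel_size)
    skel = skeletonize(mask)
    network = build_network(skel, images.pixel_size)
    if not network.edges:
        raise RuntimeError("segmentation produced an empty network")
    metrics = length_metrics(network)

    spots = detect_spots(nucleoid, radius=config.spot_radius_px, quality_threshold=config.spot_quality)
    records = assign_to_network(spots, network, max_dist=config.assign_dist_px)
    # size table from an Otsu threshold of the 8-bit DNA channel
    img8 = to_8bit(nucleoid)
    if np.ptp(img8) > 0:
        from skimage.filters import threshold_otsu

        sizes = measure_nucleoid_sizes(img8, float(threshold_otsu(img8)), images.pixel_size)
        records = match_sizes_to_spots(records, sizes)

    assigned = [r for r in records if r.assigned]
    pattern = NetworkPointPattern(network, [r.location for r in assigned])
    geo = GeodesicStructure(network)
    pcf_cfg = config.pcf_config()

    ratio_curve = None
    nnd = None
    counts = pattern.counts_by_cluster()
    if any(n >= 2 for n in counts.values()):
        raw = pooled_pcf(pattern, network, config=pcf_cfg, geo=geo)
        ratio_curve = normalize_to_irp(raw, pattern, network, config=pcf_cfg, geo=geo)
        nnd = normalize_to_irp(nndist(pattern, geo=geo), pattern, network, config=pcf_cfg, geo=geo)

    partition = None
    if images.cell_mask is not None and images.nucleus_mask is not None:
        partition = partition_perinuclear(
            images.cell_mask, images.nucleus_mask, images.pixel_size, fraction=config.region_fraction
        )
        partition = label_clusters(partition, network)
        records = assign_regions(records, partition)
    mean_p, mean_n, sratio = size_ratio(records)

    values = {
        "cell_id": config.cell_id,
        "total_length_um": metrics.total_length_um,
        "J": metrics.n_junctions,
        "E": metrics.n_ends,
        "connectivity": metrics.connectivity,
        "n_clusters": metrics.n_clusters,
        "inv_short": metrics.inv_short,
        "n_nucleoids": len(assigned),
        "density_per_um": len(assigned) / metrics.total_length_um if metrics.total_length_um else math.nan,
        "nndist_um": nnd.mean if nnd else math.nan,
        "nndist_ratio": nnd.ratio if nnd else math.nan,
        "pcf_R1": region_average(ratio_curve, *WINDOW_R1) if ratio_curve is not None else math.nan,
        "pcf_R2": region_average(ratio_curve, *WINDOW_R2) if ratio_curve is not None else math.nan,
        "peak_um": peak_distance(ratio_curve) if ratio_curve is not None else math.nan,
        "entropy_bits": pcf_entropy(ratio_curve, EntropyConfig()) if ratio_curve is not None else math.nan,
        "mean_size_P_um": mean_p,
        "mean_size_N_um": mean_n,
        "size_ratio": sratio,
    }
    artifacts = {
        "network": network,
        "mask": mask,
        "skeleton": skel,
        "records": records,
        "pattern": pattern,
        "curve": ratio_curve,
        "nndist": nnd,
        "partition": partition,
    }
    return CellReport(values), artifacts


def _write_artifacts(report: CellReport, artifacts: dict, config: RunConfig) -> None:
    import tifffile

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_frame().to_csv(out / f"{config.cell_id}_report.csv", index=False, float_format="%.6g")
    mio.write_graphml(artifacts["network"], out / f"{config.cell_id}_network.graphml")
    mio.nucleoid_table(artifacts["records"]).to_csv(
        out / f"{config.cell_id}_nucleoids.csv", index=False, float_format="%.6g"
    )
    if artifacts["curve"] is not None:
        mio.write_curve_csv(artifacts["curve"], out / f"{config.cell_id}_curve.csv")
        mio.plot_curve(artifacts["curve"], out / f"{config.cell_id}_curve.png", r_max_um=5.0)
    tifffile.imwrite(out / f"{config.cell_id}_mask.tif", artifacts["mask"].grid.astype(np.uint8) * 255)
    tifffile.imwrite(out / f"{config.cell_id}_skeleton.tif", artifacts["skeleton"].grid.astype(np.uint8) * 255)
    part = artifacts.get("partition")
    if part is not None:
        tifffile.imwrite(
            out / f"{config.cell_id}_regions.tif",
            (part.perinuclear_mask.grid.astype(np.uint8) * 1 + part.peripheral_mask.grid.astype(np.uint8) * 2),
        )


def run_cell(config: RunConfig) -> CellReport:
    """Load images per config, run the pipeline, write artifacts if out_dir set."""
    if config.mito_path is None:
        raise ValueError("config.mito_path is required")
    images = load_image_set(
        config.mito_path,
        config.nucleoid_path,
        config.pixel_size,
        config.nucleus_mask_path,
        config.cell_mask_path,
    )
    report, artifacts = run_cell_images(images, config)
    if config.out_dir:
        _write_artifacts(report, artifacts, config)
    return report


def run_batch(configs: list[RunConfig]) -> pd.DataFrame:
    """One report row per cell; failures are logged and skipped."""
    if not configs:
        raise ValueError("run_batch needs at least one config")
    rows = []
    for cfg in configs:
        try:
            rows.append(run_cell(cfg).to_frame())
        except Exception as exc:  # noqa: BLE001 - batch must continue
            logger.error("cell %s failed: %s", cfg.cell_id, exc)
    if rows:
        return pd.concat(rows, ignore_index=True)
    return pd.DataFrame(columns=REPORT_COLUMNS)
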