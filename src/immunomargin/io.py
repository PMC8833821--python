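"""File formats: label masks (TIFF + YAML sidecar), detection and cohort CSVs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from immunomargin.geometry import ROIPartition, TissueSection


def write_mask(path: str | Path, section: TissueSection) -> None:
    """Single-channel integer-label TIFF with a YAML calibration sidecar."""
    path = Path(path)
    tifffile.imwrite(path, section.labels.astype(np.uint8))
    sidecar = path.with_suffix(".yaml")
    sidecar.write_text(yaml.safe_dump({"pixel_size_um": float(section.pixel_size_um)}))


def read_mask(path: str | Path) -> TissueSection:
    path = Path(path)
    labels = tifffile.imread(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return TissueSection(labels=labels, pixel_size_um=float(meta["pixel_size_um"]))


def write_points(path: str | Path, points: pd.DataFrame) -> None:
    """Detection table: one row per cell profile, coordinates in um."""
    cols = [c for c in ("marker", "x_um", "y_um", "roi") if c in points.columns]
    points[cols].to_csv(path, index=False)


def read_points(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_partition(directory: str | Path, partition: ROIPartition, stem: str) -> None:
    """Partition as one label raster plus a JSON-able area summary."""
    directory = Path(directory)
    tifffile.imwrite(directory / f"{stem}_rois.tif", partition.as_label_raster())
    summary = {
        "band_width_um": partition.band_width_um,
        "pixel_size_um": partition.pixel_size_um,
        "areas_mm2": {k: float(v) for k, v in partition.areas_mm2.items()},
        "warnings": partition.warnings,
    }
    (directory / f"{stem}_rois.yaml").write_text(yaml.safe_dump(summary))
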