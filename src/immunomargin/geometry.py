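"""Region-of-interest geometry: band partition of a calibrated tissue mask.

A tissue section is a 2D integer label raster (background / non-tumor
liver / tumor) with a known pixel size in micrometres.  The invasive
margin is defined relative to the tumor border -- the set of tumor pixels
4-adjacent to non-tumor liver.  The inner margin (innM) is the band of
tumor pixels within ``band_width`` um of that border, the outer margin
(outM) the band of liver pixels within ``band_width`` um, and the
peritumor region (PT) the next ``band_width`` um of liver.  The tumor
center (TC) is the remaining tumor.  Non-tumor liver (NT) comes from a
separate, distant section and is attached explicitly.

Distances are Euclidean on pixel centers; a pixel exactly at
``band_width`` belongs to the band nearer the border (closed upper bound,
half-open outer bound).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# Raster labels for tissue classes.
LABEL_BACKGROUND = 0
LABEL_LIVER = 1
LABEL_TUMOR = 2

#: Canonical ROI order used throughout the package.
ROI_NAMES = ("TC", "innM", "outM", "PT", "NT")


class MarginError(ValueError):
    """Raised when a section has no tumor / non-tumor interface."""


@dataclass
class TissueSection:
    """A calibrated label mask, optionally carrying its ROI partition."""

    labels: np.ndarray
    pixel_size_um: float
    partition: "ROIPartition | None" = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("label mask must be 2D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        extra = set(np.unique(self.labels)) - {
            LABEL_BACKGROUND,
            LABEL_LIVER,
            LABEL_TUMOR,
        }
        if extra:
            raise ValueError(f"unknown labels in mask: {sorted(extra)}")

    @property
    def tumor_mask(self) -> np.ndarray:
        return self.labels == LABEL_TUMOR

    @property
    def liver_mask(self) -> np.ndarray:
        return self.labels == LABEL_LIVER


@dataclass
class ROIPartition:
    """Binary masks for the five ROIs on a common pixel grid.

    ``masks`` holds TC/innM/outM/PT on the tumor-section grid.  NT, when
    present, lives on its own grid (a separate section) and is stored with
    its own pixel size.
    """

    masks: dict[str, np.ndarray]
    pixel_size_um: float
    band_width_um: float
    nt_mask: np.ndarray | None = None
    nt_pixel_size_um: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        # ROI masks must be pairwise disjoint on the shared grid.
        stacked = np.zeros_like(next(iter(self.masks.values())), dtype=int)
        for m in self.masks.values():
            stacked += m.astype(int)
        if (stacked > 1).any():
            raise ValueError("ROI masks overlap")

    def mask(self, roi: str) -> np.ndarray:
        if roi == "NT":
            if self.nt_mask is None:
                raise KeyError("NT section not attached")
            return self.nt_mask
        return self.masks[roi]

    def roi_pixel_size(self, roi: str) -> float:
        if roi == "NT":
            if self.nt_pixel_size_um is None:
                raise KeyError("NT section not attached")
            return self.nt_pixel_size_um
        return self.pixel_size_um

    @property
    def rois(self) -> tuple[str, ...]:
        base = tuple(self.masks)
        return base + ("NT",) if self.nt_mask is not None else base

    def area_mm2(self, roi: str) -> float:
        px = self.roi_pixel_size(roi)
        return float(self.mask(roi).sum()) * px * px / 1e6

    @property
    def areas_mm2(self) -> dict[str, float]:
        return {roi: self.area_mm2(roi) for roi in self.rois}

    def as_label_raster(self) -> np.ndarray:
        """Encode the tumor-section partition as one integer raster.

        0 = outside all ROIs, then 1..4 in canonical ROI order.
        """
        out = np.zeros(next(iter(self.masks.values())).shape, dtype=np.uint8)
        for i, roi in enumerate(("TC", "innM", "outM", "PT"), start=1):
            if roi in self.masks:
                out[self.masks[roi]] = i
        return out


def tumor_border(section: TissueSection) -> np.ndarray:
    """Tumor pixels 4-adjacent to non-tumor liver (the malignant border)."""
    cross = ndimage.generate_binary_structure(2, 1)
    near_liver = ndimage.binary_dilation(section.liver_mask, structure=cross)
    return section.tumor_mask & near_liver


def partition_rois(section: TissueSection, band_width_um: float = 500.0) -> ROIPartition:
    """Partition a tumor-bearing section into TC, innM, outM and PT bands.

    Parameters
    ----------
    section:
        Calibrated label mask containing tumor and non-tumor liver.
    band_width_um:
        Margin half-width in micrometres (default 500: the inner and outer
        margins each extend 500 um from the tumor border, and PT covers
        the next 500 um of liver).

    Raises
    ------
    MarginError
        If the mask has no tumor pixel adjacent to non-tumor liver.
    """
    if band_width_um < 0:
        raise ValueError("band_width_um must be >= 0")
    tumor = section.tumor_mask
    liver = section.liver_mask
    if not tumor.any() or not liver.any():
        raise MarginError("section lacks a tumor/non-tumor interface")
    border = tumor_border(section)
    if not border.any():
        raise MarginError("tumor and non-tumor liver share no border")

    warnings: list[str] = []
    edge = np.zeros_like(tumor)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    if (tumor & edge).any():
        warnings.append("tumor touches image edge; margin truncated")

    if band_width_um == 0:
        # Degenerate band: no margin, TC is the whole tumor.
        empty = np.zeros_like(tumor)
        masks = {"TC": tumor.copy(), "innM": empty, "outM": empty.copy(), "PT": empty.copy()}
        return ROIPartition(masks, section.pixel_size_um, 0.0, warnings=warnings)

    # Euclidean distance (um) from every pixel center to the nearest
    # border pixel center; border pixels themselves are at distance 0.
    dist = ndimage.distance_transform_edt(~border) * section.pixel_size_um

    inn = tumor & (dist <= band_width_um)
    tc = tumor & ~inn
    out = liver & (dist <= band_width_um)
    pt = liver & (dist > band_width_um) & (dist <= 2.0 * band_width_um)
    masks = {"TC": tc, "innM": inn, "outM": out, "PT": pt}
    return ROIPartition(masks, section.pixel_size_um, float(band_width_um), warnings=warnings)


def designate_nt(partition: ROIPartition, nt_section: TissueSection | None) -> ROIPartition:
    """Attach a distant non-tumor liver section as the NT region.

    NT is sampled from a separate tissue block 2-3 cm from the tumor, so
    it is never derived from the tumor-bearing section; it is accepted
    verbatim provided it contains no tumor label.  Passing ``None`` marks
    NT absent, and downstream NT statistics are skipped.
    """
    if nt_section is None:
        partition.nt_mask = None
        partition.nt_pixel_size_um = None
        partition.warnings.append("NT section absent; NT statistics skipped")
        return partition
    if nt_section.tumor_mask.any():
        raise ValueError("NT section contains tumor label pixels")
    partition.nt_mask = nt_section.liver_mask.copy()
    partition.nt_pixel_size_um = nt_section.pixel_size_um
    return partition
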