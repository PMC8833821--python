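"""Stereological density estimation with 2D unbiased counting frames.

Q_A -- the areal density of nucleated immunopositive cell profiles -- is
estimated per ROI by (1) selecting fields of view (FOV) by systematic
uniform random sampling (SURS) over a fixed raster enumeration of
ROI-intersecting grid cells, (2) laying a fixed grid of non-overlapping
square counting frames inside each FOV, keeping only frames wholly inside
the ROI mask, and (3) counting cell centroids under the unbiased-frame
rule.  For centroid (point) data the classic forbidden-line rule with
extensions collapses to a half-open rectangle: a point is counted iff
``x in (x0, x0+w]`` and ``y in (y0, y0+h]`` (left and bottom edges
excluded, right and top included), which tiles the plane without double
counting.

Q_A = (total counted profiles) / (total frame area) * 1e6, in profiles
per mm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed unbiased-counting-frame areas (um^2) for density-adaptive ROIs.
FRAME_AREA_LADDER = (8700.0, 17400.0, 26100.0, 34801.0)

#: Margin design: 6 frames per FOV x 8 FOV totalling 417,611 um^2.
MARGIN_TOTAL_FRAME_AREA = 417_611.0
MARGIN_FRAME_AREA = MARGIN_TOTAL_FRAME_AREA / 48.0

#: Peritumor design: 9 frames per FOV x 8 FOV totalling 417,215 um^2.
PT_TOTAL_FRAME_AREA = 417_215.0
PT_FRAME_AREA = PT_TOTAL_FRAME_AREA / 72.0

#: Camera field of view (um) by objective; PT uses 10x, all else 20x.
OBJECTIVE_FOV = {"20x": (600.0, 450.0), "10x": (1200.0, 900.0)}


@dataclass(frozen=True)
class CountingFrame:
    """A square unbiased counting frame in physical (um) coordinates."""

    x0: float
    y0: float
    width: float
    height: float

    @property
    def area_um2(self) -> float:
        return self.width * self.height

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Half-open inclusion test (vectorized).

        Left and bottom edges are forbidden lines (a centroid exactly on
        them is rejected); right and top edges are acceptance lines.
        """
        x = np.asarray(x)
        y = np.asarray(y)
        return (
            (x > self.x0)
            & (x <= self.x0 + self.width)
            & (y > self.y0)
            & (y <= self.y0 + self.height)
        )


@dataclass(frozen=True)
class FieldOfView:
    x0: float
    y0: float
    width: float
    height: float


@dataclass
class SamplingDesign:
    """Per-ROI sampling design.

    Defaults mirror the margin protocol: 8 FOVs at the 20x objective with
    6 frames per FOV, the 48 frames totalling 417,611 um^2.
    """

    n_fov: int = 8
    frames_per_fov: int = 6
    frame_area_um2: float = MARGIN_FRAME_AREA
    fov_width_um: float = OBJECTIVE_FOV["20x"][0]
    fov_height_um: float = OBJECTIVE_FOV["20x"][1]

    def __post_init__(self) -> None:
        if self.n_fov < 1:
            raise ValueError("n_fov must be >= 1")
        if self.frame_area_um2 <= 0:
            raise ValueError("frame_area_um2 must be positive")
        side = self.frame_side_um
        slots = math.floor(self.fov_width_um / side) * math.floor(self.fov_height_um / side)
        if slots < self.frames_per_fov:
            raise ValueError("frames do not fit inside the FOV without overlap")

    @property
    def frame_side_um(self) -> float:
        return math.sqrt(self.frame_area_um2)


def default_design(roi: str, expected_density_per_mm2: float | None = None) -> SamplingDesign:
    """The protocol's per-ROI design.

    innM/outM: 6 frames x 8 FOV (20x); PT: 9 frames x 8 FOV (10x); TC and
    NT adapt frame size (and count, 6-9) to the expected lymphocyte
    density when one is supplied.
    """
    if roi in ("innM", "outM"):
        return SamplingDesign()
    if roi == "PT":
        w, h = OBJECTIVE_FOV["10x"]
        return SamplingDesign(
            frames_per_fov=9, frame_area_um2=PT_FRAME_AREA, fov_width_um=w, fov_height_um=h
        )
    if roi in ("TC", "NT"):
        if expected_density_per_mm2 is None:
            return SamplingDesign()
        area = adaptive_frame_area(expected_density_per_mm2)
        w, h = OBJECTIVE_FOV["20x"]
        side = math.sqrt(area)
        capacity = math.floor(w / side) * math.floor(h / side)
        frames = min(adaptive_frames_per_fov(area), capacity)
        return SamplingDesign(frames_per_fov=frames, frame_area_um2=area)
    raise KeyError(f"unknown ROI {roi!r}")


def adaptive_frame_area(
    expected_density_per_mm2: float,
    ladder: tuple[float, ...] = FRAME_AREA_LADDER,
    target_count: float = 2.0,
) -> float:
    """Pick the smallest ladder area whose expected count meets the target.

    The expected count in a frame of area ``A`` um^2 is
    ``density * A / 1e6``.  Sparse regions get larger frames, capped at
    the ladder maximum; dense regions get the smallest frame.
    """
    if not ladder:
        raise ValueError("ladder must be nonempty")
    for area in sorted(ladder):
        if expected_density_per_mm2 * area / 1e6 >= target_count:
            return float(area)
    return float(max(ladder))


def adaptive_frames_per_fov(
    frame_area_um2: float, ladder: tuple[float, ...] = FRAME_AREA_LADDER
) -> int:
    """More (9) small frames per image, fewer (6) large ones."""
    idx = sorted(ladder).index(frame_area_um2)
    return 9 - idx


def sample_fovs(
    roi_mask: np.ndarray,
    pixel_size_um: float,
    design: SamplingDesign,
    rng: np.random.Generator,
) -> tuple[list[FieldOfView], list[str]]:
    """Select FOV placements over an ROI by systematic uniform random sampling.

    Candidate anchors are the cells of an FOV-sized grid over the ROI
    bounding box, enumerated in raster (row-major) order and kept when
    the cell contains at least one ROI pixel.  SURS takes one uniform
    random start and then every ceil(N / n_fov)-th candidate.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    rows, cols = np.nonzero(roi_mask)
    x_min = cols.min() * pixel_size_um
    y_min = rows.min() * pixel_size_um
    x_max = (cols.max() + 1) * pixel_size_um
    y_max = (rows.max() + 1) * pixel_size_um

    warnings: list[str] = []
    w, h = design.fov_width_um, design.fov_height_um
    if (x_max - x_min) < w and (y_max - y_min) < h:
        # Degenerate: ROI smaller than one FOV; center a single FOV on it.
        cx, cy = (x_min + x_max) / 2.0, (y_min + y_max) / 2.0
        warnings.append("ROI smaller than one FOV; single centered FOV used")
        return [FieldOfView(cx - w / 2.0, cy - h / 2.0, w, h)], warnings

    nx = math.ceil((x_max - x_min) / w)
    ny = math.ceil((y_max - y_min) / h)
    candidates: list[FieldOfView] = []
    for j in range(ny):
        for i in range(nx):
            fx, fy = x_min + i * w, y_min + j * h
            r0 = int(fy // pixel_size_um)
            r1 = min(int(math.ceil((fy + h) / pixel_size_um)), roi_mask.shape[0])
            c0 = int(fx // pixel_size_um)
            c1 = min(int(math.ceil((fx + w) / pixel_size_um)), roi_mask.shape[1])
            if roi_mask[r0:r1, c0:c1].any():
                candidates.append(FieldOfView(fx, fy, w, h))

    n = len(candidates)
    if n <= design.n_fov:
        if n < design.n_fov:
            warnings.append(f"ROI supports only {n} FOVs (requested {design.n_fov})")
        return candidates, warnings
    step = math.ceil(n / design.n_fov)
    start = int(rng.integers(0, step))
    selected = candidates[start::step]
    if len(selected) < design.n_fov:
        warnings.append(
            f"SURS spacing yielded {len(selected)} FOVs (requested {design.n_fov})"
        )
    return selected, warnings


def layout_frames(
    fov: FieldOfView,
    design: SamplingDesign,
    roi_mask: np.ndarray | None = None,
    pixel_size_um: float | None = None,
) -> list[CountingFrame]:
    """Lay frames on a fixed grid inside an FOV, top-left first.

    When an ROI mask is given, only frame slots whose full pixel
    footprint lies inside the ROI are eligible; this keeps the frame-area
    denominator honest (every frame samples ROI tissue only).
    """
    side = design.frame_side_um
    frames: list[CountingFrame] = []
    ny = int(fov.height // side)
    nx = int(fov.width // side)
    for j in range(ny):
        for i in range(nx):
            x0 = fov.x0 + i * side
            y0 = fov.y0 + j * side
            if roi_mask is not None:
                if not _footprint_inside(roi_mask, pixel_size_um, x0, y0, side):
                    continue
            frames.append(CountingFrame(x0, y0, side, side))
            if len(frames) == design.frames_per_fov:
                return frames
    return frames


def _footprint_inside(
    roi_mask: np.ndarray, pixel_size_um: float, x0: float, y0: float, side: float
) -> bool:
    r0 = int(y0 // pixel_size_um)
    r1 = int(math.ceil((y0 + side) / pixel_size_um))
    c0 = int(x0 // pixel_size_um)
    c1 = int(math.ceil((x0 + side) / pixel_size_um))
    if r0 < 0 or c0 < 0 or r1 > roi_mask.shape[0] or c1 > roi_mask.shape[1]:
        return False
    return bool(roi_mask[r0:r1, c0:c1].all())


def count_in_frame(
    points: pd.DataFrame,
    frame: CountingFrame,
    roi_mask: np.ndarray | None = None,
    pixel_size_um: float | None = None,
) -> int:
    """Count cell centroids inside one unbiased counting frame.

    Points on the left or bottom edge are excluded (forbidden lines);
    points on the right or top edge are included.  If an ROI mask is
    given, only points whose location falls on an ROI pixel count.
    """
    if len(points) == 0:
        return 0
    x = points["x_um"].to_numpy(dtype=float)
    y = points["y_um"].to_numpy(dtype=float)
    inside = frame.contains(x, y)
    if roi_mask is not None:
        if pixel_size_um is None:
            raise ValueError("pixel_size_um required with roi_mask")
        rows = np.floor(y / pixel_size_um).astype(int)
        cols = np.floor(x / pixel_size_um).astype(int)
        ok = (
            (rows >= 0)
            & (rows < roi_mask.shape[0])
            & (cols >= 0)
            & (cols < roi_mask.shape[1])
        )
        in_roi = np.zeros(len(points), dtype=bool)
        in_roi[ok] = roi_mask[rows[ok], cols[ok]]
        inside &= in_roi
    return int(inside.sum())


@dataclass
class CountResult:
    """Counted profiles and sampled frame area for one patient x marker x ROI."""

    counted_profiles: int
    total_frame_area_um2: float
    patient_id: str | None = None
    marker: str | None = None
    roi: str | None = None
    n_fov: int = 0
    n_frames: int = 0
    warnings: list[str] = field(default_factory=list)

    @property
    def qa_per_mm2(self) -> float:
        return self.counted_profiles / self.total_frame_area_um2 * 1e6


def estimate_qa(
    counts: list[int] | np.ndarray,
    frame_areas_um2: list[float] | np.ndarray,
    **meta,
) -> CountResult:
    """Pool per-frame counts into a single Q_A estimate.

    Q_A = sum(counts) / sum(areas) * 1e6 (profiles per mm^2).
    """
    counts = np.asarray(counts)
    areas = np.asarray(frame_areas_um2, dtype=float)
    if counts.size == 0 or areas.size == 0:
        raise ValueError("at least one frame is required")
    if counts.size != areas.size:
        raise ValueError("counts and frame areas must align")
    if (areas <= 0).any():
        raise ValueError("frame areas must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    return CountResult(
        counted_profiles=int(counts.sum()),
        total_frame_area_um2=float(areas.sum()),
        **meta,
    )


def estimate_roi_qa(
    points: pd.DataFrame,
    roi_mask: np.ndarray,
    pixel_size_um: float,
    design: SamplingDesign,
    rng: np.random.Generator,
    **meta,
) -> CountResult:
    """Full stereological estimate for one ROI: SURS FOVs, frames, counting.

    ``points`` needs columns ``x_um``/``y_um`` and should already be
    restricted to the marker of interest.  Frames are wholly inside the
    ROI mask, so for in-ROI detections no per-point mask test is needed.
    """
    fovs, warnings = sample_fovs(roi_mask, pixel_size_um, design, rng)
    x = points["x_um"].to_numpy(dtype=float) if len(points) else np.empty(0)
    y = points["y_um"].to_numpy(dtype=float) if len(points) else np.empty(0)

    counts: list[int] = []
    areas: list[float] = []
    n_frames = 0
    for fov in fovs:
        frames = layout_frames(fov, design, roi_mask, pixel_size_um)
        if len(frames) < design.frames_per_fov:
            warnings.append(
                f"FOV at ({fov.x0:.0f},{fov.y0:.0f}) holds {len(frames)} frames "
                f"(requested {design.frames_per_fov})"
            )
        if not frames:
            continue
        # Pre-filter to the FOV box (frames are subsets of it).
        sel = (x > fov.x0) & (x <= fov.x0 + fov.width) & (y > fov.y0) & (y <= fov.y0 + fov.height)
        fx, fy = x[sel], y[sel]
        for frame in frames:
            counts.append(int(frame.contains(fx, fy).sum()))
            areas.append(frame.area_um2)
        n_frames += len(frames)
    if not counts:
        raise ValueError("no counting frame fits inside the ROI")
    result = estimate_qa(counts, areas, **meta)
    result.n_fov = len(fovs)
    result.n_frames = n_frames
    result.warnings = warnings
    return result
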