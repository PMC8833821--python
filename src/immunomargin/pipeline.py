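"""End-to-end orchestration: synthesize -> partition -> count -> score -> associate.

A run is driven by a :class:`RunConfig` (constructable from YAML) and a
master seed.  Every random draw comes from a named substream derived
from the master seed, so reruns with the same config and seed reproduce
all stochastic stages bit-for-bit; the manifest records seed, config
hash and library versions.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from immunomargin import __version__
from immunomargin.geometry import TissueSection, partition_rois, designate_nt
from immunomargin.scoring import score_cohort
from immunomargin.stereology import default_design, estimate_roi_qa
from immunomargin.survival import (
    CoxResult,
    cox_multivariable,
    cox_univariable,
    endpoint_table,
    inverse_km_followup,
    region_comparison,
    correlate,
)
from immunomargin.synthesize import (
    CohortConfig,
    TissueGeometryConfig,
    generate_tissue,
    sample_cells,
    sample_patient_profiles,
    simulate_outcomes,
)
from immunomargin import io as imio


def substream(master_seed: int, *names) -> np.random.Generator:
    """A named, reproducible child random stream of the master seed."""
    tag = zlib.crc32("/".join(str(n) for n in names).encode())
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF, spawn_key=(tag,))
    )


@dataclass
class RunConfig:
    """Configuration of one pipeline run (synthetic mode by default).

    Exactly one of the two modes is active: synthetic mode generates
    sections, detections and a cohort; real-input mode reads them from
    ``mask_paths`` / ``detection_paths`` / ``patient_table``.
    """

    n_patients: int = 30
    geometry: TissueGeometryConfig = field(
        default_factory=lambda: TissueGeometryConfig(
            width_um=5400.0, height_um=5400.0, pixel_size_um=10.0, radius_um=1500.0
        )
    )
    cohort: CohortConfig = field(default_factory=CohortConfig)
    band_width_um: float = 500.0
    cuts: tuple[float, float] = (25.0, 70.0)
    endpoints: tuple[str, ...] = ("TTR", "DFS", "OS")
    markers: tuple[str, ...] = ("CD3", "CD8", "CD20")
    include_nt: bool = True
    nt_size_um: float = 3000.0
    seed: int = 0
    # real-input mode (optional)
    mask_paths: dict | None = None
    detection_paths: dict | None = None
    patient_table: str | None = None

    def __post_init__(self) -> None:
        if (self.mask_paths is None) != (self.detection_paths is None):
            raise ValueError("real-input mode needs both masks and detections")

    @property
    def synthetic(self) -> bool:
        return self.mask_paths is None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "geometry" in raw:
            raw["geometry"] = TissueGeometryConfig(**raw["geometry"])
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**raw["cohort"])
        for key in ("cuts", "endpoints", "markers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def synthesize_study(config: RunConfig) -> dict:
    """Generate the synthetic study: sections, per-patient detections, cohort.

    The tumor-section geometry is shared across patients (patients differ
    in their intensity profiles and sampling streams); NT is a separate
    liver-only section.
    """
    geo = config.geometry
    section = generate_tissue(geo)
    section.partition = partition_rois(section, config.band_width_um)
    if config.include_nt:
        n_px = int(round(config.nt_size_um / geo.pixel_size_um))
        nt_section = TissueSection(
            labels=np.ones((n_px, n_px), dtype=np.uint8), pixel_size_um=geo.pixel_size_um
        )
        designate_nt(section.partition, nt_section)
    else:
        designate_nt(section.partition, None)

    n = config.n_patients
    levels, profiles, penetration = sample_patient_profiles(
        n, substream(config.seed, "profiles"), latent_sd=config.cohort.latent_sd
    )
    rng_cov = substream(config.seed, "covariates")
    age = rng_cov.normal(config.cohort.age_mean, config.cohort.age_sd, size=n).clip(18.0, 95.0)
    tnm = rng_cov.choice(
        np.arange(1, len(config.cohort.tnm_probs) + 1), size=n, p=config.cohort.tnm_probs
    )
    # The hazard-driving immune score combines overall infiltration with
    # tumor penetration, so both per-ROI categories and inner/outer
    # ratios carry prognostic signal (high score = protective).
    score = np.log(levels) + penetration
    group_high = (score > 0.0).astype(int)
    outcomes = simulate_outcomes(
        group_high, age, tnm, config.cohort, substream(config.seed, "outcomes")
    )
    cohort = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:03d}" for i in range(n)],
            "age": age,
            "tnm_stage": tnm,
            "immune_level": levels,
            "group": np.where(group_high == 1, "high", "low"),
        }
    )
    cohort = pd.concat([cohort, outcomes], axis=1)

    detections = {}
    for i, pid in enumerate(cohort["patient_id"]):
        per_marker = []
        for marker in config.markers:
            pts = sample_cells(
                section, profiles[i][marker], substream(config.seed, "points", pid, marker)
            )
            per_marker.append(pts)
        detections[pid] = pd.concat(per_marker, ignore_index=True)
    return {"section": section, "cohort": cohort, "detections": detections}


def count_study(config: RunConfig, section: TissueSection, detections: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stereological Q_A for every patient x marker x ROI.

    Returns the tidy density table and the raw margin count table used
    for count-pooled entire-margin densities.  TC/NT frame sizes adapt
    to a pilot density read off the detections themselves.
    """
    part = section.partition
    rows = []
    for pid, pts in detections.items():
        for marker in config.markers:
            mpts = pts[pts["marker"] == marker]
            for roi in part.rois:
                roi_pts = mpts[mpts["roi"] == roi] if "roi" in mpts.columns else mpts
                area = part.area_mm2(roi)
                if area == 0:
                    continue
                pilot = len(roi_pts) / area
                design = default_design(roi, expected_density_per_mm2=pilot)
                res = estimate_roi_qa(
                    roi_pts,
                    part.mask(roi),
                    part.roi_pixel_size(roi),
                    design,
                    substream(config.seed, "fov", pid, marker, roi),
                    patient_id=pid,
                    marker=marker,
                    roi=roi,
                )
                rows.append(
                    {
                        "patient_id": pid,
                        "marker": marker,
                        "roi": roi,
                        "counted_profiles": res.counted_profiles,
                        "total_frame_area_um2": res.total_frame_area_um2,
                        "qa": res.qa_per_mm2,
                        "n_fov": res.n_fov,
                        "warnings": "; ".join(res.warnings),
                    }
                )
    density = pd.DataFrame(rows)
    margin_counts = density[density["roi"].isin(["innM", "outM"])][
        ["patient_id", "marker", "roi", "counted_profiles", "total_frame_area_um2"]
    ]
    return density, margin_counts


def associate(config: RunConfig, features: pd.DataFrame, cohort: pd.DataFrame, density: pd.DataFrame) -> dict:
    """The survival battery over the scored features."""
    eps = endpoint_table(cohort.set_index("patient_id")).rename_axis("patient_id")
    data = features.join(eps).join(
        cohort.set_index("patient_id")[["age", "tnm_stage"]]
    )

    cat_features = [c for c in features.columns if c.endswith("_cat")]
    ratio_features = [c for c in features.columns if c.endswith("_median_group")]

    univariable: dict[str, dict[str, CoxResult]] = {}
    for feat in cat_features + ratio_features:
        per_ep = {}
        for ep in config.endpoints:
            per_ep[ep] = cox_univariable(
                data[f"{ep}_time"], data[f"{ep}_event"], data[feat], term=feat
            )
        univariable[feat] = per_ep

    # Multivariable models (TTR, adjusted for age and TNM) for features
    # significant in the univariable TTR analysis.
    multivariable: dict[str, CoxResult] = {}
    for feat, per_ep in univariable.items():
        res = per_ep.get("TTR")
        if res is not None and res.ok and res.type3_p < 0.05:
            multivariable[feat] = cox_multivariable(
                data, "TTR_time", "TTR_event", feat
            )

    followup = inverse_km_followup(data["OS_time"], data["OS_event"])

    regions = {}
    correlations = {}
    wide = density.pivot_table(index="patient_id", columns=["marker", "roi"], values="qa")
    for marker in config.markers:
        sub = wide[marker]
        roi_cols = [r for r in ("TC", "innM", "outM", "PT") if r in sub.columns]
        if len(roi_cols) >= 2:
            regions[marker] = region_comparison(sub[roi_cols])
        if {"TC", "innM", "outM"} <= set(sub.columns):
            ratio = sub["innM"] / sub["outM"].replace(0.0, np.nan)
            correlations[f"{marker}_innM_over_outM_vs_TC"] = correlate(ratio, sub["TC"])
    return {
        "univariable": univariable,
        "multivariable": multivariable,
        "followup": followup,
        "regions": regions,
        "correlations": correlations,
    }


def _cox_rows(feature: str, result: CoxResult, endpoint: str) -> list[dict]:
    if not result.ok:
        return [
            {
                "feature": feature,
                "endpoint": endpoint,
                "level": "NA",
                "HR": f"NA ({'; '.join(result.flags)})",
                "CI95_low": "NA",
                "CI95_high": "NA",
                "p": "NA",
                "type3_p": "NA",
                "n": result.n,
            }
        ]
    return [
        {
            "feature": feature,
            "endpoint": endpoint,
            "level": eff.level,
            "HR": round(eff.hazard_ratio, 4),
            "CI95_low": round(eff.ci_low, 4),
            "CI95_high": round(eff.ci_high, 4),
            "p": round(eff.p, 5),
            "type3_p": round(result.type3_p, 5),
            "n": result.n,
        }
        for eff in result.levels
    ]


def make_report(stats: dict, cutpoints: dict) -> dict[str, pd.DataFrame]:
    """Render the association results as flat tables.

    table1: per-ROI percentile-category features; table2: median-split
    inter-ROI ratios (median cutpoint echoed per row); table3:
    age/TNM-adjusted models for univariably significant features.
    Flagged (non-converged or degenerate) fits appear as "NA (reason)".
    """
    t1, t2 = [], []
    for feat, per_ep in stats["univariable"].items():
        for ep, res in per_ep.items():
            rows = _cox_rows(feat, res, ep)
            if feat.endswith("_median_group"):
                med = cutpoints.get(feat, {}).get("median")
                for r in rows:
                    r["median_cutpoint"] = round(med, 4) if med is not None else "NA"
                t2.extend(rows)
            else:
                t1.extend(rows)
    t3 = []
    for feat, res in stats["multivariable"].items():
        t3.extend(_cox_rows(feat, res, "TTR"))
    cols1 = ["feature", "endpoint", "level", "HR", "CI95_low", "CI95_high", "p", "type3_p", "n"]
    return {
        "table1_categories": pd.DataFrame(t1, columns=cols1),
        "table2_ratios": pd.DataFrame(t2, columns=cols1 + ["median_cutpoint"]),
        "table3_adjusted": pd.DataFrame(t3, columns=cols1),
    }


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic:
        study = synthesize_study(config)
        section, cohort, detections = (
            study["section"],
            study["cohort"],
            study["detections"],
        )
        imio.write_mask(out / "section.tif", section)
        imio.write_partition(out, section.partition, "section")
        part = section.partition
        if part.nt_mask is not None:
            from immunomargin.geometry import LABEL_LIVER

            nt = TissueSection(
                labels=(part.nt_mask * LABEL_LIVER).astype(np.uint8),
                pixel_size_um=part.nt_pixel_size_um,
            )
            imio.write_mask(out / "nt.tif", nt)
        cohort.to_csv(out / "cohort.csv", index=False)
    else:
        raise NotImplementedError(
            "real-input mode: load masks/detections with immunomargin.io and "
            "call the stage functions directly"
        )

    density, margin_counts = count_study(config, section, detections)
    density.to_csv(out / "density_table.csv", index=False)

    features, cutpoints = score_cohort(density, margin_counts)
    features.to_csv(out / "features.csv")
    (out / "cutpoints.json").write_text(json.dumps(cutpoints, indent=2, default=float))

    stats = associate(config, features, cohort, density)
    tables = make_report(stats, cutpoints)
    for name, table in tables.items():
        table.to_csv(out / f"{name}.csv", index=False)

    med, ci, fu_flags = stats["followup"]
    manifest = {
        "seed": config.seed,
        "config_sha256": config.digest(),
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_patients": config.n_patients,
        "median_followup_months": None if np.isnan(med) else round(med, 2),
        "followup_flags": fu_flags,
        "nt_present": section.partition.nt_mask is not None,
        "warnings": section.partition.warnings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {
        "section": section,
        "cohort": cohort,
        "density": density,
        "features": features,
        "cutpoints": cutpoints,
        "stats": stats,
        "tables": tables,
        "manifest": manifest,
    }
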