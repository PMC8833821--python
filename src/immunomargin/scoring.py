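"""Prognostic features derived from the density table.

Raw Q_A values are skewed, so the cohort analysis works on rank-based
transforms: three-level percentile categories (low < 25th percentile,
intermediate 25th-70th, high > 70th), a two-level split at the 25th
percentile (low vs intermediate-high), inter-ROI ratios of raw Q_A
dichotomized at the cohort median, a pooled entire-margin density, and a
four-group combination of the CD8 and CD20 two-level categories in the
inner margin.  A ratio of inner to outer margin density below 0.1 flags
the immune-excluded phenotype: lymphocytes mass at the border but fail
to penetrate the tumor.

Percentiles use average ranks for ties, scaled as rank / n * 100; the
middle interval is closed ([25, 70]) because the outer categories are
defined by strict inequalities.  Missing values are propagated, never
imputed; cutpoints are recorded for audit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from immunomargin.stereology import CountResult

IMMUNE_EXCLUDED_THRESHOLD = 0.1

THREE_LEVELS = ("low", "intermediate", "high")
TWO_LEVELS = ("low", "intermediate-high")
MEDIAN_LEVELS = ("under-median", "above-median")

COMBINED_GROUPS = (
    "both intermediate-high",
    "only CD20 intermediate-high",
    "only CD8 intermediate-high",
    "both low",
)


@dataclass
class CategoryAssignment:
    """Per-patient category labels plus the cutpoints that produced them."""

    feature: str
    levels: pd.Series  # index: patient_id; values: category labels (or NaN)
    cutpoints: dict[str, float]
    warnings: list[str]


@dataclass
class RatioFeature:
    """An inter-ROI density ratio for one patient and marker."""

    patient_id: str | None
    marker: str | None
    numerator_roi: str | None
    denominator_roi: str | None
    ratio: float  # NaN when undefined (denominator 0 or missing input)

    @property
    def immune_excluded(self) -> bool | None:
        if np.isnan(self.ratio):
            return None
        return bool(self.ratio < IMMUNE_EXCLUDED_THRESHOLD)


def rank_percentiles(values: pd.Series) -> pd.Series:
    """Rank-based percentile of each non-missing value: rank / n * 100.

    Ties receive average ranks, so equal values get equal percentiles.
    """
    v = values.dropna()
    ranks = stats.rankdata(v.to_numpy(), method="average")
    pct = pd.Series(ranks / len(v) * 100.0, index=v.index)
    return pct.reindex(values.index)


def percentile_categorize(
    values: pd.Series,
    cuts: tuple[float, float] = (25.0, 70.0),
    two_level: bool = False,
    feature: str = "qa",
) -> CategoryAssignment:
    """Assign low / intermediate / high by rank percentile.

    low: percentile < cuts[0]; high: percentile > cuts[1]; intermediate
    otherwise (the middle interval is closed).  ``two_level`` merges
    intermediate and high into a single level at the lower cut.
    """
    values = pd.Series(values)
    non_missing = values.dropna()
    if len(non_missing) < 4:
        raise ValueError("percentile categories need >= 4 non-missing values")
    warn: list[str] = []
    pct = rank_percentiles(values)
    if non_missing.nunique() == 1:
        warn.append("all values identical; every patient assigned intermediate")
        mid = TWO_LEVELS[1] if two_level else "intermediate"
        levels = pd.Series(
            np.where(values.notna(), mid, None), index=values.index, dtype=object
        )
        return CategoryAssignment(feature, levels, {"cuts": cuts}, warn)

    if two_level:
        labels = np.where(pct < cuts[0], TWO_LEVELS[0], TWO_LEVELS[1])
    else:
        labels = np.where(
            pct < cuts[0], "low", np.where(pct > cuts[1], "high", "intermediate")
        )
    levels = pd.Series(labels, index=values.index, dtype=object).where(values.notna())
    return CategoryAssignment(feature, levels, {"cuts": cuts}, warn)


def dichotomize_at_median(values: pd.Series, feature: str = "ratio") -> CategoryAssignment:
    """Split at the sample median: strictly greater -> above-median.

    Ties at the median go under-median (the reported thresholds are
    strict '>' cutoffs).  The median is stored for audit.
    """
    values = pd.Series(values)
    non_missing = values.dropna()
    if len(non_missing) < 2:
        raise ValueError("median dichotomization needs >= 2 non-missing values")
    warn: list[str] = []
    med = float(np.median(non_missing))
    if non_missing.nunique() == 1:
        warn.append("all values identical; every patient under-median")
    labels = np.where(values > med, MEDIAN_LEVELS[1], MEDIAN_LEVELS[0])
    levels = pd.Series(labels, index=values.index, dtype=object).where(values.notna())
    return CategoryAssignment(feature, levels, {"median": med}, warn)


def compute_ratio(
    qa_numerator: float,
    qa_denominator: float,
    patient_id: str | None = None,
    marker: str | None = None,
    numerator_roi: str | None = None,
    denominator_roi: str | None = None,
) -> RatioFeature:
    """Ratio of two Q_A values; undefined (NaN) when the denominator is 0."""
    if (
        qa_numerator is None
        or qa_denominator is None
        or np.isnan(qa_numerator)
        or np.isnan(qa_denominator)
        or qa_denominator == 0
    ):
        ratio = float("nan")
    else:
        ratio = float(qa_numerator) / float(qa_denominator)
    return RatioFeature(patient_id, marker, numerator_roi, denominator_roi, ratio)


def entire_margin_qa(inn: CountResult, out: CountResult) -> float:
    """Pooled margin density: total counts over total frame area.

    Equivalent to the area-weighted mean of the two bands' Q_A; NaN if
    either side is missing.
    """
    if inn is None or out is None:
        return float("nan")
    total_area = inn.total_frame_area_um2 + out.total_frame_area_um2
    return (inn.counted_profiles + out.counted_profiles) / total_area * 1e6


def combined_cd8_cd20_group(cd8_level: str | None, cd20_level: str | None) -> str | None:
    """2x2 grouping of the two-level CD8 and CD20 inner-margin categories."""
    if cd8_level is None or cd20_level is None:
        return None
    if isinstance(cd8_level, float) or isinstance(cd20_level, float):  # NaN
        return None
    high = TWO_LEVELS[1]
    if cd8_level == high and cd20_level == high:
        return COMBINED_GROUPS[0]
    if cd20_level == high:
        return COMBINED_GROUPS[1]
    if cd8_level == high:
        return COMBINED_GROUPS[2]
    return COMBINED_GROUPS[3]


RATIO_PAIRS = (("innM", "outM"), ("TC", "outM"), ("TC", "M"), ("TC", "PT"))


def score_cohort(
    density: pd.DataFrame,
    margin_counts: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Build the full feature table from a tidy density table.

    Parameters
    ----------
    density:
        Tidy table with columns ``patient_id, marker, roi, qa`` (one row
        per combination; missing ROIs simply absent).
    margin_counts:
        Optional tidy table ``patient_id, marker, roi, counted_profiles,
        total_frame_area_um2`` for innM/outM, used to pool the entire
        margin ("M") by raw counts.  Without it, M is the unweighted
        mean of the two band densities (equal design areas).

    Returns
    -------
    (features, cutpoints):
        ``features`` is one row per patient with one column per feature;
        ``cutpoints`` records every percentile cut and median used.
    """
    wide = density.pivot_table(
        index="patient_id", columns=["marker", "roi"], values="qa", aggfunc="first"
    )
    patients = wide.index
    features = pd.DataFrame(index=patients)
    cutlog: dict[str, dict] = {}

    markers = sorted({m for m, _ in wide.columns})
    for marker in markers:
        sub = wide[marker]
        # Entire margin M: count-pooled when raw counts are available.
        if margin_counts is not None:
            mc = margin_counts[margin_counts["marker"] == marker]
            pooled = (
                mc.groupby("patient_id")[["counted_profiles", "total_frame_area_um2"]]
                .sum()
                .assign(M=lambda d: d.counted_profiles / d.total_frame_area_um2 * 1e6)
            )["M"]
            sub = sub.assign(M=pooled.reindex(patients))
        elif {"innM", "outM"} <= set(sub.columns):
            sub = sub.assign(M=sub[["innM", "outM"]].mean(axis=1, skipna=False))

        for roi in [r for r in ("TC", "innM", "outM", "PT", "NT") if r in sub.columns]:
            name = f"{marker}_{roi}"
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cat3 = percentile_categorize(sub[roi], feature=name)
            features[f"{name}_cat"] = cat3.levels
            cutlog[f"{name}_cat"] = cat3.cutpoints
            cat2 = percentile_categorize(sub[roi], two_level=True, feature=name)
            features[f"{name}_cat2"] = cat2.levels

        for num, den in RATIO_PAIRS:
            if num not in sub.columns or den not in sub.columns:
                continue
            name = f"{marker}_{num}_over_{den}"
            ratio = sub[num] / sub[den].replace(0.0, np.nan)
            features[f"{name}_ratio"] = ratio
            if ratio.notna().sum() >= 2:
                dich = dichotomize_at_median(ratio, feature=name)
                features[f"{name}_median_group"] = dich.levels
                cutlog[f"{name}_median_group"] = dich.cutpoints
            if (num, den) == ("innM", "outM"):
                features[f"{marker}_immune_excluded"] = (
                    ratio < IMMUNE_EXCLUDED_THRESHOLD
                ).where(ratio.notna())

    if {"CD8_innM_cat2", "CD20_innM_cat2"} <= set(features.columns):
        features["CD8_CD20_innM_group"] = [
            combined_cd8_cd20_group(c8, c20)
            for c8, c20 in zip(features["CD8_innM_cat2"], features["CD20_innM_cat2"])
        ]
    return features, cutlog
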