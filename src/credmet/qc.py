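"""Internal-standard normalization and quality-control filters.

Reimplements the consolidation script used for targeted LC-MS data:

1. per-sample normalization to the averaged factor of mean-centered
   internal-standard peak areas;
2. removal of metabolites whose pooled-QC dilution series is not linear
   (R² of area vs dilution factor at or below ``rsq_min``);
3. removal of metabolites with pooled-QC coefficient of variation at or
   above ``cv_max``;
4. normalization for biological material amount by the averaged
   mean-centered area of high-confidence metabolites (the per-sample
   "scaling factor" reused by the untargeted analyses);

plus LoD imputation (one fifth of the minimum positive value per
variable) and the log / Pareto transform applied before multivariate
statistics, and a blood-contamination check based on the intracellular
marker glucose-6-phosphate.

"Mean-centered" is implemented as division by the cross-sample mean
(ratio-centering): subtraction could produce negative factors, which is
incompatible with factor semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import Config
from .model import FeatureTable


@dataclass
class NormalizationReport:
    """Factors applied and features removed during QC normalization."""

    is_factor: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    biomaterial_factor: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    removed_features: list[tuple[str, str, float]] = field(default_factory=list)
    n_high_confidence: int = 0


def compute_is_factor(table: FeatureTable, is_ids: list[str]) -> pd.Series:
    """Per-sample technical factor from spiked internal standards.

    Each internal standard's areas are divided by that standard's
    cross-sample mean; a sample's factor is the average of these
    centered values over all standards measured in it.
    """
    is_ids = [i for i in is_ids if i in table.features.index]
    if not is_ids:
        raise ValueError("no internal-standard features present in table")
    sub = table.areas.loc[is_ids]
    centered = sub.div(sub.mean(axis=1, skipna=True), axis=0)
    factor = centered.mean(axis=0, skipna=True)
    dead = factor.index[factor.isna()].tolist()
    if dead:
        raise ValueError(f"all internal standards missing in sample(s): {dead}")
    return factor.rename("is_factor")


def apply_factor(table: FeatureTable, factor: pd.Series) -> FeatureTable:
    """Divide every area by its sample's factor."""
    return table.with_areas(table.areas.div(factor, axis=1))


def dilution_rsq(areas: pd.Series, dilution: pd.Series) -> float:
    """R² of ordinary least squares of peak area on dilution factor."""
    ok = areas.notna()
    if ok.sum() < 3:
        return np.nan
    y = areas[ok].to_numpy(dtype=float)
    x = dilution[ok].to_numpy(dtype=float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        return 0.0
    res = sps.linregress(x, y)
    return float(res.rvalue**2)


def filter_by_dilution_rsq(table: FeatureTable, cfg: Config
                           ) -> tuple[FeatureTable, list[tuple[str, str, float]]]:
    """Drop features whose dilution-QC series is not linear (R² <= rsq_min)."""
    dil = table.samples.index[table.samples["role"] == "dilution_qc"]
    levels = set(np.round(table.samples.loc[dil, "dilution_factor"].astype(float), 6))
    if len(levels) < 3:
        raise ValueError("dilution-linearity filter requires >=3 distinct dilution factors")
    dilution = table.samples.loc[dil, "dilution_factor"].astype(float)
    removals = []
    keep = []
    for fid in table.features.index:
        rsq = dilution_rsq(table.areas.loc[fid, dil], dilution)
        if np.isnan(rsq) or rsq <= cfg.rsq_min:
            removals.append((fid, "rsq_fail", float(rsq)))
        else:
            keep.append(fid)
    return table.subset_features(keep), removals


def pool_cv(values: pd.Series, ddof: int = 0) -> float:
    """Coefficient of variation over pooled-QC injections, missing excluded."""
    v = values.dropna().to_numpy(dtype=float)
    if v.size == 0 or v.mean() == 0:
        return np.nan
    return float(v.std(ddof=ddof) / v.mean())


def filter_by_pool_cv(table: FeatureTable, cfg: Config
                      ) -> tuple[FeatureTable, list[tuple[str, str, float]]]:
    """Drop features with pooled-QC CV >= cv_max (or CV undefined)."""
    pools = table.sample_ids("pool_qc")
    if len(pools) < 3:
        raise ValueError("pool-CV filter requires >=3 pool_qc injections")
    removals = []
    keep = []
    for fid in table.features.index:
        cv = pool_cv(table.areas.loc[fid, pools], ddof=cfg.cv_ddof)
        if np.isnan(cv) or cv >= cfg.cv_max:
            removals.append((fid, "cv_fail", float(cv)))
        else:
            keep.append(fid)
    return table.subset_features(keep), removals


def biomaterial_normalize(table: FeatureTable, high_confidence_ids: list[str]
                          ) -> tuple[FeatureTable, pd.Series]:
    """Normalize for biological material amount.

    The per-sample "scaling factor" is the average of mean-centered
    areas over the high-confidence metabolite set; the table is divided
    through by it.  A sample with twice the biological material gets a
    factor of about 2 and normalizes back to baseline.
    """
    ids = [i for i in high_confidence_ids if i in table.features.index]
    if not ids:
        raise ValueError("high-confidence metabolite set is empty")
    sub = table.areas.loc[ids]
    centered = sub.div(sub.mean(axis=1, skipna=True), axis=0)
    factor = centered.mean(axis=0, skipna=True).rename("biomaterial_factor")
    if factor.isna().any():
        bad = factor.index[factor.isna()].tolist()
        raise ValueError(f"no high-confidence metabolite measured in sample(s): {bad}")
    return apply_factor(table, factor), factor


def impute_lod(matrix: pd.DataFrame, lod_fraction: float = 0.2) -> pd.DataFrame:
    """Fill missing cells with the per-feature limit of detection.

    Missing becomes ``min positive value x lod_fraction`` per feature;
    observed values (including zeros) are never altered.  A feature with
    no positive value is left missing.
    """
    out = matrix.copy()
    for fid in out.index:
        row = out.loc[fid]
        if not row.isna().any():
            continue
        positive = row[row > 0]
        if positive.empty:
            continue  # entirely missing/zero: left as-is, caller may flag
        out.loc[fid] = row.fillna(float(positive.min()) * lod_fraction)
    return out


def log_pareto(matrix: pd.DataFrame, base: float | None = None) -> pd.DataFrame:
    """Log transform then Pareto scale each feature row.

    Natural log by default; then per feature subtract the mean and
    divide by the square root of the (sample, ddof=1) standard
    deviation.  Constant rows scale to all zeros.
    """
    arr = matrix.to_numpy(dtype=float)
    bad = np.argwhere(~(arr > 0) & ~np.isnan(arr))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value at feature {matrix.index[i]!r}, "
            f"sample {matrix.columns[j]!r}: log transform undefined"
        )
    if np.isnan(arr).any():
        i, j = np.argwhere(np.isnan(arr))[0]
        raise ValueError(
            f"missing value at feature {matrix.index[i]!r}, sample "
            f"{matrix.columns[j]!r}: impute before transforming"
        )
    logged = np.log(arr) if base is None else np.log(arr) / np.log(base)
    centered = logged - logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = np.where(sd > 0, centered / np.sqrt(sd), centered)
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def blood_contamination_check(table: FeatureTable, reference: FeatureTable,
                              marker_feature_id: str,
                              threshold: float = 0.1) -> tuple[pd.Series, pd.Series]:
    """Flag samples whose glucose-6-phosphate level suggests blood carryover.

    The marker (an intracellular metabolite abundant in lysis-prone red
    blood cells, absent from clean CSF) is compared per test sample
    against its median level in the plasma-like reference table; samples
    whose ratio exceeds ``threshold`` are flagged.
    """
    if marker_feature_id not in table.features.index:
        raise ValueError(f"marker {marker_feature_id!r} absent from test table")
    if marker_feature_id not in reference.features.index:
        raise ValueError(f"marker {marker_feature_id!r} absent from reference table")
    ref_med = float(reference.areas.loc[marker_feature_id].median(skipna=True))
    if not np.isfinite(ref_med) or ref_med <= 0:
        raise ValueError("reference marker level is zero or missing everywhere")
    ratio = (table.areas.loc[marker_feature_id].fillna(0.0) / ref_med).rename("g6p_ratio")
    return ratio, (ratio >= threshold).rename("contaminated")


def normalize_pipeline(table: FeatureTable, is_ids: list[str],
                       high_confidence_ids: list[str], cfg: Config
                       ) -> tuple[FeatureTable, NormalizationReport]:
    """Run the fixed QC-normalization stage order.

    is-factor → dilution-RSQ filter → pool-CV filter → biomaterial
    factor.  (LoD imputation and log/Pareto are applied separately, only
    on the way into multivariate statistics.)
    """
    report = NormalizationReport()
    report.is_factor = compute_is_factor(table, is_ids)
    norm = apply_factor(table, report.is_factor)
    norm, rsq_removed = filter_by_dilution_rsq(norm, cfg)
    report.removed_features.extend(rsq_removed)
    norm, cv_removed = filter_by_pool_cv(norm, cfg)
    report.removed_features.extend(cv_removed)
    hc = [i for i in high_confidence_ids if i in norm.features.index]
    report.n_high_confidence = len(hc)
    norm, report.biomaterial_factor = biomaterial_normalize(norm, hc)
    return norm, report
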