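"""Feature credentialing: mock filtering and isotope-pair (IROA) pairing.

Two independent strategies decide which detected features are true
biological signals rather than shared background:

* **Mock filtering** compares each feature's mean abundance in
  biological samples against empty-tube mock extractions; features more
  than ``mock_fold_threshold``-fold higher in samples (strict ``>``) and
  above the minimum credible intensity are retained.
* **IROA credentialing** searches, for each candidate light (12C)
  feature, a co-eluting heavy partner shifted by exactly
  ``n x 1.0033548 Da`` for some carbon count ``n``; only features with a
  matched heavy signal from the 13C-labeled reference metabolome are
  retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import Config
from .formulas import ppm_error
from .model import FeatureTable

REASONS = ("below_min_intensity", "mock_ratio_below_threshold", "retained_fold",
           "retained_absent_in_mock", "iroa_paired", "iroa_unpaired")
RETAIN_REASONS = ("retained_fold", "retained_absent_in_mock", "iroa_paired")


@dataclass
class CredentialReport:
    """Why one feature was retained or rejected."""

    feature_id: str
    decision: str  # retained | rejected
    reason: str
    sample_mock_ratio: float | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.decision not in ("retained", "rejected"):
            raise ValueError(f"bad decision {self.decision!r}")
        if self.reason not in REASONS:
            raise ValueError(f"bad reason {self.reason!r}")
        if self.decision == "retained" and self.reason not in RETAIN_REASONS:
            raise ValueError(f"retained feature with non-retain reason {self.reason!r}")


@dataclass
class IroaPair:
    """A matched light/heavy isotopologue pair."""

    light_feature_id: str
    heavy_feature_id: str
    carbon_count: int
    ppm_error: float
    rt_delta: float  # seconds
    ratio: float  # heavy/light mean intensity


def reports_to_frame(reports: list[CredentialReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in reports],
            "decision": [r.decision for r in reports],
            "reason": [r.reason for r in reports],
            "sample_mock_ratio": [r.sample_mock_ratio for r in reports],
            "p_value": [r.p_value for r in reports],
        }
    ).set_index("feature_id")


def retained_ids(reports: list[CredentialReport]) -> list[str]:
    return [r.feature_id for r in reports if r.decision == "retained"]


def mock_filter(table: FeatureTable, cfg: Config) -> list[CredentialReport]:
    """Credential features by their sample/mock abundance ratio.

    Per feature, the mean area over biological samples is compared with
    the mean over mock samples; missing cells are replaced by the noise
    floor (smallest positive area in the table times ``lod_fraction``).
    Retention requires ``bio_mean / mock_mean > mock_fold_threshold``
    (strict) and ``bio_mean >= min_intensity``.  A feature absent from
    every mock is retained on the intensity gate alone.  A Welch t
    p-value is reported when both sides have at least three samples, and
    optionally gated on via ``cfg.welch_gate_p``.
    """
    bio = table.sample_ids("biological")
    mock = table.sample_ids("mock")
    if not mock:
        raise ValueError("mock filtering requires at least one mock sample")
    if not bio:
        raise ValueError("mock filtering requires at least one biological sample")

    arr = table.areas.to_numpy()
    positive = arr[np.isfinite(arr) & (arr > 0)]
    eps = float(positive.min()) * cfg.lod_fraction if positive.size else np.nan

    reports = []
    for fid in table.features.index:
        bio_vals = table.areas.loc[fid, bio].to_numpy(dtype=float)
        mock_vals = table.areas.loc[fid, mock].to_numpy(dtype=float)
        absent_in_mock = bool(np.all(np.isnan(mock_vals)))
        bio_f = np.where(np.isnan(bio_vals), eps, bio_vals)
        mock_f = np.where(np.isnan(mock_vals), eps, mock_vals)
        bio_mean = float(bio_f.mean())
        mock_mean = float(mock_f.mean())
        ratio = bio_mean / mock_mean if mock_mean > 0 else np.inf

        p = None
        if len(bio_f) >= 3 and len(mock_f) >= 3:
            if np.ptp(bio_f) == 0 and np.ptp(mock_f) == 0:
                p = 1.0
            else:
                p = float(sps.ttest_ind(bio_f, mock_f, equal_var=False).pvalue)

        if bio_mean < cfg.min_intensity:
            reports.append(CredentialReport(fid, "rejected", "below_min_intensity",
                                            None if absent_in_mock else ratio, p))
            continue
        if absent_in_mock:
            reports.append(CredentialReport(fid, "retained", "retained_absent_in_mock",
                                            None, p))
            continue
        passes = ratio > cfg.mock_fold_threshold
        if passes and cfg.welch_gate_p is not None:
            passes = p is not None and p < cfg.welch_gate_p
        if passes:
            reports.append(CredentialReport(fid, "retained", "retained_fold", ratio, p))
        else:
            reports.append(CredentialReport(fid, "rejected", "mock_ratio_below_threshold",
                                            ratio, p))
    return reports


def iroa_credential(
    table: FeatureTable, cfg: Config,
    formulas_known: dict[str, str] | None = None,
) -> tuple[list[IroaPair], list[CredentialReport]]:
    """Credential features by matched 13C heavy partners.

    For every candidate light feature ``f`` the search visits features
    ``g`` with retention time within ``rt_tol`` and
    ``mz(g) = mz(f) + n x carbon_mass_delta`` for an integer carbon
    count ``n`` in ``[1, iroa_max_carbons]`` within ``ppm_tol`` (ppm
    computed on the heavier m/z).  Both partners must exceed
    ``min_intensity``.  Among multiple candidates the smallest
    ``|ppm_error|`` wins, ties broken by smallest ``|rt_delta|``.  Heavy
    partners consumed by a pair are not themselves credentialed.
    """
    fids = list(table.features.index)
    mzs = table.features["mz"].to_numpy(dtype=float)
    rts = table.features["rt"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        mean_area = np.nanmean(table.areas.to_numpy(dtype=float), axis=1)
    mean_area = np.where(np.isfinite(mean_area), mean_area, 0.0)
    intense = mean_area >= cfg.min_intensity
    rt_tol_min = cfg.rt_tol_min
    delta = cfg.carbon_mass_delta
    n_max = cfg.iroa_max_carbons

    order = np.argsort(mzs, kind="stable")
    pairs: list[IroaPair] = []
    paired_light: dict[str, IroaPair] = {}
    used_heavy: set[str] = set()

    for i in order:
        fid = fids[i]
        if not intense[i] or fid in used_heavy:
            continue
        best: tuple[float, float, int, int] | None = None  # (|ppm|, |drt|, j, n)
        for j in range(len(fids)):
            if j == i or not intense[j] or fids[j] in used_heavy or fids[j] in paired_light:
                continue
            if mzs[j] <= mzs[i]:
                continue
            if abs(rts[j] - rts[i]) > rt_tol_min:
                continue
            n = int(round((mzs[j] - mzs[i]) / delta))
            if n < 1 or n > n_max:
                continue
            err = ppm_error(mzs[j], mzs[i] + n * delta)
            if abs(err) > cfg.ppm_tol:
                continue
            key = (abs(err), abs(rts[j] - rts[i]))
            if best is None or key < (best[0], best[1]):
                best = (abs(err), abs(rts[j] - rts[i]), j, n)
        if best is not None:
            _, _, j, n = best
            err = ppm_error(mzs[j], mzs[i] + n * delta)
            light_mean = mean_area[i]
            ratio = mean_area[j] / light_mean if light_mean > 0 else np.inf
            pair = IroaPair(fid, fids[j], n, float(err),
                            float((rts[j] - rts[i]) * 60.0), float(ratio))
            pairs.append(pair)
            paired_light[fid] = pair
            used_heavy.add(fids[j])

    reports = []
    for i, fid in enumerate(fids):
        if fid in paired_light:
            reports.append(CredentialReport(fid, "retained", "iroa_paired"))
        elif not intense[i]:
            reports.append(CredentialReport(fid, "rejected", "below_min_intensity"))
        else:
            reports.append(CredentialReport(fid, "rejected", "iroa_unpaired"))
    return pairs, reports
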