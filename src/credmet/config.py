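"""Pipeline configuration.

All numeric parameters of the pipeline live here so that every stage is
driven by one explicit, serializable object.  Defaults follow the values
used throughout the study design this package implements: a 3-fold
sample/mock abundance gate, 5 ppm mass tolerance, 40 s retention-time
tolerance, dilution-linearity RSQ > 0.95, pooled-QC CV < 30 %, LoD
imputation at one fifth of the minimum positive value, a minimum signal
intensity of 10,000 area units, and Top-8 data-dependent acquisition with
a 6 s dynamic-exclusion window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

#: Mass difference between 13C and 12C, Da (physical constant).
CARBON_MASS_DELTA = 1.0033548378

#: Proton mass, Da, used for [M+H]+ / [M-H]- adduct arithmetic.
PROTON_MASS = 1.007276466

#: Monoisotopic mass of water, Da, for the optional [M-H2O-H]- adduct.
WATER_MASS = 18.0105646863


@dataclass
class Config:
    """Numeric parameters shared by all pipeline stages.

    Attributes
    ----------
    mock_fold_threshold : float
        Sample/mock mean-ratio above which a feature is credentialed
        (strict ``>``), default 3.
    ppm_tol : float
        Mass tolerance in parts per million for MS1 matching and isotope
        pairing, default 5.
    rt_tol : float
        Retention-time tolerance in **seconds** for library matching and
        isotope-pair co-elution, default 40.  Converted to minutes at the
        point of use (retention times are stored in minutes).
    rt_align_max : float
        Maximum credible retention-time shift in seconds, default 60;
        informational (alignment itself is upstream of this package).
    rsq_min : float
        Minimum R² of peak area vs dilution factor, default 0.95.
    cv_max : float
        Maximum pooled-QC coefficient of variation, default 0.30.
    lod_fraction : float
        Fraction of the minimum positive value used for LoD imputation
        and for the mock noise floor, default 1/5.
    iqr_filter_frac : float
        Fraction of lowest-IQR features removed before multivariate
        statistics, default 0.05.
    min_intensity : float
        Minimal credible signal intensity in area units, default 10000.
    carbon_mass_delta : float
        13C-12C mass difference, Da.
    dda_top_n : int
        Precursors fragmented per MS1 scan in DDA, default 8.
    dda_exclusion_s : float
        DDA dynamic-exclusion window, seconds, default 6.
    labeling_purity : float
        13C enrichment of the labeled reference metabolome, default 0.95.
    ms2_score_min : float
        Cosine similarity at or above which an MS2 match counts as
        identification evidence, default 0.7.
    welch_gate_p : float | None
        Optional significance gate for mock filtering (Welch p below this
        value required in addition to the fold gate); ``None`` disables.
    use_water_loss_adduct : bool
        Enable the [M-H2O-H]- adduct in negative-mode matching.
    log_base : float | None
        Base for the log transform before Pareto scaling; ``None`` means
        natural log.
    cv_ddof : int
        Degrees-of-freedom correction for the pooled-QC CV (0 =
        population sd, the default convention; 1 = sample sd).
    iroa_max_carbons : int
        Largest carbon count searched during isotope pairing, default 60.
    rng_seed : int
        Seed for every stochastic component.
    """

    mock_fold_threshold: float = 3.0
    ppm_tol: float = 5.0
    rt_tol: float = 40.0
    rt_align_max: float = 60.0
    rsq_min: float = 0.95
    cv_max: float = 0.30
    lod_fraction: float = 0.2
    iqr_filter_frac: float = 0.05
    min_intensity: float = 10000.0
    carbon_mass_delta: float = CARBON_MASS_DELTA
    dda_top_n: int = 8
    dda_exclusion_s: float = 6.0
    labeling_purity: float = 0.95
    ms2_score_min: float = 0.7
    welch_gate_p: float | None = None
    use_water_loss_adduct: bool = False
    log_base: float | None = None
    cv_ddof: int = 0
    iroa_max_carbons: int = 60
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mock_fold_threshold", "ppm_tol", "rt_tol", "rt_align_max",
                     "rsq_min", "cv_max", "min_intensity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Config.{name} must be strictly positive")
        if not 0 < self.lod_fraction < 1:
            raise ValueError("lod_fraction must lie in (0, 1)")
        if not 0 <= self.iqr_filter_frac < 1:
            raise ValueError("iqr_filter_frac must lie in [0, 1)")

    @property
    def rt_tol_min(self) -> float:
        """Retention-time tolerance converted to minutes."""
        return self.rt_tol / 60.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
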