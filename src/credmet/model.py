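"""Domain containers shared by every pipeline stage.

The universal currency is the :class:`FeatureTable`: an aligned LC-MS
feature × sample peak-area matrix plus feature coordinates (m/z,
retention time, polarity) and sample metadata.  Internally it is
pandas-backed in the AnnData spirit — ``features`` (var), ``samples``
(obs) and ``areas`` (X, with ``NaN`` meaning *missing*, which is kept
strictly distinct from an integrated area of zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

POLARITIES = ("negative", "positive")
ROLES = ("biological", "mock", "pool_qc", "dilution_qc")
DILUTION_FACTORS = (1.0, 1.0 / 3.0, 0.1)


@dataclass
class Feature:
    """One detected LC-MS signal."""

    feature_id: str
    mz: float
    rt: float  # minutes
    polarity: str
    areas: dict[str, float | None] = field(default_factory=dict)
    formula: str | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"feature {self.feature_id}: mz must be > 0")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: rt must be >= 0")
        if self.polarity not in POLARITIES:
            raise ValueError(f"feature {self.feature_id}: bad polarity {self.polarity!r}")
        for sid, area in self.areas.items():
            if area is not None and area < 0:
                raise ValueError(f"feature {self.feature_id}: negative area in {sid}")


@dataclass
class SampleMeta:
    """Metadata for one injected sample."""

    sample_id: str
    role: str = "biological"
    group: str | None = None
    batch: str | None = None
    dilution_factor: float = 1.0
    timepoint: float | None = None  # minutes
    compartment: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"sample {self.sample_id}: bad role {self.role!r}")
        if self.role == "dilution_qc":
            if not any(np.isclose(self.dilution_factor, d, rtol=1e-6) for d in DILUTION_FACTORS):
                raise ValueError(
                    f"sample {self.sample_id}: dilution_factor must be 1, 1/3 or 1/10, "
                    f"got {self.dilution_factor}"
                )
        if self.dilution_factor <= 0:
            raise ValueError(f"sample {self.sample_id}: dilution_factor must be positive")


class FeatureTable:
    """Aligned features × samples peak-area matrix with metadata.

    Parameters
    ----------
    features : pandas.DataFrame
        Indexed by ``feature_id``; columns ``mz``, ``rt``, ``polarity``
        and optionally ``formula``.
    samples : pandas.DataFrame
        Indexed by ``sample_id``; columns ``role``, ``group``, ``batch``,
        ``dilution_factor``, ``timepoint``, ``compartment``.
    areas : pandas.DataFrame
        Shape (n_features, n_samples); ``NaN`` encodes a missing
        (below-detection) cell, zero a genuine zero-area integration.
    """

    SAMPLE_COLUMNS = ("role", "group", "batch", "dilution_factor", "timepoint", "compartment")

    def __init__(self, features: pd.DataFrame, samples: pd.DataFrame, areas: pd.DataFrame):
        self.features = features
        self.samples = samples
        self.areas = areas
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, features: list[Feature], samples: list[SampleMeta]) -> "FeatureTable":
        fids = [f.feature_id for f in features]
        sids = [s.sample_id for s in samples]
        fdf = pd.DataFrame(
            {
                "mz": [f.mz for f in features],
                "rt": [f.rt for f in features],
                "polarity": [f.polarity for f in features],
                "formula": [f.formula for f in features],
            },
            index=pd.Index(fids, name="feature_id"),
        )
        sdf = pd.DataFrame(
            {
                "role": [s.role for s in samples],
                "group": [s.group for s in samples],
                "batch": [s.batch for s in samples],
                "dilution_factor": [s.dilution_factor for s in samples],
                "timepoint": [s.timepoint for s in samples],
                "compartment": [s.compartment for s in samples],
            },
            index=pd.Index(sids, name="sample_id"),
        )
        areas = pd.DataFrame(np.nan, index=fdf.index, columns=sdf.index, dtype=float)
        for f in features:
            for sid, area in f.areas.items():
                if sid not in areas.columns:
                    raise ValueError(
                        f"feature {f.feature_id} has an area for undeclared sample {sid!r}"
                    )
                if area is not None:
                    areas.loc[f.feature_id, sid] = area
        return cls(fdf, sdf, areas)

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if self.features.index.has_duplicates:
            dups = self.features.index[self.features.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature_ids: {dups}")
        if self.samples.index.has_duplicates:
            dups = self.samples.index[self.samples.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample_ids: {dups}")
        if not self.areas.index.equals(self.features.index):
            raise ValueError("areas rows do not match feature index")
        if not self.areas.columns.equals(self.samples.index):
            raise ValueError("areas columns do not match sample index")
        bad_pol = set(self.features["polarity"]) - set(POLARITIES)
        if bad_pol:
            raise ValueError(f"bad polarity values: {sorted(bad_pol)}")
        if (self.features["mz"] <= 0).any():
            bad = self.features.index[self.features["mz"] <= 0].tolist()
            raise ValueError(f"non-positive mz for features: {bad}")
        if (self.features["rt"] < 0).any():
            bad = self.features.index[self.features["rt"] < 0].tolist()
            raise ValueError(f"negative rt for features: {bad}")
        bad_role = set(self.samples["role"]) - set(ROLES)
        if bad_role:
            raise ValueError(f"bad sample roles: {sorted(bad_role)}")
        with np.errstate(invalid="ignore"):
            if (self.areas.to_numpy() < 0).any():
                raise ValueError("negative peak areas present")

    # -- convenience ---------------------------------------------------

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_ids(self, role: str | None = None) -> list[str]:
        """Sample ids, optionally restricted to one role."""
        if role is None:
            return list(self.samples.index)
        return list(self.samples.index[self.samples["role"] == role])

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.features.copy(), self.samples.copy(), self.areas.copy())

    def subset_features(self, feature_ids) -> "FeatureTable":
        keep = self.features.index.intersection(pd.Index(feature_ids))
        # preserve original row order
        keep = self.features.index[self.features.index.isin(keep)]
        return FeatureTable(self.features.loc[keep].copy(), self.samples.copy(),
                            self.areas.loc[keep].copy())

    def with_areas(self, areas: pd.DataFrame) -> "FeatureTable":
        """Same metadata, new area matrix (must share both indexes)."""
        return FeatureTable(self.features.copy(), self.samples.copy(), areas)

    def equals(self, other: "FeatureTable") -> bool:
        same_meta = self.features.equals(other.features) and self.samples.equals(other.samples)
        a, b = self.areas.to_numpy(), other.areas.to_numpy()
        same_areas = (
            a.shape == b.shape
            and bool(np.all((np.isnan(a) & np.isnan(b)) | np.isclose(a, b, equal_nan=False,
                                                                     rtol=0, atol=1e-9)))
        )
        return same_meta and same_areas

    def __repr__(self) -> str:
        return f"FeatureTable({self.n_features} features × {self.n_samples} samples)"


@dataclass
class LibraryEntry:
    """One MS1 compound-library entry."""

    name: str
    formula: str | None
    monoisotopic_mass: float
    adducts: tuple[str, ...] = ("[M-H]-", "[M+H]+")
    rt: float | None = None  # minutes
    source: str = "house_ms1"

    def __post_init__(self) -> None:
        if self.formula:
            from .formulas import monoisotopic_mass as _mono

            expected = _mono(self.formula)
            if abs(expected - self.monoisotopic_mass) > 0.001:
                raise ValueError(
                    f"{self.name}: monoisotopic mass {self.monoisotopic_mass} inconsistent "
                    f"with formula {self.formula} ({expected:.5f})"
                )


@dataclass
class SpectrumRecord:
    """One MS2 spectrum: precursor, collision energy, relative-intensity peaks."""

    library_name: str
    precursor_mz: float
    polarity: str
    nce: str  # "20", "40", "80" or "averaged"
    peaks: list[tuple[float, float]]  # (mz, relative intensity 0-100), sorted by mz

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"{self.library_name}: spectrum has no peaks")
        mzs = [p[0] for p in self.peaks]
        if any(b < a for a, b in zip(mzs, mzs[1:])):
            self.peaks = sorted(self.peaks, key=lambda p: p[0])
        if any(p[1] < 0 for p in self.peaks):
            raise ValueError(f"{self.library_name}: negative peak intensity")

    def rescaled(self) -> "SpectrumRecord":
        """Copy with intensities scaled so the base peak is 100."""
        top = max(p[1] for p in self.peaks)
        if top == 0:
            return self
        peaks = [(mz, i / top * 100.0) for mz, i in self.peaks]
        return SpectrumRecord(self.library_name, self.precursor_mz, self.polarity,
                              self.nce, peaks)


def dilution_label(factor: float) -> str:
    """Human-readable dilution factor (1, 1/3, 1/10)."""
    return str(Fraction(factor).limit_denominator(10))
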