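"""Readers and writers for the pipeline's on-disk formats.

Feature tables, sample metadata and MS1 libraries travel as plain CSV
(comma-separated, UTF-8, mandatory header).  MS2 spectral libraries use
the community MSP and MGF formats, read and written through matchms.

A blank intensity cell means *missing* (below detection); ``0`` is a
genuine zero — the distinction is preserved on every round trip.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FeatureTable, LibraryEntry, SpectrumRecord

FEATURE_META_COLUMNS = ("feature_id", "mz", "rt", "polarity", "formula")
SAMPLE_COLUMNS = ("sample_id", "role", "group", "batch", "dilution_factor",
                  "timepoint", "compartment")


def read_feature_table(path: str | Path, meta_path: str | Path) -> FeatureTable:
    """Read a feature-table CSV plus its sample-metadata CSV.

    The feature CSV has one row per feature with columns ``feature_id``,
    ``mz``, ``rt``, ``polarity``, optionally ``formula``, and one column
    per sample.  Blank cells parse as missing.
    """
    raw = pd.read_csv(path, dtype={"feature_id": str})
    if "feature_id" not in raw.columns:
        raise ValueError(f"{path}: missing feature_id column")
    dup = raw["feature_id"][raw["feature_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate feature_id(s): {dup}")

    meta = pd.read_csv(meta_path, dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise ValueError(f"{meta_path}: missing sample_id column")
    dup = meta["sample_id"][meta["sample_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{meta_path}: duplicate sample_id(s): {dup}")
    meta = meta.set_index("sample_id")
    for col in ("role", "group", "batch", "compartment"):
        if col not in meta.columns:
            meta[col] = None
        else:
            meta[col] = meta[col].astype(object).where(meta[col].notna(), None)
    if "dilution_factor" not in meta.columns:
        meta["dilution_factor"] = 1.0
    meta["dilution_factor"] = meta["dilution_factor"].fillna(1.0).astype(float)
    if "timepoint" not in meta.columns:
        meta["timepoint"] = np.nan
    meta["role"] = meta["role"].fillna("biological")
    meta = meta[list(FeatureTable.SAMPLE_COLUMNS)]

    known_meta = [c for c in FEATURE_META_COLUMNS if c in raw.columns]
    sample_cols = [c for c in raw.columns if c not in FEATURE_META_COLUMNS]
    missing = [c for c in sample_cols if c not in meta.index]
    if missing:
        raise ValueError(
            f"{path}: sample column(s) absent from metadata sheet: {missing}"
        )
    features = raw[known_meta].set_index("feature_id")
    if "formula" not in features.columns:
        features["formula"] = None
    else:
        features["formula"] = features["formula"].astype(object).where(
            features["formula"].notna(), None)
    areas = raw.set_index("feature_id")[sample_cols].astype(float)
    areas.columns.name = "sample_id"
    meta = meta.loc[sample_cols]
    return FeatureTable(features, meta, areas)


def write_feature_table(table: FeatureTable, path: str | Path,
                        meta_path: str | Path | None = None) -> None:
    """Write a feature table (and optionally its metadata) to CSV.

    m/z is serialized to 6 decimals, retention time to 3; missing cells
    are written empty, zero areas as ``0``.
    """
    out = table.features.copy()
    out["mz"] = out["mz"].map(lambda v: f"{v:.6f}")
    out["rt"] = out["rt"].map(lambda v: f"{v:.3f}")
    cols = ["mz", "rt", "polarity"]
    if out["formula"].notna().any():
        cols.append("formula")
    body = table.areas.map(lambda v: "" if pd.isna(v) else repr(float(v)))
    pd.concat([out[cols], body], axis=1).to_csv(path, index_label="feature_id")
    if meta_path is not None:
        write_sample_metadata(table, meta_path)


def write_sample_metadata(table: FeatureTable, path: str | Path) -> None:
    table.samples.to_csv(path, index_label="sample_id")


def read_ms1_library(path: str | Path) -> list[LibraryEntry]:
    """Read an MS1 compound library CSV.

    Columns: name, formula, monoisotopic_mass, adduct (``;``-separated),
    rt (optional), source.
    """
    df = pd.read_csv(path)
    entries = []
    for _, row in df.iterrows():
        adducts = tuple(str(row.get("adduct", "[M-H]-;[M+H]+")).split(";"))
        rt = row.get("rt")
        entries.append(LibraryEntry(
            name=str(row["name"]),
            formula=None if pd.isna(row.get("formula")) else str(row["formula"]),
            monoisotopic_mass=float(row["monoisotopic_mass"]),
            adducts=adducts,
            rt=None if pd.isna(rt) else float(rt),
            source=str(row.get("source", "house_ms1")),
        ))
    return entries


def write_ms1_library(entries: list[LibraryEntry], path: str | Path) -> None:
    pd.DataFrame(
        {
            "name": [e.name for e in entries],
            "formula": [e.formula for e in entries],
            "monoisotopic_mass": [f"{e.monoisotopic_mass:.6f}" for e in entries],
            "adduct": [";".join(e.adducts) for e in entries],
            "rt": [e.rt for e in entries],
            "source": [e.source for e in entries],
        }
    ).to_csv(path, index=False)


# -- MS2 spectral libraries (MSP / MGF via matchms) --------------------

_NCE_RE = re.compile(r"NCE[=:\s]+([0-9]+|averaged)", re.IGNORECASE)


def _nce_from_metadata(meta: dict) -> str:
    for key in ("collision_energy", "nce"):
        val = meta.get(key)
        if val is not None:
            m = _NCE_RE.search(f"NCE={val}")
            if m:
                return m.group(1).lower()
            return str(val)
    comment = meta.get("comment", "") or ""
    m = _NCE_RE.search(str(comment))
    return m.group(1).lower() if m else "averaged"


def read_spectral_library(path: str | Path) -> list[SpectrumRecord]:
    """Read MSP or MGF into :class:`SpectrumRecord` objects.

    Intensities are rescaled so the base peak is 100.  Spectra with no
    peaks are skipped with a warning giving the skip count.
    """
    from matchms.importing import load_from_mgf, load_from_msp

    path = Path(path)
    loader = load_from_mgf if path.suffix.lower() == ".mgf" else load_from_msp
    records: list[SpectrumRecord] = []
    skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for spec in loader(str(path)):
            if spec is None or len(spec.peaks.mz) == 0:
                skipped += 1
                continue
            meta = spec.metadata
            name = meta.get("compound_name") or meta.get("title") or meta.get("name") or ""
            polarity = meta.get("ionmode", "")
            if polarity not in ("negative", "positive"):
                polarity = "negative"
            rec = SpectrumRecord(
                library_name=str(name),
                precursor_mz=float(meta.get("precursor_mz") or meta.get("pepmass") or 0.0),
                polarity=polarity,
                nce=_nce_from_metadata(meta),
                peaks=list(zip(spec.peaks.mz.tolist(), spec.peaks.intensities.tolist())),
            ).rescaled()
            records.append(rec)
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} spectra with zero peaks")
    return records


def write_spectral_library(records: list[SpectrumRecord], path: str | Path) -> None:
    """Write spectra to MSP or MGF (chosen by file extension)."""
    import matchms
    from matchms.exporting import save_as_mgf, save_as_msp

    path = Path(path)
    spectra = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for rec in records:
            peaks = sorted(rec.peaks, key=lambda p: p[0])
            spectra.append(matchms.Spectrum(
                mz=np.array([p[0] for p in peaks], dtype=float),
                intensities=np.array([p[1] for p in peaks], dtype=float),
                metadata={
                    "compound_name": rec.library_name,
                    "precursor_mz": rec.precursor_mz,
                    "ionmode": rec.polarity,
                    "collision_energy": rec.nce,
                },
                metadata_harmonization=False,
            ))
        if path.exists():
            path.unlink()  # matchms appends to existing files
        if path.suffix.lower() == ".mgf":
            save_as_mgf(spectra, str(path))
        else:
            save_as_msp(spectra, str(path))
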