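"""Metabolite annotation against MS1/MS2 libraries with confidence levels.

Credentialed features are matched to compound libraries by exact mass
(ppm tolerance) and retention time, and to spectral libraries by a
greedy square-root-intensity-weighted cosine.  Each feature receives an
identification confidence level following the community tiers:

* **Level 1** — in-house library candidate with a retention-time match,
  backed by exact mass and/or an in-house MS2 match;
* **Level 2** — exact mass plus an external-library MS2 match, with no
  retention time available;
* **Level 3** — formula-based putative name from an external compound
  list (top listed hit);
* **Level 4** — formula only; displayed as a ``MW<mass>_RT<rt>`` label.

Features without an assigned molecular formula are excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config
from .formulas import adduct_mz, adducts_for_polarity, ppm_error
from .model import FeatureTable, LibraryEntry, SpectrumRecord

EVIDENCE_FLAGS = ("house_ms1_rt", "house_ms2", "external_ms2", "formula_only")
HOUSE_SOURCES = ("house_ms1", "house_ms2", "msmls")


@dataclass
class Candidate:
    """One library hit for a feature."""

    entry: LibraryEntry
    adduct: str
    ppm_error: float
    rt_delta: float | None  # seconds, None when the entry has no RT
    ms2_score: float | None = None


@dataclass
class AnnotationRecord:
    """Annotation outcome for one feature."""

    feature_id: str
    candidates: list[Candidate] = field(default_factory=list)
    level: int = 4
    evidence: tuple[str, ...] = ()
    display_name: str = ""
    polarity: str = "negative"
    formula: str | None = None


def mw_rt_label(mz: float, rt: float) -> str:
    """Molecular-weight / retention-time label for unnamed features."""
    return f"MW{mz:.4f}_RT{rt:.2f}"


def match_ms1(mz: float, rt: float, polarity: str,
              library: list[LibraryEntry], cfg: Config) -> list[Candidate]:
    """Exact-mass (and, when available, retention-time) library matching.

    A candidate requires ``|observed - adduct m/z|`` within ``ppm_tol``
    (ppm on the adduct m/z) and, when the entry carries a retention
    time, ``|ΔRT|`` within ``rt_tol``.  Results sort by (RT match
    present first, |ppm error|, |ΔRT|).
    """
    allowed = adducts_for_polarity(polarity, cfg.use_water_loss_adduct)
    out = []
    for entry in library:
        for adduct in entry.adducts:
            if adduct not in allowed:
                continue
            ref = adduct_mz(entry.monoisotopic_mass, adduct)
            err = ppm_error(mz, ref)
            if abs(err) > cfg.ppm_tol:
                continue
            if entry.rt is not None:
                drt = (rt - entry.rt) * 60.0
                if abs(drt) > cfg.rt_tol:
                    continue
            else:
                drt = None
            out.append(Candidate(entry, adduct, float(err), drt))
    out.sort(key=lambda c: (c.rt_delta is None, abs(c.ppm_error),
                            abs(c.rt_delta) if c.rt_delta is not None else np.inf))
    return out


def match_ms2(query: SpectrumRecord, ref: SpectrumRecord,
              mz_tol: float = 0.01) -> float:
    """Greedy sqrt-intensity-weighted cosine similarity in [0, 1].

    Candidate peak pairs within ``mz_tol`` are accepted greedily in
    order of increasing m/z difference, each peak used at most once; the
    score is the cosine of the matched sqrt-intensity vectors.
    """
    q = query.peaks
    r = ref.peaks
    if not q or not r:
        return 0.0
    pairs = []
    for i, (qm, qi) in enumerate(q):
        for j, (rm, ri) in enumerate(r):
            d = abs(qm - rm)
            if d <= mz_tol:
                pairs.append((d, i, j))
    pairs.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    num = 0.0
    for _, i, j in pairs:
        if i in used_q or j in used_r:
            continue
        used_q.add(i)
        used_r.add(j)
        num += np.sqrt(q[i][1]) * np.sqrt(r[j][1])
    denom = np.sqrt(sum(p[1] for p in q)) * np.sqrt(sum(p[1] for p in r))
    return float(num / denom) if denom > 0 else 0.0


def assign_level(feature_id: str, mz: float, rt: float, polarity: str,
                 formula: str | None, candidates: list[Candidate], cfg: Config,
                 house_ms2_score: float | None = None,
                 external_ms2_score: float | None = None) -> AnnotationRecord | None:
    """Assign the identification confidence level; first rule wins.

    Returns ``None`` for features without a formula (excluded: no
    credible molecular-formula assignment).
    """
    house = [c for c in candidates if c.entry.source in HOUSE_SOURCES]
    external = [c for c in candidates if c.entry.source not in HOUSE_SOURCES]
    house_rt = [c for c in house if c.rt_delta is not None]

    # Level 1: in-house candidate with RT match, exact mass and/or MS2
    if house_rt:
        flags = ["house_ms1_rt"]
        if house_ms2_score is not None and house_ms2_score >= cfg.ms2_score_min:
            flags.append("house_ms2")
        best = house_rt[0]
        best.ms2_score = house_ms2_score
        return AnnotationRecord(feature_id, candidates, 1, tuple(flags),
                                best.entry.name, polarity, formula or best.entry.formula)
    # Level 2: exact mass + external MS2 match, no RT available
    if (external_ms2_score is not None and external_ms2_score >= cfg.ms2_score_min
            and (external or house)):
        pool = external or house
        best = pool[0]
        best.ms2_score = external_ms2_score
        return AnnotationRecord(feature_id, candidates, 2, ("external_ms2",),
                                best.entry.name, polarity, formula or best.entry.formula)
    if formula is None:
        return None
    # Level 3: formula plus a name from an external compound list
    if external:
        return AnnotationRecord(feature_id, candidates, 3, ("formula_only",),
                                external[0].entry.name, polarity, formula)
    # Level 4: formula only
    return AnnotationRecord(feature_id, candidates, 4, ("formula_only",),
                            mw_rt_label(mz, rt), polarity, formula)


def annotate_table(table: FeatureTable, library: list[LibraryEntry], cfg: Config,
                   ms2_scores: dict[str, tuple[float | None, float | None]] | None = None,
                   ) -> list[AnnotationRecord]:
    """Annotate every feature of a table; features without formula or
    library evidence may be excluded (not returned)."""
    ms2_scores = ms2_scores or {}
    records = []
    for fid in table.features.index:
        row = table.features.loc[fid]
        cands = match_ms1(float(row["mz"]), float(row["rt"]), row["polarity"],
                          library, cfg)
        house_s, ext_s = ms2_scores.get(fid, (None, None))
        rec = assign_level(fid, float(row["mz"]), float(row["rt"]), row["polarity"],
                           row.get("formula"), cands, cfg, house_s, ext_s)
        if rec is not None:
            records.append(rec)
    return records


# -- compound database -------------------------------------------------


@dataclass
class CompoundDB:
    """Curated MS1 + MS2 compound database built from credentialed data."""

    ms1_entries: list[LibraryEntry] = field(default_factory=list)
    ms2_entries: list[SpectrumRecord] = field(default_factory=list)
    provenance: pd.DataFrame = field(default_factory=pd.DataFrame)


def spectrum_snr(spec: SpectrumRecord) -> float:
    """Base peak over median peak intensity; infinity for one peak."""
    intens = [p[1] for p in spec.peaks]
    if len(intens) == 1:
        return np.inf
    med = float(np.median(intens))
    return np.inf if med == 0 else max(intens) / med


def build_compound_db(table: FeatureTable, annotations: list[AnnotationRecord],
                      spectra: dict[str, SpectrumRecord] | None, cfg: Config,
                      snr_min: float = 3.0) -> CompoundDB:
    """Assemble the compound database from annotated, credentialed features.

    Low-quality spectra (base-peak to median-peak ratio below
    ``snr_min``) are dropped; duplicate display names are resolved to
    the candidate nearest the library retention time, the rest demoted
    to ``MW_RT`` labels at Level 4.
    """
    spectra = spectra or {}
    anns = [a for a in annotations if a.feature_id in table.features.index]

    # de-duplicate names: nearest |rt_delta| keeps the name
    by_name: dict[tuple[str, str], list[AnnotationRecord]] = {}
    for a in anns:
        by_name.setdefault((a.display_name, a.polarity), []).append(a)
    for (_, _), group in by_name.items():
        if len(group) <= 1:
            continue

        def rt_dist(a: AnnotationRecord) -> float:
            deltas = [abs(c.rt_delta) for c in a.candidates if c.rt_delta is not None]
            return min(deltas) if deltas else np.inf

        group.sort(key=rt_dist)
        for a in group[1:]:
            row = table.features.loc[a.feature_id]
            a.display_name = mw_rt_label(float(row["mz"]), float(row["rt"]))
            a.level = 4
            a.evidence = ("formula_only",)

    ms1_entries = []
    ms2_entries = []
    prov = []
    seen: set[tuple[str, str, str]] = set()
    for a in anns:
        row = table.features.loc[a.feature_id]
        adduct = adducts_for_polarity(a.polarity)[0]
        key = (a.display_name, adduct, a.polarity)
        if key in seen:
            continue
        seen.add(key)
        mono = float(row["mz"]) - adduct_mz(0.0, adduct)
        try:
            entry = LibraryEntry(name=a.display_name, formula=a.formula,
                                 monoisotopic_mass=mono, adducts=(adduct,),
                                 rt=float(row["rt"]), source="cd1_db")
        except ValueError:
            # observed mass too far from the claimed formula: keep the
            # observed mass, drop the formula claim
            entry = LibraryEntry(name=a.display_name, formula=None,
                                 monoisotopic_mass=mono, adducts=(adduct,),
                                 rt=float(row["rt"]), source="cd1_db")
        ms1_entries.append(entry)
        spec = spectra.get(a.feature_id)
        has_spec = spec is not None and spectrum_snr(spec) >= snr_min
        if has_spec:
            ms2_entries.append(SpectrumRecord(
                a.display_name, spec.precursor_mz, spec.polarity, spec.nce,
                list(spec.peaks)))
        prov.append((a.feature_id, a.display_name, a.level, has_spec))
    return CompoundDB(
        ms1_entries, ms2_entries,
        pd.DataFrame(prov, columns=["feature_id", "display_name", "level",
                                    "has_ms2"]).set_index("feature_id"),
    )


def db_coverage_percent(n_detected: int, n_total: int) -> int:
    """Percent of database compounds detected, rounded as printed."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return int(round(100.0 * n_detected / n_total))


def db_coverage(table: FeatureTable, db: CompoundDB, cfg: Config,
                polarity: str | None = None) -> tuple[int, int, int]:
    """(n detected, n database entries, percent) for one polarity."""
    entries = [e for e in db.ms1_entries
               if polarity is None or ("-" in e.adducts[0]) == (polarity == "negative")]
    n_total = len(entries)
    detected = 0
    feats = table.features
    if polarity is not None:
        feats = feats[feats["polarity"] == polarity]
    for e in entries:
        ref = adduct_mz(e.monoisotopic_mass, e.adducts[0])
        hit = False
        for fid in feats.index:
            if abs(ppm_error(float(feats.loc[fid, "mz"]), ref)) <= cfg.ppm_tol:
                if e.rt is None or abs(float(feats.loc[fid, "rt"]) - e.rt) * 60 <= cfg.rt_tol:
                    hit = True
                    break
        detected += hit
    return detected, n_total, db_coverage_percent(detected, n_total)


# -- data-dependent acquisition lists ----------------------------------


def generate_dda_lists(features: pd.DataFrame, mock_features: pd.DataFrame,
                       collected_ids: set[str], cfg: Config
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inclusion/exclusion lists for the next iterative DDA round.

    Inclusion: credentialed features with no collected spectrum, as
    (m/z, RT ± rt_tol window).  Exclusion: mock-derived features already
    fragmented.  Both frames carry columns (mz, rt_start, rt_end,
    polarity); the underlying feature sets are disjoint.
    """

    def window(df: pd.DataFrame) -> pd.DataFrame:
        half = cfg.rt_tol_min
        return pd.DataFrame({
            "mz": df["mz"].astype(float),
            "rt_start": (df["rt"].astype(float) - half).clip(lower=0.0),
            "rt_end": df["rt"].astype(float) + half,
            "polarity": df["polarity"],
        }, index=df.index)

    inc = features.loc[[i for i in features.index if i not in collected_ids]]
    exc = mock_features.loc[[i for i in mock_features.index if i in collected_ids]]
    return window(inc), window(exc)


def simulate_dda_rounds(features: pd.DataFrame, intensities: pd.Series, cfg: Config,
                        scans_per_round: int = 40, rounds: int = 4,
                        mock_features: pd.DataFrame | None = None
                        ) -> list[int]:
    """Iterative DDA acquisition: inclusion-list sizes per round.

    Each round fragments the ``scans_per_round`` most abundant
    not-yet-collected inclusion-list precursors (Top-N selection
    repeated over the run makes abundance the effective priority); the
    inclusion list shrinks monotonically until empty.
    """
    if mock_features is None:
        mock_features = features.iloc[0:0]
    collected: set[str] = set()
    sizes = []
    for _ in range(rounds):
        inc, _ = generate_dda_lists(features, mock_features, collected, cfg)
        sizes.append(len(inc))
        if inc.empty:
            break
        todo = intensities.loc[inc.index].sort_values(ascending=False)
        collected.update(todo.index[:scans_per_round])
    return sizes


def merge_polarity(neg: FeatureTable, pos: FeatureTable) -> FeatureTable:
    """Concatenate negative- and positive-mode annotated tables.

    Features are never merged by name; negative-mode display names are
    suffixed ``_[M-H]`` so both ions of one compound remain visible.
    """
    if set(neg.samples.index) != set(pos.samples.index):
        raise ValueError("negative and positive tables must share the same samples")
    neg = neg.copy()
    pos = pos.copy()
    if "display_name" in neg.features.columns:
        neg.features["display_name"] = [
            n if n is None or str(n).endswith("_[M-H]") else f"{n}_[M-H]"
            for n in neg.features["display_name"]
        ]
    overlap = set(neg.features.index) & set(pos.features.index)
    if overlap:
        mapper = {fid: f"{fid}_neg" for fid in overlap}
        neg.features = neg.features.rename(index=mapper)
        neg.areas = neg.areas.rename(index=mapper)
    features = pd.concat([neg.features, pos.features])
    areas = pd.concat([neg.areas, pos.areas[neg.samples.index]])
    return FeatureTable(features, neg.samples, areas)
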