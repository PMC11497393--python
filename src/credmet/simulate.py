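"""Synthetic LC-MS experiment generator with known ground truth.

Emulates the study design this pipeline targets: a handful of biological
samples (microliter-scale biofluid extractions) alongside empty-tube
mock extractions, spiked isotope-labeled internal standards, pooled-QC
reinjections, a 1x / 3x / 10x dilution series, two-group treatment
effects, 13C-labeled reference mixes for isotope-pair credentialing, and
exponential-decay time courses across body compartments.

Every abundance is drawn log-normally per metabolite; each sample
carries one multiplicative technical factor (the quantity the
internal-standard normalizer must recover); censoring below a global
detection threshold produces missing cells.  All randomness flows
through a single seeded :class:`numpy.random.Generator`.

m/z values for true metabolites come from a bundled mini-library of real
formulas (amino acids, kynurenine-pathway intermediates, corticosteroids
and common polar metabolites) so that annotation against the same
library is meaningful; contaminant m/z are rejection-sampled to sit more
than 10 ppm away from every library adduct mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import Config
from .formulas import adduct_mz, adducts_for_polarity, formula_carbon_count, monoisotopic_mass
from .model import FeatureTable, LibraryEntry

# (name, formula, HILIC-like retention time in minutes)
MINI_LIBRARY_SPECS: list[tuple[str, str, float]] = [
    # proteinogenic amino acids
    ("glycine", "C2H5NO2", 8.10), ("alanine", "C3H7NO2", 7.80),
    ("serine", "C3H7NO3", 8.40), ("proline", "C5H9NO2", 7.20),
    ("valine", "C5H11NO2", 6.90), ("threonine", "C4H9NO3", 8.00),
    ("cysteine", "C3H7NO2S", 8.60), ("leucine", "C6H13NO2", 6.30),
    ("isoleucine", "C6H13NO2", 6.50), ("asparagine", "C4H8N2O3", 8.70),
    ("aspartate", "C4H7NO4", 9.10), ("glutamine", "C5H10N2O2", 8.30),
    ("lysine", "C6H14N2O2", 10.40), ("glutamate", "C5H9NO4", 8.90),
    ("methionine", "C5H11NO2S", 7.00), ("histidine", "C6H9N3O2", 10.10),
    ("phenylalanine", "C9H11NO2", 6.00), ("arginine", "C6H14N4O2", 10.60),
    ("tyrosine", "C9H11NO3", 6.70), ("tryptophan", "C11H12N2O2", 5.80),
    # kynurenine pathway
    ("kynurenine", "C10H12N2O3", 6.20), ("kynurenic acid", "C10H7NO3", 4.90),
    ("quinolinic acid", "C7H5NO4", 9.40), ("3-hydroxykynurenine", "C10H12N2O4", 6.80),
    ("xanthurenic acid", "C10H7NO4", 5.30), ("anthranilic acid", "C7H7NO2", 4.20),
    ("niacinamide", "C6H6N2O", 3.90), ("indoxyl sulfate", "C8H7NO4S", 3.50),
    ("picolinic acid", "C6H5NO2", 8.20),
    # glucocorticoid pathway
    ("cortisol", "C21H30O5", 2.20), ("cortisone", "C21H28O5", 2.40),
    ("corticosterone", "C21H30O4", 2.10), ("11-deoxycortisol", "C21H30O4", 2.60),
    ("deoxycorticosterone", "C21H30O3", 1.90), ("aldosterone", "C21H28O5", 2.80),
    ("progesterone", "C21H30O2", 1.60),
    # central carbon / energy metabolism
    ("glucose", "C6H12O6", 7.40), ("glucose-6-phosphate", "C6H13O9P", 11.20),
    ("lactate", "C3H6O3", 5.10), ("pyruvate", "C3H4O3", 5.60),
    ("citrate", "C6H8O7", 11.60), ("succinate", "C4H6O4", 9.80),
    ("fumarate", "C4H4O4", 9.60), ("malate", "C4H6O5", 10.20),
    ("alpha-ketoglutarate", "C5H6O5", 10.80), ("glutathione", "C10H17N3O6S", 9.20),
    # nucleotides and related
    ("hypoxanthine", "C5H4N4O", 4.60), ("xanthine", "C5H4N4O2", 5.00),
    ("uric acid", "C5H4N4O3", 6.10), ("adenosine", "C10H13N5O4", 5.40),
    ("inosine", "C10H12N4O5", 5.70), ("uridine", "C9H12N2O6", 6.40),
    ("AMP", "C10H14N5O7P", 11.00),
    # other common polar metabolites
    ("creatinine", "C4H7N3O", 7.60), ("creatine", "C4H9N3O2", 8.50),
    ("choline", "C5H13NO", 9.00), ("betaine", "C5H11NO2", 7.10),
    ("carnitine", "C7H15NO3", 8.80), ("taurine", "C2H7NO3S", 9.30),
    ("spermidine", "C7H19N3", 11.40), ("citrulline", "C6H13N3O3", 9.50),
    ("ornithine", "C5H12N2O2", 10.30), ("hippurate", "C9H9NO3", 3.70),
]


def mini_library(polarity: str | None = None) -> list[LibraryEntry]:
    """The bundled in-house MS1 mini-library with computed exact masses."""
    entries = []
    for name, formula, rt in MINI_LIBRARY_SPECS:
        entries.append(LibraryEntry(
            name=name, formula=formula,
            monoisotopic_mass=monoisotopic_mass(formula),
            adducts=("[M-H]-", "[M+H]+"), rt=rt, source="house_ms1",
        ))
    return entries


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    Defaults reproduce the study conditions: 37 spiked internal
    standards, mock extractions alongside biological samples, pooled-QC
    reinjections and a 1x/3x/10x dilution series, 20 % technical
    coefficient of variation, and a small fraction of true metabolites
    carrying a treatment effect.
    """

    n_true: int = 100
    n_contaminant: int = 100
    n_is: int = 37
    n_bio: int = 8
    n_mock: int = 4
    n_pool_qc: int = 4
    dilution_levels: tuple[float, ...] = (1.0, 1.0 / 3.0, 0.1)
    dilution_reps: int = 2
    effect_frac: float = 0.05
    effect_log2fc: float = 1.5
    noise_cv: float = 0.20
    qc_injection_cv: float = 0.05
    lod_quantile: float = 0.02
    mock_floor_frac: float = 0.01
    frac_saturating: float = 0.0
    base_abundance: float = 1.0e6
    abundance_sigma: float = 1.0
    groups: tuple[str, str] = ("saline", "polyIC")
    polarity: str = "negative"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_true", "n_contaminant", "n_is", "n_bio", "n_mock", "n_pool_qc"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimConfig.{name} must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.effect_frac > 0 and self.n_bio < 2:
            raise ValueError("n_bio < 2 with effect_frac > 0: no contrast possible")


@dataclass
class GroundTruth:
    """Labels behind a synthetic experiment.

    ``features`` is indexed by feature_id with columns ``label`` (one of
    true_metabolite / contaminant / internal_standard / noise), ``name``,
    ``formula``, ``carbon_count``, ``group_effect`` (log2 fold-change, 0
    for null) and ``base_abundance``; ``sample_factors`` holds the
    per-sample multiplicative technical factor actually applied.
    """

    features: pd.DataFrame
    sample_factors: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def ids(self, label: str) -> list[str]:
        return list(self.features.index[self.features["label"] == label])

    @property
    def effect_ids(self) -> list[str]:
        return list(self.features.index[self.features["group_effect"] != 0])

    def to_csv(self, path) -> None:
        self.features.to_csv(path, index_label="feature_id")


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit median and the given CV."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def _contaminant_mz(rng: np.random.Generator, library_mzs: np.ndarray) -> float:
    """Random m/z more than 10 ppm from every library adduct mass."""
    while True:
        mz = rng.uniform(80.0, 800.0)
        if library_mzs.size == 0:
            return mz
        if np.min(np.abs(mz - library_mzs) / library_mzs) * 1e6 > 10.0:
            return mz


def generate_experiment(sim: SimConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate one full synthetic experiment with ground truth.

    Biological, mock, pooled-QC and dilution-QC samples are produced per
    the configured counts; abundances follow the generative model in the
    module docstring.  Fully reproducible from ``sim.rng_seed``.
    """
    rng = np.random.default_rng(sim.rng_seed)
    lib = mini_library()
    adduct = adducts_for_polarity(sim.polarity)[0]
    lib_mzs = np.array([adduct_mz(e.monoisotopic_mass, a)
                        for e in lib for a in e.adducts])

    # ---- features and ground-truth labels ----------------------------
    rows = []
    for i in range(sim.n_true):
        entry = lib[i % len(lib)]
        mz = adduct_mz(entry.monoisotopic_mass, adduct)
        # repeated uses of a library compound get a small RT offset so
        # feature coordinates stay distinct
        rt = entry.rt + 0.35 * (i // len(lib))
        rows.append(("T%03d" % i, "true_metabolite", entry.name, entry.formula,
                     formula_carbon_count(entry.formula), mz, rt))
    for i in range(sim.n_contaminant):
        mz = _contaminant_mz(rng, lib_mzs)
        rt = rng.uniform(0.5, 12.0)
        rows.append(("C%03d" % i, "contaminant", "", None, 0, mz, rt))
    for i in range(sim.n_is):
        mz = rng.uniform(80.0, 800.0)
        rt = rng.uniform(0.5, 12.0)
        rows.append(("IS%02d" % i, "internal_standard", "IS_%02d" % i, None, 0, mz, rt))
    truth_df = pd.DataFrame(
        rows, columns=["feature_id", "label", "name", "formula",
                       "carbon_count", "mz", "rt"],
    ).set_index("feature_id")

    base = sim.base_abundance * np.exp(
        rng.normal(0.0, sim.abundance_sigma, size=len(truth_df)))
    base[truth_df["label"] == "internal_standard"] = sim.base_abundance / 2.0
    truth_df["base_abundance"] = base

    effects = np.zeros(len(truth_df))
    is_true = (truth_df["label"] == "true_metabolite").to_numpy()
    n_effect = int(round(sim.effect_frac * sim.n_true))
    if n_effect > 0:
        hit = rng.choice(np.flatnonzero(is_true), size=n_effect, replace=False)
        effects[hit] = sim.effect_log2fc
    truth_df["group_effect"] = effects

    saturating = np.zeros(len(truth_df), dtype=bool)
    if sim.frac_saturating > 0:
        n_sat = int(round(sim.frac_saturating * len(truth_df)))
        saturating[rng.choice(len(truth_df), size=n_sat, replace=False)] = True
    truth_df["saturating"] = saturating

    # ---- samples -----------------------------------------------------
    samp_rows = []
    for i in range(sim.n_bio):
        group = sim.groups[0] if i < sim.n_bio / 2 else sim.groups[1]
        samp_rows.append(("bio%02d" % i, "biological", group, "b1", 1.0))
    for i in range(sim.n_mock):
        samp_rows.append(("mock%02d" % i, "mock", None, "b1", 1.0))
    for i in range(sim.n_pool_qc):
        samp_rows.append(("pool%02d" % i, "pool_qc", None, "b1", 1.0))
    for lvl in sim.dilution_levels:
        for r in range(sim.dilution_reps):
            samp_rows.append(("dil%.3f_%d" % (lvl, r), "dilution_qc", None, "b1", lvl))
    samples = pd.DataFrame(
        samp_rows, columns=["sample_id", "role", "group", "batch", "dilution_factor"],
    ).set_index("sample_id")
    samples["timepoint"] = np.nan
    samples["compartment"] = None

    # QC reinjections of one pooled aliquot vary only by injection
    # precision; biological and mock extractions carry the full
    # technical CV of independent sample preparation
    is_qc = samples["role"].isin(["pool_qc", "dilution_qc"]).to_numpy()
    factors_arr = np.where(
        is_qc,
        _lognormal_noise(rng, sim.qc_injection_cv, len(samples)),
        _lognormal_noise(rng, sim.noise_cv, len(samples)),
    )
    factors = pd.Series(factors_arr, index=samples.index, name="technical_factor")

    # ---- expected abundances per (feature, sample) -------------------
    n_feat, n_samp = len(truth_df), len(samples)
    expected = np.zeros((n_feat, n_samp))
    labels = truth_df["label"].to_numpy()
    base = truth_df["base_abundance"].to_numpy()
    median_true = float(np.median(base[labels == "true_metabolite"])) if is_true.any() else 0.0
    mock_floor = sim.mock_floor_frac * median_true

    bio_expect = np.zeros((n_feat, sim.n_bio))
    for j, sid in enumerate(samples.index[samples["role"] == "biological"]):
        group = samples.loc[sid, "group"]
        mult = np.where(
            (truth_df["group_effect"].to_numpy() != 0) & (group == sim.groups[1]),
            2.0 ** truth_df["group_effect"].to_numpy(), 1.0)
        col = np.where(labels == "true_metabolite", base * mult,
                       np.where(labels == "contaminant", base, base))
        bio_expect[:, j] = col
    pool_expect = bio_expect.mean(axis=1)

    for j, sid in enumerate(samples.index):
        role = samples.loc[sid, "role"]
        if role == "biological":
            k = list(samples.index[samples["role"] == "biological"]).index(sid)
            col = bio_expect[:, k].copy()
            col[labels == "true_metabolite"] = bio_expect[labels == "true_metabolite", k]
            expected[:, j] = col
        elif role == "mock":
            col = np.where(labels == "contaminant", base, 0.0)
            col = np.where(labels == "internal_standard", base, col)
            col = np.where(labels == "true_metabolite", mock_floor, col)
            expected[:, j] = col
        elif role == "pool_qc":
            expected[:, j] = pool_expect
        elif role == "dilution_qc":
            lvl = float(samples.loc[sid, "dilution_factor"])
            col = pool_expect * lvl
            col[truth_df["saturating"].to_numpy()] = pool_expect[
                truth_df["saturating"].to_numpy()]
            expected[:, j] = col
        # internal standards are spiked at reconstitution: constant
        # expected level in every sample regardless of role or dilution
        expected[labels == "internal_standard", j] = base[labels == "internal_standard"]

    cell_noise = np.where(
        is_qc[None, :],
        _lognormal_noise(rng, sim.qc_injection_cv, (n_feat, n_samp)),
        _lognormal_noise(rng, sim.noise_cv, (n_feat, n_samp)),
    )
    areas = expected * factors.to_numpy()[None, :] * cell_noise

    # ---- censoring below the detection limit -------------------------
    if sim.lod_quantile > 0:
        positive = areas[areas > 0]
        threshold = float(np.quantile(positive, sim.lod_quantile)) if positive.size else 0.0
        areas = np.where(areas < threshold, np.nan, areas)
    areas = np.where(areas == 0, np.nan, areas)  # zero expectation => not detected

    features = truth_df[["mz", "rt"]].copy()
    features["polarity"] = sim.polarity
    features["formula"] = truth_df["formula"]
    table = FeatureTable(
        features, samples[list(FeatureTable.SAMPLE_COLUMNS)],
        pd.DataFrame(areas, index=truth_df.index, columns=samples.index),
    )
    truth = GroundTruth(
        truth_df[["label", "name", "formula", "carbon_count", "mz", "rt",
                  "base_abundance", "group_effect", "saturating"]].copy(),
        factors,
    )
    return table, truth


def generate_iroa_mix(truth: GroundTruth, design: str, cfg: Config,
                      n_samples: int = 3, noise_cv: float = 0.15,
                      seed: int | None = None, coverage: float = 1.0) -> FeatureTable:
    """Synthesize an isotope-ratio credentialing mix from ground truth.

    Every formula-bearing true metabolite contributes a light (12C)
    feature at its adduct m/z and a co-eluting heavy partner shifted by
    ``n_carbons x 1.0033548 Da``; contaminants contribute the light
    feature only.  ``design`` selects the mixing ratio: ``"LTRS"`` (the
    1:1 mix of 95:5 and 5:95 pools, heavy/light ~ 1) or ``"IS"`` (the
    5:95 internal-standard pool, heavy/light ~ 95/5).  ``coverage``
    restricts the labeled reference to a random fraction of the true
    metabolites, emulating a reference metabolome that covers only part
    of the biofluid's metabolite complement.
    """
    if design not in ("LTRS", "IS"):
        raise ValueError(f"unknown IROA design: {design!r}")
    ratio = 1.0 if design == "LTRS" else 95.0 / 5.0
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)

    tf = truth.features
    true_ids = list(tf.index[tf["label"] == "true_metabolite"])
    n_labeled = int(round(coverage * len(true_ids)))
    labeled = set(rng.choice(true_ids, size=n_labeled, replace=False)) \
        if n_labeled < len(true_ids) else set(true_ids)

    feats = []
    skipped = 0
    for fid in tf.index:
        row = tf.loc[fid]
        if row["label"] == "true_metabolite":
            if not row.get("formula"):
                skipped += 1
                continue
            n_c = formula_carbon_count(row["formula"])
            light_mz = float(row["mz"])
            feats.append((fid + "_L", light_mz, float(row["rt"]), 1.0))
            if n_c > 0 and fid in labeled:
                feats.append((fid + "_H", light_mz + n_c * cfg.carbon_mass_delta,
                              float(row["rt"]), ratio))
        elif row["label"] == "contaminant":
            feats.append((fid + "_L", float(row["mz"]), float(row["rt"]), 1.0))
    if skipped:
        import warnings

        warnings.warn(f"generate_iroa_mix: skipped {skipped} metabolites without formula")

    base = tf["base_abundance"] if "base_abundance" in tf.columns else None
    fids = [f[0] for f in feats]
    features = pd.DataFrame(
        {
            "mz": [f[1] for f in feats],
            "rt": [f[2] for f in feats],
            "polarity": "negative",
            "formula": None,
        },
        index=pd.Index(fids, name="feature_id"),
    )
    samples = pd.DataFrame(
        {
            "role": "biological", "group": None, "batch": "iroa",
            "dilution_factor": 1.0, "timepoint": np.nan, "compartment": None,
        },
        index=pd.Index(["iroa%02d" % i for i in range(n_samples)], name="sample_id"),
    )
    level = np.empty(len(feats))
    for i, (fid, _, _, mult) in enumerate(feats):
        parent = fid[:-2]
        b = float(base.loc[parent]) if base is not None and parent in base.index else 1.0e6
        level[i] = b * mult
    areas = level[:, None] * _lognormal_noise(rng, noise_cv, (len(feats), n_samples))
    return FeatureTable(features, samples[list(FeatureTable.SAMPLE_COLUMNS)],
                        pd.DataFrame(areas, index=features.index, columns=samples.index))


def generate_decay_series(compartments: list[str], rates: list[float],
                          t: list[float], n_rep: int, noise_cv: float,
                          seed: int, c0: float = 100.0,
                          metabolite: str = "kynurenine") -> pd.DataFrame:
    """Exponential-decay time courses per compartment, long format.

    ``value = c0 * exp(-rate * t)`` times log-normal replicate noise.
    Returns columns (compartment, metabolite, time, replicate, value).
    """
    t = np.asarray(t, dtype=float)
    if t.size == 0:
        raise ValueError("t must be non-empty")
    if (t <= 0).any():
        raise ValueError("sampling times must be strictly positive")
    if any(r <= 0 for r in rates):
        raise ValueError("decay rates must be strictly positive")
    if len(rates) != len(compartments):
        raise ValueError("one rate per compartment required")
    rng = np.random.default_rng(seed)
    records = []
    for comp, rate in zip(compartments, rates):
        clean = c0 * np.exp(-rate * t)
        noise = _lognormal_noise(rng, noise_cv, (n_rep, t.size))
        for rep in range(n_rep):
            for k, tk in enumerate(t):
                records.append((comp, metabolite, float(tk), rep,
                                float(clean[k] * noise[rep, k])))
    return pd.DataFrame(records, columns=["compartment", "metabolite", "time",
                                          "replicate", "value"])
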