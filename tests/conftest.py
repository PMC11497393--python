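import numpy as np
import pandas as pd
import pytest

from credmet import Config, FeatureTable, SimConfig, generate_experiment


@pytest.fixture
def cfg():
    return Config()


@pytest.fixture(scope="session")
def default_experiment():
    """Default synthetic study: 100 true / 100 contaminant features."""
    return generate_experiment(SimConfig(rng_seed=1))


@pytest.fixture(scope="session")
def mia_experiment():
    """Two-group contrast: 200 metabolites, 10 with a 1.5-log2FC effect."""
    sim = SimConfig(n_true=200, n_contaminant=0, effect_frac=0.05,
                    effect_log2fc=1.5, noise_cv=0.2, rng_seed=5)
    return generate_experiment(sim)


def tiny_table(area_rows, roles, mz=None, rt=None, polarity="negative"):
    """Small FeatureTable from a dict of feature_id -> list of areas."""
    fids = list(area_rows)
    n_samp = len(roles)
    sids = [f"s{i}" for i in range(n_samp)]
    features = pd.DataFrame({
        "mz": mz if mz is not None else [100.0 + i for i in range(len(fids))],
        "rt": rt if rt is not None else [5.0] * len(fids),
        "polarity": polarity,
        "formula": None,
    }, index=pd.Index(fids, name="feature_id"))
    samples = pd.DataFrame({
        "role": roles, "group": None, "batch": "b", "dilution_factor": 1.0,
        "timepoint": np.nan, "compartment": None,
    }, index=pd.Index(sids, name="sample_id"))
    areas = pd.DataFrame([area_rows[f] for f in fids], index=features.index,
                         columns=samples.index, dtype=float)
    return FeatureTable(features, samples, areas)
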