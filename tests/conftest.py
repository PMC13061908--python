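import warnings

import numpy as np
import pandas as pd
import pytest

import rinsemet as rm
from rinsemet.synth import PlantedEffect


@pytest.fixture(scope="session")
def default_table():
    """One default synthetic study (the study-design configuration)."""
    return rm.simulate_study(rm.GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def filtered_imputed(default_table):
    filt, _ = rm.filter_features(default_table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rm.impute_below_lod(filt)


@pytest.fixture()
def tiny_table():
    """Hand-built 4-participant, 2-time-point, 3-feature table."""
    samples = pd.DataFrame(
        {
            "participant": ["P1", "P1", "P2", "P2", "P3", "P3", "P4", "P4"],
            "group": ["control"] * 4 + ["high-stress"] * 4,
            "time_point": ["Rest", "Post-UK"] * 4,
            "sex": ["M", "M", "F", "F", "M", "M", "F", "F"],
            "age_group": ["20s"] * 4 + ["30s"] * 4,
        },
        index=pd.Index(
            [f"P{i}_{t}" for i in (1, 2, 3, 4) for t in ("Rest", "Post-UK")],
            name="sample",
        ),
    )
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        rng.uniform(1, 10, (8, 3)), index=samples.index, columns=["fA", "fB", "fC"]
    )
    feats = pd.DataFrame(
        {
            "feature_class": ["metabolite", "metabolite", "protein"],
            "recovery": [100.0, 100.0, np.nan],
            "rsd": [5.0, 5.0, np.nan],
            "min_quantifiable": [0.5, 0.5, 0.5],
        },
        index=pd.Index(["fA", "fB", "fC"], name="feature"),
    )
    mask = pd.DataFrame(False, index=vals.index, columns=vals.columns)
    return rm.FeatureTable(values=vals, below_lod=mask, samples=samples, features=feats)


def null_config(seed, **kw):
    """A study with no planted effects and no pair latent (global null)."""
    base = dict(planted_effects=[], latent_pairs=[], seed=seed)
    base.update(kw)
    return rm.GeneratorConfig(**base)


def prepared(config):
    """simulate -> qc filter -> impute, warnings silenced."""
    table = rm.simulate_study(config)
    filt, _ = rm.filter_features(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return rm.impute_below_lod(filt)
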