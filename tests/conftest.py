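import numpy as np
import pandas as pd
import pytest

from lipidscreen.feature_table import FeatureTable, SampleInfo
from lipidscreen.lipids import build_database
from lipidscreen.synthetic import preset_paper_design, simulate_cohort

RUN_SEED = 7


@pytest.fixture(scope="session")
def pos_db():
    """Positive-mode database over the plasma acquisition window."""
    return build_database(polarity="pos", mz_range=(400.0, 1000.0))


@pytest.fixture(scope="session")
def paper_cohort():
    """One draw of the default three-group design (fixed seed)."""
    config = preset_paper_design(seed=RUN_SEED)
    table, truth = simulate_cohort(config)
    return table, truth, config


def make_table(values, groups=None, qc=None, mz=None, annotation=None):
    """Small hand-built feature table for unit tests."""
    values = np.asarray(values, dtype=float)
    nf, ns = values.shape
    groups = groups or ["control"] * ns
    qc = qc or [False] * ns
    ids = [f"F{i:03d}" for i in range(nf)]
    cols = [f"S{j:02d}" for j in range(ns)]
    samples = [SampleInfo(c, g, "plasma", q) for c, g, q in zip(cols, groups, qc)]
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(400, 900, nf),
            "annotation": annotation if annotation is not None else [""] * nf,
        },
        index=pd.Index(ids, name="feature_id"),
    )
    return FeatureTable(
        pd.DataFrame(values, index=features.index, columns=cols), features, samples
    )
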