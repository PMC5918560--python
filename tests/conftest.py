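import numpy as np
import pandas as pd
import pytest

from dietindex import ffq as fq
from dietindex import synthetic as syn


@pytest.fixture(scope="session")
def spec_small():
    return syn.CohortSpec(n_subjects=80, n_items=26, seed=11)


@pytest.fixture(scope="session")
def composition(spec_small):
    return syn.generate_composition_table(spec_small)


@pytest.fixture(scope="session")
def cohort(spec_small, composition):
    return syn.generate_ffq_cohort(spec_small, composition)


@pytest.fixture(scope="session")
def intakes(cohort):
    return fq.to_daily_grams(cohort)


@pytest.fixture(scope="session")
def full_cohort():
    """A mid-size cohort with the full 152-item list, shared across tests."""
    spec = syn.CohortSpec(n_subjects=300, seed=5)
    composition = syn.generate_composition_table(spec)
    data = syn.generate_ffq_cohort(spec, composition)
    return spec, composition, data


def toy_intakes(rows, items=None):
    """Small intake frame from a list of per-subject gram dicts."""
    frame = pd.DataFrame(rows).fillna(0.0)
    if items is not None:
        frame = frame.reindex(columns=items, fill_value=0.0)
    frame.index = [f"T{i}" for i in range(len(frame))]
    return frame


def empty_composition(items):
    """All-zero composition rows for hand-built test diets."""
    comp = pd.DataFrame(
        0.0, index=pd.Index(items, name="item"),
        columns=[c for c in fq.COMPOSITION_COLUMNS if c not in ("category", "mds_group")],
    )
    comp.insert(0, "category", "test")
    comp.insert(1, "mds_group", "vegetables")
    comp["health_value"] = 1.0
    comp["portion_g"] = 100.0
    return comp
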