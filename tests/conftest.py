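import numpy as np
import pandas as pd
import pytest

from exacmark import (
    PeptideTable,
    ProteinMatrix,
    SimConfig,
    generate_cohort,
    preprocess_pipeline,
)
from exacmark.io import CONVALESCENT, EXACERBATION


def make_samples(n_patients=2, cohort="test"):
    """Paired sample metadata: P001_E/P001_C etc."""
    pats = [f"P{i+1:03d}" for i in range(n_patients)]
    ids = [f"{p}_E" for p in pats] + [f"{p}_C" for p in pats]
    return pd.DataFrame(
        {
            "patient_id": pats * 2,
            "state": [EXACERBATION] * n_patients + [CONVALESCENT] * n_patients,
            "cohort": cohort,
            "timepoint_days": [0] * n_patients + [14] * n_patients,
        },
        index=pd.Index(ids, name="sample_id"),
    )


def make_table(ratios: dict, samples=None, meta_overrides=None):
    """Hand-built PeptideTable from {peptide_id: [values...]}."""
    samples = samples if samples is not None else make_samples()
    ratios = pd.DataFrame.from_dict(ratios, orient="index", columns=samples.index)
    ratios.index.name = "peptide_id"
    meta = pd.DataFrame(
        {
            "protein_id": [f"PROT_{p}" for p in ratios.index],
            "uniprot_id": [f"UP{i:05d}" for i in range(len(ratios))],
            "gene_symbol": [f"G{i}" for i in range(len(ratios))],
            "median_response": 5000.0,
            "standard_recoveries": [[100.0, 101.0, 99.0, 100.5]] * len(ratios),
        },
        index=ratios.index,
    )
    if meta_overrides:
        for pid, over in meta_overrides.items():
            for col, val in over.items():
                if isinstance(val, list):
                    meta[col] = meta[col].astype(object)
                meta.at[pid, col] = val
    return PeptideTable(ratios=ratios, peptide_meta=meta, samples=samples)


@pytest.fixture
def samples4():
    return make_samples(2)


@pytest.fixture
def small_table(samples4):
    return make_table(
        {"pepA": [4.0, 2.0, 1.0, 8.0], "pepB": [0.5, 0.25, 1.0, 2.0], "pepC": [1.0, 1.0, 1.0, 1.0]},
        samples4,
    )


@pytest.fixture(scope="session")
def cohort16():
    """Moderately sized synthetic cohort shared across tests (read-only)."""
    cfg = SimConfig(n_patients=16)
    table, truth = generate_cohort(cfg, seed=42)
    return cfg, table, truth


@pytest.fixture(scope="session")
def matrix16(cohort16):
    _, table, truth = cohort16
    matrix, report = preprocess_pipeline(table)
    return matrix, report, truth
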