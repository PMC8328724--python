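import numpy as np
import pandas as pd
import pytest

from secretodep import QuantMatrix, SampleDesign, SimulationConfig, generate_dataset
from secretodep.io_tables import DESIGN_COLUMNS


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_proteins=120, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """No noise, no missingness: planted ratios are exact after normalization."""
    return SimulationConfig(
        n_proteins=80,
        seed=5,
        missing_rate=0.0,
        fc_noise_sd=0.0,
        tech_rep_sd_log10=0.0,
        animal_sd_log10=0.0,
        frac_unquantifiable=0.0,
        coverage_range=(20.0, 95.0),
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    return generate_dataset(clean_config)


def toy_design(n_animals=2, groups=(("CT", "T50"), ("LPS", "T50")), n_reps=1):
    rows = []
    for cond, endpoint in groups:
        group = f"{cond}{endpoint[1:]}"
        for a in range(1, n_animals + 1):
            animal = f"{group}-{a}"
            for tp in ("T0", endpoint):
                for rep in range(1, n_reps + 1):
                    rows.append(
                        {
                            "sample_id": f"{animal}_{tp}_r{rep}" if n_reps > 1 else f"{animal}_{tp}",
                            "animal_id": animal,
                            "condition": cond,
                            "timepoint": tp,
                            "tech_rep": rep,
                            "group": group,
                        }
                    )
    return SampleDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))


def toy_matrix(values, sample_ids, protein_ids=None, coverage=50.0):
    values = np.asarray(values, dtype=float)
    if protein_ids is None:
        protein_ids = [f"P{i}" for i in range(1, values.shape[0] + 1)]
    intens = pd.DataFrame(values, index=protein_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {
            "gene_name": [f"g{i}" for i in range(len(protein_ids))],
            "n_unique_peptides": 3,
            "quality_score": 10.0,
            "coverage_pct": coverage,
        },
        index=protein_ids,
    )
    return QuantMatrix(intens, meta)
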