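import numpy as np
import pandas as pd
import pytest

from crossback_re import synthetic_data as sd


@pytest.fixture(scope="session")
def full_design():
    """Both arms at study sizes, no missing visits, no replicates."""
    return sd.generate_design(sd.StudyDesignSpec(
        n_subjects_arm_bhb=16, n_subjects_arm_hbh=19,
        p_missing_visit=0.0, p_replicate_visit=0.0, seed=11))


@pytest.fixture(scope="session")
def bhb_design(full_design):
    return full_design[full_design["arm"] == "B1HB2"].reset_index(drop=True)


@pytest.fixture(scope="session")
def gene_model():
    return sd.toy_gene_model(n_genes=12)


@pytest.fixture(scope="session")
def repeat_model(gene_model):
    return sd.toy_repeat_model(gene_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_sheet():
    """Minimal hand-written, internally consistent sample sheet."""
    rows = []
    for subject, arm in [("s1", "B1HB2"), ("s2", "B1HB2"), ("s3", "H1BH2")]:
        for visit in ("baseline", "crossover", "crossback"):
            rows.append({
                "sample_id": f"{subject}_{visit}",
                "subject_id": subject,
                "arm": arm,
                "visit": visit,
                "condition": {
                    ("B1HB2", "baseline"): "background",
                    ("B1HB2", "crossover"): "high_dbp",
                    ("B1HB2", "crossback"): "background",
                    ("H1BH2", "baseline"): "high_dbp",
                    ("H1BH2", "crossover"): "background",
                    ("H1BH2", "crossback"): "high_dbp",
                }[(arm, visit)],
                "batch": "batch1",
                "age": 35.0,
                "bmi": 26.0,
            })
    return pd.DataFrame(rows)
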