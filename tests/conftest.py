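import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_variants(rows):
    """Variant DataFrame from (patient, gene, effect, vaf, pathogenicity,
    pop_maf, is_driver) tuples."""
    return pd.DataFrame(rows, columns=["patient_id", "gene", "effect", "vaf",
                                       "pathogenicity", "pop_maf", "is_driver"])


def make_cnvs(rows):
    return pd.DataFrame(rows, columns=["patient_id", "region", "kind"])


@pytest.fixture
def small_variants():
    return make_variants([
        ("p1", "TET2", "missense", 10.0, "pathogenic", 0.0, 0),
        ("p1", "TET2", "frameshift", 30.0, "likely_pathogenic", 0.0, 0),
        ("p1", "JAK2", "missense", 60.0, "pathogenic", 0.0, 1),
        ("p2", "DNMT3A", "missense", 4.0, "pathogenic", 0.0, 0),
        ("p2", "ASXL1", "nonsense", 22.0, "likely_pathogenic", 0.0, 0),
        ("p3", "JAK2", "missense", 45.0, "pathogenic", 0.0, 1),
    ])


@pytest.fixture
def clinical_frame():
    """Five-patient clinical table exercising every outcome pattern."""
    return pd.DataFrame({
        "patient_id": ["p1", "p2", "p3", "p4", "p5"],
        "age_dx": [66, 55, 72, 60, 80],
        "sex": ["male", "female", "male", "male", "female"],
        "prior_arterial_thrombosis": [0, 0, 1, 0, 0],
        "prior_venous_thrombosis": [0, 1, 0, 0, 0],
        "constitutional_symptoms": [0, 0, 0, 1, 0],
        "pruritus": [1, 0, 0, 0, 0],
        "leukocytes": [9.0, 12.0, 15.0, 8.0, 11.0],
        "platelets": [450, 600, 300, 500, 400],
        "neutrophil_lymphocyte_ratio": [3.0, 5.5, 4.0, 2.0, 6.0],
        "driver": ["V617F"] * 5,
        "driver_vaf": [40, 20, 70, 35, 55],
        # p1 transformed at 5 then died at 7; p2 censored alive at 10;
        # p3 died at 4 untransformed; p4 transformed at 2, alive at 9;
        # p5 censored at 12
        "time_transformation": [5.0, np.nan, np.nan, 2.0, np.nan],
        "event_transformation": [1, 0, 0, 1, 0],
        "time_death": [7.0, np.nan, 4.0, np.nan, np.nan],
        "event_death": [1, 0, 1, 0, 0],
        "time_censor": [8.0, 10.0, 6.0, 9.0, 12.0],
    })
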