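"""Shared fixtures: compact cohort builders and small synthetic cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from radharm.cohort import CohortTable, RESERVED_COLUMNS


def build_cohort(rows: list[dict], n_features: int = 3,
                 feature_rng: np.random.Generator | None = None) -> CohortTable:
    """Build a cohort from compact row dicts.

    Each row needs scan_id; patient/nodule ids, labels and acquisition
    levels default sensibly; feature values default to standard normals
    (seeded) unless given as a "features" list.
    """
    rng = feature_rng or np.random.default_rng(0)
    feature_names = [f"f{i}" for i in range(n_features)]
    out = []
    for r in rows:
        rec = {
            "scan_id": r["scan_id"],
            "patient_id": r.get("patient_id", "P_" + r["scan_id"]),
            "nodule_id": r.get("nodule_id", "N_" + r["scan_id"]),
            "dataset_label": r.get("dataset_label", "EARLY"),
            "endpoint_label": r.get("endpoint_label", "BENIGN"),
            "CE": r.get("CE", "no"),
            "KVP": r.get("KVP", "120"),
            "FOCAL_SPOT": r.get("FOCAL_SPOT", "small"),
            "MANUFACTURER": r.get("MANUFACTURER", "A"),
        }
        feats = r.get("features", rng.normal(size=n_features))
        rec.update(dict(zip(feature_names, np.asarray(feats, float))))
        out.append(rec)
    df = pd.DataFrame(out, columns=list(RESERVED_COLUMNS) + feature_names)
    return CohortTable(df, feature_names)


@pytest.fixture
def toy_cohort() -> CohortTable:
    """Six-scan cohort spanning all three datasets."""
    return build_cohort([
        {"scan_id": "S1", "patient_id": "P1", "nodule_id": "N1"},
        {"scan_id": "S2", "patient_id": "P1", "nodule_id": "N1", "CE": "yes"},
        {"scan_id": "S3", "patient_id": "P2", "nodule_id": "N2",
         "endpoint_label": "MALIGNANT"},
        {"scan_id": "S4", "patient_id": "P3", "nodule_id": "N3",
         "dataset_label": "AUG_BENIGN"},
        {"scan_id": "S5", "patient_id": "P2", "nodule_id": "N2",
         "dataset_label": "AUG_MALIGNANT", "endpoint_label": "MALIGNANT"},
        {"scan_id": "S6", "patient_id": "P4", "nodule_id": "N4",
         "dataset_label": "AUG_MALIGNANT", "endpoint_label": "MALIGNANT",
         "KVP": "100"},
    ])


@pytest.fixture(scope="session")
def default_cohort():
    """One full-scale synthetic cohort under the default study conditions."""
    from radharm.simulate import default_config, generate_cohort

    return generate_cohort(default_config(), seed=11)
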