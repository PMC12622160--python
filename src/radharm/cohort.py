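"""Scan-level cohort tables: data model, CSV I/O, structural validation.

A cohort is one row per CT scan of a pulmonary nodule (PN).  Reserved
metadata columns identify the scan, its patient and nodule, the dataset it
belongs to (early-development vs. the two augmentation datasets), the
endpoint diagnosis reached after follow-up, and four categorical
acquisition parameters.  All remaining columns are numeric radiomic
features shared, in order, by every scan in the cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class DatasetLabel(str, Enum):
    """Which dataset a scan belongs to.

    EARLY: interpreted benign / probably benign / indeterminate at scan
    time; the only dataset models are ever tested on.  AUG_BENIGN /
    AUG_MALIGNANT: later-development scans with a confirmed endpoint, used
    only to augment training sets.
    """

    EARLY = "EARLY"
    AUG_BENIGN = "AUG_BENIGN"
    AUG_MALIGNANT = "AUG_MALIGNANT"


class EndpointLabel(str, Enum):
    """Final benign/malignant diagnosis of the nodule after follow-up."""

    BENIGN = "BENIGN"
    MALIGNANT = "MALIGNANT"


#: Acquisition parameters harmonization corrects for, in canonical order.
ACQUISITION_PARAMETERS: tuple[str, ...] = ("CE", "KVP", "FOCAL_SPOT", "MANUFACTURER")

#: Reserved (non-feature) columns, in file order.
RESERVED_COLUMNS: tuple[str, ...] = (
    "scan_id",
    "patient_id",
    "nodule_id",
    "dataset_label",
    "endpoint_label",
) + ACQUISITION_PARAMETERS


class CohortError(ValueError):
    """Schema, parse or integrity problem in a cohort file or table."""


@dataclass(frozen=True)
class ScanRecord:
    """One scan of one nodule, with metadata and its feature vector."""

    scan_id: str
    patient_id: str
    nodule_id: str
    dataset_label: DatasetLabel
    endpoint_label: EndpointLabel
    acquisition: Mapping[str, str]
    features: np.ndarray

    def __post_init__(self) -> None:
        missing = [p for p in ACQUISITION_PARAMETERS if p not in self.acquisition]
        if missing:
            raise CohortError(
                f"scan {self.scan_id!r}: missing acquisition parameters {missing}"
            )


@dataclass
class CohortTable:
    """A cohort of scans backed by a pandas DataFrame.

    ``df`` holds the reserved columns followed by the feature columns (in
    ``feature_names`` order).  Rows are scans; ``scan_id`` values are
    expected (and validated) to be unique.
    """

    df: pd.DataFrame
    feature_names: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in RESERVED_COLUMNS if c not in self.df.columns]
        if missing:
            raise CohortError(f"cohort missing reserved columns {missing}")
        if not self.feature_names:
            raise CohortError("cohort must have at least one feature column")
        missing_f = [c for c in self.feature_names if c not in self.df.columns]
        if missing_f:
            raise CohortError(f"cohort missing feature columns {missing_f[:5]}")
        self.df = self.df.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def feature_matrix(self) -> np.ndarray:
        """Scans x features array of the feature block."""
        return self.df[self.feature_names].to_numpy(dtype=float)

    def with_features(self, values: np.ndarray, provenance: str | None = None) -> "CohortTable":
        """Copy of the cohort with the feature block replaced (same shape)."""
        if values.shape != (len(self), self.n_features):
            raise CohortError(
                f"feature block shape {values.shape} does not match cohort "
                f"({len(self)}, {self.n_features})"
            )
        df = self.df.copy()
        df[self.feature_names] = values
        return CohortTable(df, list(self.feature_names),
                           self.provenance if provenance is None else provenance)

    def subset(self, mask_or_ids: Iterable) -> "CohortTable":
        """Sub-cohort by boolean mask or iterable of scan_ids (order kept)."""
        arr = np.asarray(list(mask_or_ids))
        if arr.dtype == bool:
            df = self.df.loc[arr]
        else:
            df = self.df[self.df["scan_id"].isin(set(arr))]
        return CohortTable(df.copy(), list(self.feature_names), self.provenance)

    def select_dataset(self, label: DatasetLabel | str) -> "CohortTable":
        label = DatasetLabel(label)
        return self.subset((self.df["dataset_label"] == label.value).to_numpy())

    def scan_ids(self) -> list[str]:
        return self.df["scan_id"].tolist()

    def endpoint_binary(self) -> np.ndarray:
        """0/1 vector, 1 = malignant endpoint."""
        return (self.df["endpoint_label"] == EndpointLabel.MALIGNANT.value).to_numpy(int)

    def records(self) -> list[ScanRecord]:
        out = []
        for _, row in self.df.iterrows():
            out.append(
                ScanRecord(
                    scan_id=str(row["scan_id"]),
                    patient_id=str(row["patient_id"]),
                    nodule_id=str(row["nodule_id"]),
                    dataset_label=DatasetLabel(row["dataset_label"]),
                    endpoint_label=EndpointLabel(row["endpoint_label"]),
                    acquisition={p: str(row[p]) for p in ACQUISITION_PARAMETERS},
                    features=row[self.feature_names].to_numpy(dtype=float),
                )
            )
        return out


def cohort_from_records(records: Sequence[ScanRecord], feature_names: Sequence[str],
                        provenance: str = "") -> CohortTable:
    rows = []
    for r in records:
        row: dict = {
            "scan_id": r.scan_id,
            "patient_id": r.patient_id,
            "nodule_id": r.nodule_id,
            "dataset_label": DatasetLabel(r.dataset_label).value,
            "endpoint_label": EndpointLabel(r.endpoint_label).value,
        }
        for p in ACQUISITION_PARAMETERS:
            row[p] = str(r.acquisition[p])
        if len(r.features) != len(feature_names):
            raise CohortError(
                f"scan {r.scan_id!r}: {len(r.features)} features, "
                f"expected {len(feature_names)}"
            )
        row.update(dict(zip(feature_names, r.features)))
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(RESERVED_COLUMNS) + list(feature_names))
    return CohortTable(df, list(feature_names), provenance)


# -- I/O ------------------------------------------------------------------


def read_cohort(path: str | Path, delimiter: str = ",") -> CohortTable:
    """Read a cohort CSV written by :func:`write_cohort` (or equivalent).

    The header must contain all reserved columns; every remaining column is
    treated as a feature, in file order.
    """
    path = Path(path)
    df = pd.read_csv(path, delimiter=delimiter, dtype=str)
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"{path}: missing required column(s) {missing}")
    feature_names = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if not feature_names:
        raise CohortError(f"{path}: no feature columns found")
    for col in feature_names:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"  # +2: header + 1-based
            raise CohortError(
                f"{path}: non-numeric feature value in column {col!r}, file line {row}"
            ) from exc
    vals = df[feature_names].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise CohortError(f"{path}: non-finite feature values present")
    dup = df["scan_id"][df["scan_id"].duplicated()]
    if len(dup):
        raise CohortError(f"{path}: duplicate scan_id(s): {sorted(set(dup))[:5]}")
    for p in ("dataset_label",):
        bad = set(df[p]) - {d.value for d in DatasetLabel}
        if bad:
            raise CohortError(f"{path}: unknown dataset_label value(s) {sorted(bad)}")
    bad = set(df["endpoint_label"]) - {e.value for e in EndpointLabel}
    if bad:
        raise CohortError(f"{path}: unknown endpoint_label value(s) {sorted(bad)}")
    if df[list(ACQUISITION_PARAMETERS)].isna().any().any():
        raise CohortError(f"{path}: missing acquisition values are not allowed")
    return CohortTable(df, feature_names, provenance=str(path))


def write_cohort(cohort: CohortTable, path: str | Path, delimiter: str = ",") -> Path:
    """Write a cohort CSV; features at 15 significant digits so a read
    round-trip preserves values well within 1e-9."""
    path = Path(path)
    cohort.df.to_csv(path, sep=delimiter, index=False, float_format="%.15g")
    return path


# -- validation -----------------------------------------------------------


@dataclass
class Issue:
    severity: str  # "ERROR" | "WARNING"
    where: str     # scan_id or "global"
    message: str


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)
    dataset_counts: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "ERROR" for i in self.issues)

    def to_json(self) -> str:
        return json.dumps(
            {
                "ok": self.ok,
                "issues": [vars(i) for i in self.issues],
                "dataset_counts": self.dataset_counts,
            },
            indent=2,
        )


def validate_cohort(cohort: CohortTable) -> ValidationReport:
    """Check structural invariants; problems are reported, never raised.

    A nodule appearing in both the early-development and an augmentation
    dataset is legitimate (augmentation datasets contain follow-up scans of
    early-development nodules) and is not flagged.
    """
    rep = ValidationReport()
    df = cohort.df

    dup = df["scan_id"][df["scan_id"].duplicated()]
    for sid in sorted(set(dup)):
        rep.issues.append(Issue("ERROR", str(sid), "duplicate scan_id"))

    # a nodule belongs to exactly one patient
    pat_per_nod = df.groupby("nodule_id")["patient_id"].nunique()
    for nod in pat_per_nod.index[pat_per_nod > 1]:
        rep.issues.append(
            Issue("ERROR", "global", f"nodule {nod!r} maps to multiple patients")
        )

    # augmentation datasets carry confirmed endpoints
    bad_b = df[(df["dataset_label"] == DatasetLabel.AUG_BENIGN.value)
               & (df["endpoint_label"] != EndpointLabel.BENIGN.value)]
    for sid in bad_b["scan_id"]:
        rep.issues.append(Issue("ERROR", str(sid),
                                "AUG_BENIGN scan with non-benign endpoint"))
    bad_m = df[(df["dataset_label"] == DatasetLabel.AUG_MALIGNANT.value)
               & (df["endpoint_label"] != EndpointLabel.MALIGNANT.value)]
    for sid in bad_m["scan_id"]:
        rep.issues.append(Issue("ERROR", str(sid),
                                "AUG_MALIGNANT scan with non-malignant endpoint"))

    # a nodule's endpoint must be consistent across its scans
    ep_per_nod = df.groupby("nodule_id")["endpoint_label"].nunique()
    for nod in ep_per_nod.index[ep_per_nod > 1]:
        rep.issues.append(
            Issue("ERROR", "global", f"nodule {nod!r} has conflicting endpoints")
        )

    feats = cohort.feature_matrix()
    if not np.all(np.isfinite(feats)):
        bad_rows = np.where(~np.isfinite(feats).all(axis=1))[0]
        for i in bad_rows:
            rep.issues.append(Issue("ERROR", str(df["scan_id"].iloc[i]),
                                    "non-finite feature value"))

    for p in ACQUISITION_PARAMETERS:
        na = df[p].isna() | (df[p].astype(str).str.len() == 0)
        for sid in df["scan_id"][na]:
            rep.issues.append(Issue("ERROR", str(sid),
                                    f"missing acquisition value for {p}"))

    for label in DatasetLabel:
        sub = df[df["dataset_label"] == label.value]
        n = len(sub)
        pct = (
            100.0 * (sub["endpoint_label"] == EndpointLabel.MALIGNANT.value).mean()
            if n else 0.0
        )
        rep.dataset_counts[label.value] = {"scans": n, "pct_malignant": pct}
    rep.dataset_counts["Total"] = {
        "scans": len(df),
        "pct_malignant": (
            100.0 * (df["endpoint_label"] == EndpointLabel.MALIGNANT.value).mean()
            if len(df) else 0.0
        ),
    }
    return rep
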