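"""Build clinarray matrices from longitudinal lab records and prune them.

A clinarray summarizes one patient's laboratory history as a vector of
per-biomarker medians over all hospital visits.  Stacking the clinarrays
of a cohort yields a biomarkers x patients matrix (rows = biomarkers,
columns = patients) with explicit missingness wherever a patient never
had a given test.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "build_clinarray",
    "prune",
    "PruneReport",
    "read_records",
    "write_matrix",
    "read_matrix",
]

RECORD_COLUMNS = ["patient_id", "biomarker", "value", "visit_date"]
MISSING_TOKEN = "NA"


@dataclass
class PruneReport:
    """Counts from the two sequential pruning passes.

    Pass 1 removes patients with fewer than ``min_biomarkers_per_patient``
    distinct observed biomarkers; pass 2 removes biomarkers observed in
    fewer than ``min_patient_fraction`` of the patients that survived
    pass 1.  The passes run exactly once, in that order: biomarker removal
    can push a surviving patient back under the patient threshold, and such
    patients are reported (``n_subthreshold_patients_after``) rather than
    re-filtered.
    """

    n_biomarkers_before: int = 0
    n_patients_before: int = 0
    n_patients_after: int = 0
    n_biomarkers_after: int = 0
    patients_removed: list = field(default_factory=list)
    biomarkers_removed: list = field(default_factory=list)
    min_biomarkers_per_patient: int = 10
    min_patient_fraction: float = 0.5
    n_subthreshold_patients_after: int = 0

    def summary(self) -> str:
        lines = [
            "pruning report",
            f"  patient threshold: >= {self.min_biomarkers_per_patient} observed biomarkers",
            f"  biomarker threshold: observed in >= {self.min_patient_fraction:.0%} of remaining patients",
            f"  patients:   {self.n_patients_before} -> {self.n_patients_after} "
            f"({len(self.patients_removed)} removed)",
            f"  biomarkers: {self.n_biomarkers_before} -> {self.n_biomarkers_after} "
            f"({len(self.biomarkers_removed)} removed)",
            f"  patients below threshold after biomarker pass: "
            f"{self.n_subthreshold_patients_after}",
        ]
        return "\n".join(lines)


def _validate_records(records: pd.DataFrame) -> None:
    if len(records) == 0:
        raise ValueError("cannot build a clinarray from an empty record list")
    missing_cols = [c for c in RECORD_COLUMNS[:3] if c not in records.columns]
    if missing_cols:
        raise ValueError(f"records are missing required columns: {missing_cols}")
    values = pd.to_numeric(records["value"], errors="coerce")
    bad = ~np.isfinite(values.to_numpy(dtype=float))
    if bad.any():
        i = int(np.argmax(bad))
        row = records.iloc[i]
        raise ValueError(
            f"non-finite lab value at record {records.index[i]} "
            f"(patient {row['patient_id']}, biomarker {row['biomarker']}): "
            f"{row['value']!r}"
        )


def build_clinarray(records: pd.DataFrame) -> pd.DataFrame:
    """Aggregate lab records into a biomarkers x patients median matrix.

    Cell (b, p) is the median of all measurements of biomarker b for
    patient p, across every visit; the even-count median is the midpoint
    of the two central values.  Pairs with no records are left missing
    (NaN).  Row order follows first appearance of each biomarker in the
    record table, column order first appearance of each patient.
    """
    _validate_records(records)
    biomarker_order = records["biomarker"].unique()
    patient_order = records["patient_id"].unique()
    medians = records.groupby(["biomarker", "patient_id"], sort=False)["value"].median()
    matrix = medians.unstack("patient_id")
    matrix = matrix.reindex(index=biomarker_order, columns=patient_order)
    matrix.index.name = "biomarker"
    matrix.columns.name = "patient_id"
    return matrix


def prune(
    matrix: pd.DataFrame,
    min_biomarkers_per_patient: int = 10,
    min_patient_fraction: float = 0.5,
) -> tuple[pd.DataFrame, PruneReport]:
    """Apply the two cohort-quality filters, once each, patients first.

    1. Drop every patient (column) with fewer than
       ``min_biomarkers_per_patient`` observed biomarkers (strict ``<``).
    2. Among the remaining patients, drop every biomarker (row) observed
       in fewer than ``min_patient_fraction`` of them (inclusive ``>=``
       survives: a biomarker observed in exactly half the patients is
       kept).

    Surviving cell values are never altered.  Raises if either pass
    empties the matrix.
    """
    report = PruneReport(
        n_biomarkers_before=matrix.shape[0],
        n_patients_before=matrix.shape[1],
        min_biomarkers_per_patient=min_biomarkers_per_patient,
        min_patient_fraction=min_patient_fraction,
    )
    observed = matrix.notna()

    patient_counts = observed.sum(axis=0)
    keep_patients = patient_counts >= min_biomarkers_per_patient
    report.patients_removed = list(matrix.columns[~keep_patients])
    pruned = matrix.loc[:, keep_patients]
    if pruned.shape[1] == 0:
        raise ValueError("empty after pruning: every patient fell below the threshold")

    n_remaining = pruned.shape[1]
    biomarker_counts = pruned.notna().sum(axis=1)
    keep_biomarkers = biomarker_counts >= min_patient_fraction * n_remaining
    report.biomarkers_removed = list(pruned.index[~keep_biomarkers])
    pruned = pruned.loc[keep_biomarkers, :]
    if pruned.shape[0] == 0:
        raise ValueError("empty after pruning: every biomarker fell below the threshold")

    report.n_biomarkers_after, report.n_patients_after = pruned.shape
    report.n_subthreshold_patients_after = int(
        (pruned.notna().sum(axis=0) < min_biomarkers_per_patient).sum()
    )
    return pruned, report


# ---------------------------------------------------------------------------
# delimited-text I/O (tab-separated, "NA" missing token, header row)

def read_records(path: str | pathlib.Path) -> pd.DataFrame:
    records = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "biomarker": str})
    _validate_records(records)
    return records


def write_matrix(matrix: pd.DataFrame, path: str | pathlib.Path) -> None:
    matrix.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)


def read_matrix(path: str | pathlib.Path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0, na_values=[MISSING_TOKEN])
    matrix.index.name = "biomarker"
    matrix.columns.name = "patient_id"
    return matrix
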