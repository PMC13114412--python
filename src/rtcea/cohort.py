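"""Patient-level cohort data model and arm-level aggregation.

A cohort is a collection of :class:`PatientRecord` objects, one per patient,
carrying the radiotherapy technique, the cancer-type stratum, the direct
medical and direct non-medical cost (EUR) and a three-point utility
trajectory (baseline, end of treatment, 6-month follow-up).  Records are
read from and written to delimited text files with a configurable column
mapping so exports from different hospitals can be ingested unchanged.

Aggregation produces :class:`ArmSummary` rows (n, mean and sample SD of
total cost and of QALY per strategy or per cancer type) and n-weighted
pooled totals across arms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Closed vocabulary of radiotherapy techniques (treatment arms).
TECHNIQUES: tuple[str, ...] = ("2D", "3D-CRT", "IMRT", "VMAT")

#: Closed vocabulary of cancer-type strata.
CANCER_TYPES: tuple[str, ...] = (
    "head_and_neck",
    "breast",
    "lung",
    "prostate",
    "skin",
    "endometrial",
    "bone_metastasis",
    "rectal",
    "pancreas",
    "stomach",
    "bladder",
    "sarcoma",
)

#: Default mapping from logical field names to file column headers.
DEFAULT_COLUMNS: dict[str, str] = {
    "patient_id": "patient_id",
    "technique": "technique",
    "cancer_type": "cancer_type",
    "direct_medical_cost": "direct_medical_cost",
    "direct_nonmedical_cost": "direct_nonmedical_cost",
    "utility_baseline": "utility_baseline",
    "utility_end_of_treatment": "utility_end_of_treatment",
    "utility_followup": "utility_followup",
}


class CohortValidationError(ValueError):
    """A cohort row violates the data model; the message names the row."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: arm, stratum, cost components, utility trajectory.

    ``utilities`` holds exactly three slots (baseline, end of treatment,
    follow-up); a ``None`` slot marks a missing measurement and flags the
    record incomplete.  Utilities live on the index scale, in [-1, 1]
    (negative values encode states worse than death).
    """

    patient_id: str
    technique: str
    cancer_type: str
    direct_medical_cost: float
    direct_nonmedical_cost: float
    utilities: tuple[float | None, float | None, float | None]

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: unknown technique {self.technique!r}; "
                f"expected one of {TECHNIQUES}"
            )
        if self.cancer_type not in CANCER_TYPES:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: unknown cancer_type {self.cancer_type!r}; "
                f"expected one of {CANCER_TYPES}"
            )
        for name in ("direct_medical_cost", "direct_nonmedical_cost"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise CohortValidationError(
                    f"patient {self.patient_id!r}: {name} must be finite and >= 0, got {value}"
                )
        if len(self.utilities) != 3:
            raise CohortValidationError(
                f"patient {self.patient_id!r}: exactly three utility slots required"
            )
        for u in self.utilities:
            if u is not None and not (math.isfinite(u) and -1.0 <= u <= 1.0):
                raise CohortValidationError(
                    f"patient {self.patient_id!r}: utility {u} outside [-1, 1]"
                )

    @property
    def total_cost(self) -> float:
        """Total patient cost: direct medical plus direct non-medical."""
        return self.direct_medical_cost + self.direct_nonmedical_cost

    @property
    def is_complete(self) -> bool:
        """True when all three utility measurements are present."""
        return all(u is not None for u in self.utilities)


@dataclass(frozen=True)
class ArmSummary:
    """n, mean and sample SD of cost and QALY for one strategy or subgroup.

    ``cost_sd``/``qaly_sd`` are ``None`` when undefined (group of size 1).
    The QALY mean may be negative (worse-than-death utility states).
    """

    label: str
    n: int
    cost_mean: float
    cost_sd: float | None
    qaly_mean: float
    qaly_sd: float | None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"arm {self.label!r}: n must be >= 1")
        if self.cost_mean < 0:
            raise ValueError(f"arm {self.label!r}: cost_mean must be >= 0")
        for name in ("cost_sd", "qaly_sd"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"arm {self.label!r}: {name} must be >= 0")


@dataclass(frozen=True)
class ComparatorSpec:
    """Literature-derived comparator arm (no radiotherapy / best supportive care).

    Shares the numeric constraints of :class:`ArmSummary` but carries no
    patient count; ``provenance`` must cite where the figures come from.
    """

    label: str
    cost_mean: float
    cost_sd: float | None
    qaly_mean: float
    qaly_sd: float | None
    provenance: str

    def __post_init__(self) -> None:
        if not self.provenance or not self.provenance.strip():
            raise ValueError(
                f"comparator {self.label!r}: provenance citation note is required"
            )
        if self.cost_mean < 0:
            raise ValueError(f"comparator {self.label!r}: cost_mean must be >= 0")
        for name in ("cost_sd", "qaly_sd"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"comparator {self.label!r}: {name} must be >= 0")


def _row_utility(value: object) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)  # range-checked by PatientRecord


def read_cohort(
    path: str,
    columns: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[PatientRecord]:
    """Read a delimited cohort file into validated :class:`PatientRecord` objects.

    ``columns`` maps logical field names (keys of :data:`DEFAULT_COLUMNS`)
    to the file's header names.  Unknown technique or cancer labels and
    negative costs raise :class:`CohortValidationError` naming the
    offending data row (1-based, excluding the header); missing utilities
    keep the record, flagged incomplete.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    frame = pd.read_csv(path, sep=delimiter, dtype={colmap["patient_id"]: str})
    missing = [c for c in colmap.values() if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"{path}: missing required columns {missing}")

    records: list[PatientRecord] = []
    n_incomplete = 0
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row_d = dict(zip(frame.columns, row))
        try:
            record = PatientRecord(
                patient_id=str(row_d[colmap["patient_id"]]),
                technique=str(row_d[colmap["technique"]]),
                cancer_type=str(row_d[colmap["cancer_type"]]),
                direct_medical_cost=float(row_d[colmap["direct_medical_cost"]]),
                direct_nonmedical_cost=float(row_d[colmap["direct_nonmedical_cost"]]),
                utilities=(
                    _row_utility(row_d[colmap["utility_baseline"]]),
                    _row_utility(row_d[colmap["utility_end_of_treatment"]]),
                    _row_utility(row_d[colmap["utility_followup"]]),
                ),
            )
        except CohortValidationError as exc:
            raise CohortValidationError(f"{path}, data row {i}: {exc}") from exc
        if not record.is_complete:
            n_incomplete += 1
        records.append(record)

    if not records:
        logger.warning("%s: cohort file contains no data rows", path)
    logger.info(
        "%s: read %d patient records (%d with incomplete utility trajectories)",
        path,
        len(records),
        n_incomplete,
    )
    return records


def write_cohort(
    records: Iterable[PatientRecord],
    path: str,
    columns: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> None:
    """Write records to a delimited file readable by :func:`read_cohort`."""
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)
    rows = []
    for r in records:
        rows.append(
            {
                colmap["patient_id"]: r.patient_id,
                colmap["technique"]: r.technique,
                colmap["cancer_type"]: r.cancer_type,
                colmap["direct_medical_cost"]: r.direct_medical_cost,
                colmap["direct_nonmedical_cost"]: r.direct_nonmedical_cost,
                colmap["utility_baseline"]: r.utilities[0],
                colmap["utility_end_of_treatment"]: r.utilities[1],
                colmap["utility_followup"]: r.utilities[2],
            }
        )
    pd.DataFrame(rows, columns=list(colmap.values())).to_csv(
        path, sep=delimiter, index=False
    )


def _mean_sd(values: Sequence[float]) -> tuple[float, float | None]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, None
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def summarize_arms(
    records: Sequence[PatientRecord],
    qalys: Mapping[str, float],
    group_by: str = "technique",
) -> list[ArmSummary]:
    """Aggregate patients into per-group cost/QALY summaries.

    ``qalys`` maps patient_id to the patient's QALY; patients absent from
    the mapping (incomplete trajectories) contribute to cost moments but
    are excluded from QALY moments, with a logged count.  Sample SDs use
    the n-1 denominator; a group of size 1 reports its SD as missing.
    Groups are emitted in vocabulary order.
    """
    if group_by not in ("technique", "cancer_type"):
        raise ValueError(f"group_by must be 'technique' or 'cancer_type', got {group_by!r}")
    order = TECHNIQUES if group_by == "technique" else CANCER_TYPES

    groups: dict[str, list[PatientRecord]] = {}
    for r in records:
        groups.setdefault(getattr(r, group_by), []).append(r)

    summaries: list[ArmSummary] = []
    for label in order:
        members = groups.get(label)
        if not members:
            continue
        costs = [r.total_cost for r in members]
        with_qaly = [r for r in members if r.patient_id in qalys]
        if len(with_qaly) < len(members):
            logger.info(
                "group %r: %d of %d patients lack a QALY and are excluded "
                "from QALY moments",
                label,
                len(members) - len(with_qaly),
                len(members),
            )
        if not with_qaly:
            raise ValueError(f"group {label!r}: no patient has a QALY value")
        qvals = [qalys[r.patient_id] for r in with_qaly]
        cost_mean, cost_sd = _mean_sd(costs)
        qaly_mean, qaly_sd = _mean_sd(qvals)
        if len(members) == 1:
            logger.warning("group %r has a single patient; SDs reported as missing", label)
        summaries.append(
            ArmSummary(
                label=label,
                n=len(members),
                cost_mean=cost_mean,
                cost_sd=cost_sd,
                qaly_mean=qaly_mean,
                qaly_sd=qaly_sd,
            )
        )
    return summaries


def pool_arms(summaries: Sequence[ArmSummary], label: str = "Total") -> ArmSummary:
    """n-weighted pooling of arm summaries into a single total row.

    Pooled means are exact (weighted means of group means); pooled SDs are
    not derivable from group moments alone and are reported as missing.
    """
    if not summaries:
        raise ValueError("pool_arms requires at least one summary")
    n = sum(s.n for s in summaries)
    cost_mean = sum(s.n * s.cost_mean for s in summaries) / n
    qaly_mean = sum(s.n * s.qaly_mean for s in summaries) / n
    if len(summaries) == 1:
        return replace(summaries[0], label=label)
    return ArmSummary(
        label=label, n=n, cost_mean=cost_mean, cost_sd=None,
        qaly_mean=qaly_mean, qaly_sd=None,
    )
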