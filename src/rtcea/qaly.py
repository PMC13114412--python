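"""EQ-5D-5L utility scoring and QALY construction by the AUC method.

Utilities come either directly (already on the index scale) or from
EQ-5D-5L profiles mapped through a pluggable value set (tariff): a
country-specific additive coefficient table.  A value set is a delimited
file with columns ``dimension, level, decrement`` holding one non-positive
decrement per dimension x level (levels 2-5); full health (profile 11111)
anchors at utility 1.

QALYs are the area under the piecewise-linear utility-versus-time curve
over the study window, computed by the trapezoidal rule, optionally with
last-value carry-forward when the accrual horizon extends past the final
measurement.  No discounting is applied anywhere: the horizon is short
(months, not years).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import PatientRecord

logger = logging.getLogger(__name__)

DIMENSIONS: tuple[str, ...] = (
    "mobility",
    "self_care",
    "usual_activities",
    "pain_discomfort",
    "anxiety_depression",
)
LEVELS = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class EQ5DProfile:
    """An EQ-5D-5L health state: five dimension levels, each in 1..5."""

    mobility: int
    self_care: int
    usual_activities: int
    pain_discomfort: int
    anxiety_depression: int

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            level = getattr(self, dim)
            if level not in LEVELS:
                raise ValueError(f"{dim} level must be in 1..5, got {level}")

    @classmethod
    def from_digits(cls, digits: str | int) -> "EQ5DProfile":
        """Build a profile from its 5-digit state code, e.g. ``'21345'``."""
        s = str(digits)
        if len(s) != 5 or not s.isdigit():
            raise ValueError(f"state code must be five digits, got {digits!r}")
        return cls(*(int(c) for c in s))

    def levels(self) -> tuple[int, int, int, int, int]:
        return tuple(getattr(self, d) for d in DIMENSIONS)  # type: ignore[return-value]


class IncompleteValueSetError(ValueError):
    """The tariff table lacks a required dimension x level cell."""


@dataclass(frozen=True)
class ValueSet:
    """Additive EQ-5D tariff: utility = intercept + sum of level decrements.

    ``decrements[(dimension, level)]`` is the (non-positive) utility change
    for reporting ``level`` > 1 on ``dimension``.  The intercept is the
    full-health utility, 1 by construction of EQ-5D index scales.
    """

    name: str
    decrements: Mapping[tuple[str, int], float]
    intercept: float = 1.0

    def __post_init__(self) -> None:
        for dim in DIMENSIONS:
            for level in LEVELS[1:]:
                key = (dim, level)
                if key not in self.decrements:
                    raise IncompleteValueSetError(
                        f"value set {self.name!r}: missing decrement for "
                        f"dimension {dim!r} level {level}"
                    )
                if self.decrements[key] > 0:
                    raise ValueError(
                        f"value set {self.name!r}: decrement for {dim!r} level "
                        f"{level} must be <= 0, got {self.decrements[key]}"
                    )

    @property
    def floor(self) -> float:
        """Minimum attainable utility (the 55555 state)."""
        return self.intercept + sum(
            self.decrements[(dim, 5)] for dim in DIMENSIONS
        )

    @classmethod
    def from_file(cls, path, name: str | None = None, delimiter: str = ",") -> "ValueSet":
        """Load a tariff from a ``dimension, level, decrement`` table."""
        frame = pd.read_csv(path, sep=delimiter)
        required = {"dimension", "level", "decrement"}
        if not required.issubset(frame.columns):
            raise ValueError(f"{path}: tariff file needs columns {sorted(required)}")
        decs = {
            (str(row.dimension), int(row.level)): float(row.decrement)
            for row in frame.itertuples(index=False)
        }
        return cls(name=name or str(path), decrements=decs)


def toy_value_set() -> ValueSet:
    """The packaged toy tariff fixture (not a published national value set)."""
    with resources.as_file(
        resources.files("rtcea.data").joinpath("toy_valueset.csv")
    ) as p:
        return ValueSet.from_file(p, name="toy-fixture")


def eq5d_index(profile: EQ5DProfile, tariff: ValueSet) -> float:
    """Map a profile to its utility under the tariff (deterministic)."""
    utility = tariff.intercept
    for dim, level in zip(DIMENSIONS, profile.levels()):
        if level > 1:
            utility += tariff.decrements[(dim, level)]
    return utility


# ---------------------------------------------------------------------------
# Trajectories and the AUC method


@dataclass(frozen=True)
class TimingConfig:
    """Measurement times (years from RT start) and the QALY accrual horizon.

    Defaults: baseline at 0, end of treatment at 6 weeks (0.115 yr),
    follow-up half a year later, horizon equal to the follow-up time (no
    carry-forward).  The study design fixes the calendar of the three
    measurements only loosely, so all times are configurable.
    """

    t_baseline: float = 0.0
    t_end_of_treatment: float = 0.115
    t_followup: float = 0.615
    horizon: float = 0.615

    def __post_init__(self) -> None:
        if not (self.t_baseline < self.t_end_of_treatment < self.t_followup):
            raise ValueError("measurement times must be strictly increasing")
        if self.horizon < self.t_followup:
            raise ValueError("horizon must be >= the follow-up time")

    @property
    def times(self) -> tuple[float, float, float]:
        return (self.t_baseline, self.t_end_of_treatment, self.t_followup)


@dataclass(frozen=True)
class UtilityTrajectory:
    """Three utility measurements on a time axis, with an accrual horizon."""

    times: tuple[float, float, float]
    utilities: tuple[float, float, float]
    horizon: float

    def __post_init__(self) -> None:
        t0, t1, t2 = self.times
        if not (t0 < t1 < t2):
            raise ValueError(f"times must be strictly increasing, got {self.times}")
        if self.horizon < t2:
            raise ValueError("horizon must be >= the last measurement time")
        if not all(np.isfinite(self.utilities)):
            raise ValueError(f"utilities must be finite, got {self.utilities}")


def auc_qaly(traj: UtilityTrajectory) -> float:
    """QALY = trapezoidal area under the piecewise-linear utility curve.

    Integrates over [t0, t2]; if the horizon extends past t2 the final
    utility is carried forward, contributing (horizon - t2) * u2.
    Units: utility-years.
    """
    area = float(np.trapezoid(traj.utilities, traj.times))
    if traj.horizon > traj.times[-1]:
        area += (traj.horizon - traj.times[-1]) * traj.utilities[-1]
    return area


def cohort_qalys(
    records: Iterable[PatientRecord],
    timing: TimingConfig | None = None,
) -> dict[str, float]:
    """Per-patient QALYs for all complete records, keyed by patient_id.

    Records with any missing utility are skipped with a logged count.
    Utilities are taken as already on the index scale (profiles are mapped
    beforehand with :func:`eq5d_index`).
    """
    timing = timing or TimingConfig()
    out: dict[str, float] = {}
    skipped = 0
    for r in records:
        if not r.is_complete:
            skipped += 1
            continue
        out[r.patient_id] = auc_qaly(
            UtilityTrajectory(
                times=timing.times,
                utilities=r.utilities,  # type: ignore[arg-type]
                horizon=timing.horizon,
            )
        )
    if skipped:
        logger.info("cohort_qalys: skipped %d incomplete records", skipped)
    return out
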