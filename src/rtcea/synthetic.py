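"""Synthetic patient-level cohorts with prescribed arm-level moments.

The hospital cohort behind the bundled summary tables is not public, so
this module generates patient-level stand-ins with the statistical
structure the analysis assumes: per arm, total costs drawn from a
moment-fitted Gamma, split 80/20 into direct medical and non-medical
components; per patient, a target QALY drawn from the arm's Beta
(moment-fitted, repaired when the printed moments are Beta-infeasible)
and a three-point utility trajectory solved *exactly* to that target
under the spec's timing, so arm-level QALY moments are recovered up to
Monte Carlo error by construction rather than approximately.

Trajectories follow a clinically shaped pattern — baseline above the
patient's average level, a dip at the end of treatment, recovery at
follow-up — plus per-patient noise; the shape is scaled down per patient
exactly as far as needed to keep all utilities inside [-1, 1] without
disturbing the area under the curve.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CANCER_TYPES, ComparatorSpec, PatientRecord
from .qaly import TimingConfig
from .reference import (
    CANCER_TYPE_TABLE,
    COMPARATOR_PROVENANCE,
    DISTRIBUTION_TABLE,
    TECHNIQUE_TABLE,
    pooled_comparator,
)
from .uncertainty import DEFAULT_SHRINK, fit_gamma_moments, repair_beta

logger = logging.getLogger(__name__)

#: Share of the total patient cost that is direct medical (the remainder
#: is direct non-medical: transportation, accompaniment, out-of-pocket).
MEDICAL_FRACTION: float = 0.8


@dataclass(frozen=True)
class ArmSpec:
    """Target moments and size for one synthetic arm."""

    label: str
    n: int
    cost_mean: float
    cost_sd: float
    qaly_mean: float
    qaly_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"arm {self.label!r}: n must be >= 1")
        if self.cost_sd < 0 or self.qaly_sd < 0:
            raise ValueError(f"arm {self.label!r}: SDs must be >= 0")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full recipe for a synthetic cohort.

    ``timing`` is the accrual calendar the trajectories are solved
    against; the default extends the horizon to one year with last-value
    carry-forward so that every Beta-distributed target QALY in [0, 1] is
    attainable with utilities bounded by 1.  ``baseline_rise`` and
    ``treatment_dip`` shape the trajectory around the patient's average
    utility level; ``noise_sd`` adds patient-level wiggle.  None of the
    three affects arm-level QALY moments (the trajectory is solved to the
    target exactly).
    """

    arms: tuple[ArmSpec, ...]
    strata_weights: dict[str, float] = field(
        default_factory=lambda: {
            k: v["n"] / 301.0 for k, v in CANCER_TYPE_TABLE.items()
        }
    )
    timing: TimingConfig = TimingConfig(horizon=1.0)
    baseline_rise: float = 0.10
    treatment_dip: float = 0.15
    noise_sd: float = 0.05
    medical_fraction: float = MEDICAL_FRACTION
    shrink: float = DEFAULT_SHRINK

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("spec needs at least one arm")
        total = sum(self.strata_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"strata weights must sum to 1, got {total}")
        unknown = set(self.strata_weights) - set(CANCER_TYPES)
        if unknown:
            raise ValueError(f"unknown cancer strata: {sorted(unknown)}")
        if not (0.0 <= self.medical_fraction <= 1.0):
            raise ValueError("medical_fraction must be in [0, 1]")


def default_spec() -> SyntheticSpec:
    """Cohort spec mirroring the reference study's arm structure.

    Arm sizes and QALY means from the technique summary table; cost means
    and all SDs from the published distribution-parameter table.
    """
    arms = tuple(
        ArmSpec(
            label=label,
            n=int(TECHNIQUE_TABLE[label]["n"]),
            cost_mean=DISTRIBUTION_TABLE[label]["cost_mean"],
            cost_sd=DISTRIBUTION_TABLE[label]["cost_sd"],
            qaly_mean=TECHNIQUE_TABLE[label]["rt_qaly"],
            qaly_sd=DISTRIBUTION_TABLE[label]["qaly_sd"],
        )
        for label in TECHNIQUE_TABLE
    )
    return SyntheticSpec(arms=arms)


def _arm_rng(seed: int | None, label: str) -> np.random.Generator:
    key = zlib.crc32(label.encode("utf-8"))
    entropy = [key] if seed is None else [seed, key]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _auc_weights(timing: TimingConfig) -> np.ndarray:
    """Weights w with AUC = w0*u0 + w1*u1 + w2*u2; sum(w) = horizon - t0."""
    t0, t1, t2 = timing.times
    return np.array(
        [(t1 - t0) / 2.0, (t2 - t0) / 2.0, (t2 - t1) / 2.0 + (timing.horizon - t2)]
    )


def _solve_trajectories(
    targets: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Per patient, utilities (n, 3) whose AUC equals the target exactly.

    Start from the constant level c = target / (horizon - t0), add the
    shaped zero-area perturbation plus noise, and shrink the perturbation
    per patient to the largest factor keeping all three utilities in
    [-1, 1].  Targets outside the attainable band [-(T - t0), T - t0] are
    clipped first (counted and logged by the caller).
    """
    w = _auc_weights(spec.timing)
    total_w = w.sum()
    n = targets.size

    c = targets / total_w
    clipped = int(np.sum((c < -1.0) | (c > 1.0)))
    c = np.clip(c, -1.0, 1.0)

    # shaped perturbation with zero AUC contribution
    d0 = spec.baseline_rise + rng.normal(0.0, spec.noise_sd, size=n)
    d1 = -spec.treatment_dip + rng.normal(0.0, spec.noise_sd, size=n)
    d2 = -(w[0] * d0 + w[1] * d1) / w[2]
    pert = np.stack([d0, d1, d2], axis=1)  # (n, 3)

    # largest lam in [0, 1] with c + lam*pert inside [-1, 1] componentwise
    with np.errstate(divide="ignore", invalid="ignore"):
        room = np.where(pert > 0, (1.0 - c[:, None]) / pert,
                        np.where(pert < 0, (-1.0 - c[:, None]) / pert, np.inf))
    lam = np.clip(room.min(axis=1), 0.0, 1.0)
    utilities = c[:, None] + lam[:, None] * pert
    return np.clip(utilities, -1.0, 1.0), clipped


def generate_cohort(
    spec: SyntheticSpec | None = None, seed: int | None = None
) -> list[PatientRecord]:
    """Generate one patient record per (arm, index) under the spec.

    Deterministic under ``seed``; each arm draws from an independent
    substream keyed by its label, so arm contents are invariant to which
    other arms are present.
    """
    spec = spec or default_spec()
    strata = sorted(spec.strata_weights)
    weights = np.array([spec.strata_weights[s] for s in strata])

    records: list[PatientRecord] = []
    for arm in spec.arms:
        rng = _arm_rng(seed, arm.label)

        if arm.cost_sd == 0:
            costs = np.full(arm.n, arm.cost_mean)
        else:
            k, theta = fit_gamma_moments(arm.cost_mean, arm.cost_sd)
            costs = rng.gamma(shape=k, scale=theta, size=arm.n)

        if arm.qaly_sd == 0:
            targets = np.full(arm.n, arm.qaly_mean)
        else:
            rep = repair_beta(arm.qaly_mean, arm.qaly_sd, shrink=spec.shrink)
            if rep.repaired:
                logger.warning(
                    "arm %r: QALY moments (%.4f, %.4f) Beta-infeasible; "
                    "sampling with repaired SD %.4f — only the mean is "
                    "recoverable", arm.label, arm.qaly_mean, arm.qaly_sd,
                    rep.adjusted_sd,
                )
            targets = rng.beta(rep.alpha, rep.beta, size=arm.n)

        utilities, clipped = _solve_trajectories(targets, spec, rng)
        if clipped:
            logger.warning(
                "arm %r: %d target QALYs outside the attainable band for "
                "horizon %.3f; clipped and recomputed", arm.label, clipped,
                spec.timing.horizon,
            )

        types = rng.choice(strata, size=arm.n, p=weights)
        for i in range(arm.n):
            total = float(costs[i])
            records.append(
                PatientRecord(
                    patient_id=f"{arm.label}-{i + 1:05d}",
                    technique=arm.label,
                    cancer_type=str(types[i]),
                    direct_medical_cost=spec.medical_fraction * total,
                    direct_nonmedical_cost=(1.0 - spec.medical_fraction) * total,
                    utilities=tuple(float(u) for u in utilities[i]),  # type: ignore[arg-type]
                )
            )
    logger.info("generated %d synthetic patients across %d arms",
                len(records), len(spec.arms))
    return records


def generate_comparator(block: ComparatorSpec | None = None) -> ComparatorSpec:
    """The literature-derived no-RT comparator for a synthetic analysis.

    With no argument, returns the packaged default (pooled no-RT cost and
    QALY with the published comparator SDs and a provenance note); a
    user-supplied block is echoed verbatim (its own validation enforces a
    non-empty provenance citation).
    """
    if block is not None:
        return block
    return pooled_comparator()
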