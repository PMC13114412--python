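"""Top-level modelling surface: CostUtilityModel -> CostUtilityResults.

The model binds a patient-level cohort to a comparator specification and
an analysis configuration (QALY timing, willingness-to-pay threshold).
``fit()`` runs the deterministic pipeline — per-patient QALYs, arm
summaries, pooled totals, incremental results with dominance
classification, and Gamma/Beta uncertainty distributions — and returns a
results object from which the probabilistic sensitivity analysis (PSA,
CEAC, CE plane, NMB), the one-way deterministic sensitivity analysis and
report tables hang.

Typical use::

    from rtcea import CostUtilityModel, synthetic

    records = synthetic.generate_cohort(seed=42)
    model = CostUtilityModel(records, comparator=synthetic.generate_comparator(),
                             timing=synthetic.default_spec().timing)
    res = model.fit()
    print(res.summary())
    sample = res.run_psa(n_iterations=10_000, seed=42)
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import psa as psa_mod
from .cohort import (
    ArmSummary,
    ComparatorSpec,
    PatientRecord,
    pool_arms,
    read_cohort,
    summarize_arms,
)
from .incremental import (
    DEFAULT_WTP,
    DSAResult,
    IncrementalResult,
    incremental_icer,
    one_way_dsa,
    subgroup_table,
)
from .qaly import TimingConfig, cohort_qalys
from .uncertainty import DEFAULT_SHRINK, DistributionParams


class CostUtilityModel:
    """Cost-utility analysis of treatment arms against a fixed comparator.

    Parameters
    ----------
    records
        Patient-level cohort (validated :class:`PatientRecord` objects).
    comparator
        The counterfactual arm (e.g. best supportive care), with
        literature provenance.
    subgroup_comparators
        Optional per-cancer-type comparator blocks enabling the subgroup
        incremental table.
    timing
        Measurement calendar and QALY accrual horizon.
    wtp
        Willingness-to-pay threshold (EUR/QALY) for verdicts.
    """

    def __init__(
        self,
        records: Sequence[PatientRecord],
        comparator: ComparatorSpec,
        subgroup_comparators: Mapping[str, ComparatorSpec] | None = None,
        timing: TimingConfig | None = None,
        wtp: float = DEFAULT_WTP,
    ) -> None:
        if not records:
            raise ValueError("model needs a non-empty cohort")
        self.records = list(records)
        self.comparator = comparator
        self.subgroup_comparators = dict(subgroup_comparators or {})
        self.timing = timing or TimingConfig()
        self.wtp = wtp

    @classmethod
    def from_cohort_file(
        cls,
        path: str,
        comparator: ComparatorSpec,
        columns: Mapping[str, str] | None = None,
        delimiter: str = ",",
        **kwargs,
    ) -> "CostUtilityModel":
        """Build the model straight from a delimited cohort file."""
        return cls(read_cohort(path, columns=columns, delimiter=delimiter),
                   comparator, **kwargs)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, comparator: ComparatorSpec, **kwargs
    ) -> "CostUtilityModel":
        """Build the model from a DataFrame with the default column names."""

        def u(v):
            return None if pd.isna(v) else float(v)

        records = [
            PatientRecord(
                patient_id=str(row["patient_id"]),
                technique=str(row["technique"]),
                cancer_type=str(row["cancer_type"]),
                direct_medical_cost=float(row["direct_medical_cost"]),
                direct_nonmedical_cost=float(row["direct_nonmedical_cost"]),
                utilities=(
                    u(row["utility_baseline"]),
                    u(row["utility_end_of_treatment"]),
                    u(row["utility_followup"]),
                ),
            )
            for _, row in frame.iterrows()
        ]
        return cls(records, comparator, **kwargs)

    def fit(
        self,
        shrink: float = DEFAULT_SHRINK,
        beta_overrides: Mapping[str, tuple[float, float]] | None = None,
    ) -> "CostUtilityResults":
        """Run the deterministic pipeline and fit uncertainty distributions.

        ``beta_overrides`` maps strategy labels to explicit Beta (alpha,
        beta) pairs (printed-override mode); all other strategies are
        moment-fitted, with the deterministic SD-shrink repair where the
        observed QALY moments are Beta-infeasible.
        """
        qalys = cohort_qalys(self.records, self.timing)
        arm_summaries = summarize_arms(self.records, qalys, group_by="technique")
        pooled = pool_arms(arm_summaries)
        incremental = [
            incremental_icer(s, self.comparator, self.wtp) for s in arm_summaries
        ]
        incremental.append(incremental_icer(pooled, self.comparator, self.wtp))

        subgroup_results: list[IncrementalResult] | None = None
        if self.subgroup_comparators:
            sub = {
                s.label: s
                for s in summarize_arms(self.records, qalys, group_by="cancer_type")
            }
            subgroup_results = subgroup_table(
                sub, self.subgroup_comparators, self.wtp
            )

        overrides = dict(beta_overrides or {})
        dist_params: dict[str, DistributionParams] = {}
        for s in arm_summaries:
            if s.cost_sd is None or s.qaly_sd is None:
                continue  # size-1 arm: no dispersion information to fit
            dist_params[s.label] = DistributionParams.from_moments(
                s.label, s.cost_mean, s.cost_sd, s.qaly_mean, s.qaly_sd,
                shrink=shrink, beta_override=overrides.get(s.label),
            )
        comp = self.comparator
        if comp.cost_sd is not None and comp.qaly_sd is not None:
            dist_params[comp.label] = DistributionParams.from_moments(
                comp.label, comp.cost_mean, comp.cost_sd,
                comp.qaly_mean, comp.qaly_sd,
                shrink=shrink, beta_override=overrides.get(comp.label),
            )

        return CostUtilityResults(
            model=self,
            qalys=qalys,
            arm_summaries={s.label: s for s in arm_summaries},
            pooled=pooled,
            incremental=incremental,
            subgroup=subgroup_results,
            dist_params=dist_params,
        )


@dataclass
class CostUtilityResults:
    """Fitted estimates and everything derived from them."""

    model: CostUtilityModel
    qalys: Mapping[str, float]
    arm_summaries: Mapping[str, ArmSummary]
    pooled: ArmSummary
    incremental: list[IncrementalResult]
    subgroup: list[IncrementalResult] | None
    dist_params: Mapping[str, DistributionParams]

    # -- reporting ---------------------------------------------------------

    def technique_frame(self) -> pd.DataFrame:
        """Technique-level table: n, cost/QALY means, ICER, classification."""
        rows = []
        for r in self.incremental:
            rows.append(
                {
                    "arm": r.intervention,
                    "n": r.n,
                    "delta_cost": round(r.delta_cost, 2),
                    "delta_qaly": round(r.delta_qaly, 4),
                    "icer": None if r.icer is None else round(r.icer, 2),
                    "classification": r.classification.value,
                    "wtp_verdict": r.wtp_verdict.value,
                }
            )
        return pd.DataFrame(rows)

    def subgroup_frame(self) -> pd.DataFrame:
        if self.subgroup is None:
            raise ValueError("no subgroup comparators were supplied")
        return pd.DataFrame(
            [
                {
                    "cancer_type": r.intervention,
                    "n": r.n,
                    "delta_cost": round(r.delta_cost, 2),
                    "delta_qaly": round(r.delta_qaly, 4),
                    "icer": None if r.icer is None else round(r.icer, 2),
                    "classification": r.classification.value,
                }
                for r in self.subgroup
            ]
        )

    def params_frame(self) -> pd.DataFrame:
        """Distribution-parameter table (means, SDs, Gamma k/theta, Beta a/b)."""
        rows = []
        for label, p in self.dist_params.items():
            rows.append(
                {
                    "strategy": label,
                    "cost_mean": round(p.cost_mean, 2),
                    "cost_sd": round(p.cost_sd, 2),
                    "qaly_mean": round(p.qaly_mean, 4),
                    "qaly_sd": round(p.qaly_sd, 4),
                    "gamma_k": round(p.gamma_k, 4),
                    "gamma_theta": round(p.gamma_theta, 4),
                    "beta_alpha": round(p.beta_alpha, 4),
                    "beta_beta": round(p.beta_beta, 4),
                    "repaired": p.repaired,
                    "adjusted_sd": None if p.adjusted_sd is None else round(p.adjusted_sd, 4),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable report of arm summaries and incremental results."""
        lines = [
            "Cost-utility analysis vs comparator "
            f"{self.model.comparator.label!r} (WTP EUR {self.model.wtp:,.0f}/QALY)",
            "=" * 78,
            f"{'arm':<10}{'n':>5}{'cost mean':>12}{'QALY mean':>11}"
            f"{'dCost':>10}{'dQALY':>9}{'ICER':>12}  class",
            "-" * 78,
        ]
        for r in self.incremental:
            s = (
                self.arm_summaries.get(r.intervention)
                if r.intervention in self.arm_summaries
                else self.pooled
            )
            icer = "undef." if r.icer is None else f"{r.icer:,.2f}"
            lines.append(
                f"{r.intervention:<10}{s.n:>5}{s.cost_mean:>12,.2f}"
                f"{s.qaly_mean:>11.4f}{r.delta_cost:>10,.2f}{r.delta_qaly:>9.4f}"
                f"{icer:>12}  {r.classification.value}"
            )
        lines.append("-" * 78)
        n_rep = sum(p.repaired for p in self.dist_params.values())
        if n_rep:
            lines.append(
                f"note: {n_rep} strategy Beta fit(s) required the SD repair rule"
            )
        return "\n".join(lines)

    # -- sensitivity analyses ---------------------------------------------

    def run_psa(
        self, n_iterations: int = 10_000, seed: int | None = None
    ) -> psa_mod.PSASample:
        """Monte Carlo PSA over all strategies with fitted distributions."""
        if not self.dist_params:
            raise ValueError("no strategy has fitted distributions")
        return psa_mod.run_psa(self.dist_params, n_iterations, seed)

    def one_way_dsa(
        self, parameter: str, percent: float = 20.0, arm: str | None = None
    ) -> DSAResult:
        """Vary one comparator parameter by +/-percent; default arm = pooled."""
        summary = self.pooled if arm is None else self.arm_summaries[arm]
        return one_way_dsa(summary, self.model.comparator, parameter, percent)

    def to_dict(self) -> dict:
        """JSON-serialisable summary of every fitted quantity."""
        return {
            "wtp": self.model.wtp,
            "timing": asdict(self.model.timing),
            "comparator": asdict(self.model.comparator),
            "arms": {k: asdict(v) for k, v in self.arm_summaries.items()},
            "pooled": asdict(self.pooled),
            "incremental": [
                {
                    **{
                        k: v
                        for k, v in asdict(r).items()
                        if k not in ("classification", "wtp_verdict")
                    },
                    "classification": r.classification.value,
                    "wtp_verdict": r.wtp_verdict.value,
                }
                for r in self.incremental
            ],
            "distribution_params": {
                k: asdict(p) for k, p in self.dist_params.items()
            },
        }

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
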