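"""Incremental cost-effectiveness analysis against a comparator.

The ICER is the incremental cost per incremental QALY,
``ICER = (C_int - C_comp) / (E_int - E_comp)``, defined whenever the QALY
difference is non-zero.  Point estimates are classified by the quadrant of
the cost-effectiveness plane they fall in:

* south-east (cheaper, more effective): **dominant**;
* north-west (costlier, less effective): **dominated**;
* north-east (costlier, more effective): value-for-money question, judged
  against the willingness-to-pay threshold;
* south-west (cheaper, less effective): **cost-saving but less effective**
  — the ratio is then savings per QALY forgone, not value for money.

Equal effectiveness with savings is reported as ``cost_saving_equal``;
equal effectiveness at higher cost counts as (weakly) dominated.  The
one-way deterministic sensitivity analysis re-computes the ICER with a
single comparator parameter moved to +/-p% of its base value.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .cohort import ArmSummary, ComparatorSpec, pool_arms


class Classification(str, Enum):
    DOMINANT = "dominant"
    DOMINATED = "dominated"
    COST_SAVING_EQUAL = "cost_saving_equal"
    MORE_EFFECTIVE_MORE_COSTLY = "more_effective_more_costly"
    COST_SAVING_LESS_EFFECTIVE = "cost_saving_less_effective"


class WTPVerdict(str, Enum):
    COST_EFFECTIVE = "cost_effective"
    NOT_COST_EFFECTIVE = "not_cost_effective"
    NOT_APPLICABLE = "not_applicable"


#: Default willingness-to-pay threshold, EUR per QALY gained.
DEFAULT_WTP: float = 30_000.0


@dataclass(frozen=True)
class IncrementalResult:
    """Deltas, ICER and dominance classification for one comparison.

    ``icer`` is ``None`` iff ``delta_qaly == 0``; otherwise it equals
    ``delta_cost / delta_qaly`` at full precision (positive in both the
    NE and SW quadrants — the classification disambiguates the reading).
    """

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    classification: Classification
    wtp: float
    wtp_verdict: WTPVerdict
    n: int | None = None


def _classify(delta_cost: float, delta_qaly: float) -> Classification:
    if delta_qaly > 0:
        return (
            Classification.MORE_EFFECTIVE_MORE_COSTLY
            if delta_cost > 0
            else Classification.DOMINANT
        )
    if delta_qaly < 0:
        return (
            Classification.DOMINATED
            if delta_cost > 0
            else Classification.COST_SAVING_LESS_EFFECTIVE
        )
    # equal effectiveness
    return (
        Classification.DOMINATED
        if delta_cost > 0
        else Classification.COST_SAVING_EQUAL
    )


def incremental_icer(
    intervention: ArmSummary,
    comparator: ComparatorSpec | ArmSummary,
    wtp: float = DEFAULT_WTP,
) -> IncrementalResult:
    """ICER, quadrant classification and WTP verdict for one comparison.

    The verdict is ``cost_effective`` iff the intervention is dominant or
    lies in the NE quadrant with ICER <= WTP; ``not_applicable`` in the SW
    quadrant, where the ratio is savings per QALY forgone and a threshold
    comparison is not meaningful.
    """
    delta_cost = intervention.cost_mean - comparator.cost_mean
    delta_qaly = intervention.qaly_mean - comparator.qaly_mean
    icer = None if delta_qaly == 0 else delta_cost / delta_qaly
    classification = _classify(delta_cost, delta_qaly)

    if classification is Classification.DOMINANT:
        verdict = WTPVerdict.COST_EFFECTIVE
    elif classification is Classification.MORE_EFFECTIVE_MORE_COSTLY:
        assert icer is not None
        verdict = (
            WTPVerdict.COST_EFFECTIVE if icer <= wtp else WTPVerdict.NOT_COST_EFFECTIVE
        )
    elif classification is Classification.COST_SAVING_LESS_EFFECTIVE:
        verdict = WTPVerdict.NOT_APPLICABLE
    else:
        verdict = WTPVerdict.NOT_COST_EFFECTIVE

    return IncrementalResult(
        intervention=intervention.label,
        comparator=comparator.label,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        icer=icer,
        classification=classification,
        wtp=wtp,
        wtp_verdict=verdict,
        n=getattr(intervention, "n", None),
    )


def subgroup_table(
    summaries: Mapping[str, ArmSummary],
    comparators: Mapping[str, ComparatorSpec],
    wtp: float = DEFAULT_WTP,
) -> list[IncrementalResult]:
    """Per-stratum incremental results plus an n-weighted pooled Total row.

    Every stratum must have a matching comparator; the pooled row compares
    the n-weighted intervention means against the n-weighted comparator
    means, weighting both sides by the stratum sample sizes.
    """
    missing = sorted(set(summaries) - set(comparators))
    if missing:
        raise KeyError(f"strata without a comparator: {missing}")

    results = [
        incremental_icer(summaries[label], comparators[label], wtp)
        for label in summaries
    ]

    pooled_int = pool_arms(list(summaries.values()), label="Total")
    total_n = sum(s.n for s in summaries.values())
    pooled_comp = ComparatorSpec(
        label="Total comparator",
        cost_mean=sum(s.n * comparators[k].cost_mean for k, s in summaries.items())
        / total_n,
        cost_sd=None,
        qaly_mean=sum(s.n * comparators[k].qaly_mean for k, s in summaries.items())
        / total_n,
        qaly_sd=None,
        provenance="n-weighted pool of stratum comparators",
    )
    results.append(incremental_icer(pooled_int, pooled_comp, wtp))
    return results


@dataclass(frozen=True)
class DSAResult:
    """One-way deterministic sensitivity analysis of a comparator parameter."""

    parameter: str
    base_value: float
    lower_value: float
    upper_value: float
    icer_base: float | None
    icer_lower: float | None
    icer_upper: float | None
    percent: float

    @property
    def icer_undefined_at_bound(self) -> bool:
        """True when a bound drove the QALY difference to zero."""
        return self.icer_lower is None or self.icer_upper is None


def one_way_dsa(
    intervention: ArmSummary,
    comparator: ComparatorSpec,
    parameter: str,
    percent: float = 20.0,
) -> DSAResult:
    """Recompute the ICER with one comparator parameter at +/-percent.

    ``parameter`` is ``'comparator_cost'`` or ``'comparator_qaly'``.  The
    bound values are base*(1 -/+ percent/100); everything else is held
    fixed.  A bound that makes the QALY difference exactly zero yields an
    undefined ICER at that bound, flagged on the result.
    """
    if percent < 0:
        raise ValueError("percent must be >= 0")
    if parameter == "comparator_cost":
        base = comparator.cost_mean
    elif parameter == "comparator_qaly":
        base = comparator.qaly_mean
    else:
        raise ValueError(
            "parameter must be 'comparator_cost' or 'comparator_qaly', "
            f"got {parameter!r}"
        )

    def icer_at(value: float) -> float | None:
        cost = value if parameter == "comparator_cost" else comparator.cost_mean
        qaly = value if parameter == "comparator_qaly" else comparator.qaly_mean
        dq = intervention.qaly_mean - qaly
        if dq == 0:
            return None
        return (intervention.cost_mean - cost) / dq

    lower = base * (1 - percent / 100.0)
    upper = base * (1 + percent / 100.0)
    return DSAResult(
        parameter=parameter,
        base_value=base,
        lower_value=lower,
        upper_value=upper,
        icer_base=icer_at(base),
        icer_lower=icer_at(lower),
        icer_upper=icer_at(upper),
        percent=percent,
    )
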