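"""Probabilistic sensitivity analysis: Monte Carlo propagation and decision output.

Parameter uncertainty in each strategy's mean cost and mean QALY is
propagated by drawing, per Monte Carlo iteration, a (cost, QALY) pair for
every strategy from its fitted Gamma/Beta distributions.  The draws feed

* the **cost-effectiveness acceptability curve** (CEAC): at each
  willingness-to-pay value, the frequency with which each strategy has the
  highest net monetary benefit (argmax mode), or beats the comparator
  (pairwise mode);
* the **cost-effectiveness plane**: quadrant frequencies of the
  incremental (QALY, cost) cloud of each strategy against the comparator;
* **net monetary benefit** summaries, NMB = QALY x WTP - cost.

Each strategy samples from an independent substream derived from the run
seed and the strategy label, so adding a strategy never perturbs the
draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .uncertainty import DistributionParams

QUADRANTS: tuple[str, ...] = ("NE", "NW", "SE", "SW")


def nmb(qaly, cost, wtp):
    """Net monetary benefit: QALY x WTP - cost (EUR); vectorises."""
    return np.asarray(qaly) * wtp - np.asarray(cost)


def default_wtp_grid() -> np.ndarray:
    """EUR 0 to 60,000 per QALY in EUR 1,000 steps."""
    return np.arange(0.0, 60_001.0, 1_000.0)


@dataclass(frozen=True)
class PSASample:
    """Monte Carlo draws: per strategy, R simulated (cost, QALY) pairs."""

    strategies: tuple[str, ...]
    costs: Mapping[str, np.ndarray]
    qalys: Mapping[str, np.ndarray]
    n_iterations: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for label in self.strategies:
            for arrays in (self.costs, self.qalys):
                arr = arrays[label]
                if arr.shape != (self.n_iterations,):
                    raise ValueError(
                        f"{label!r}: array length {arr.shape} != R={self.n_iterations}"
                    )
                if not np.all(np.isfinite(arr)):
                    raise ValueError(f"{label!r}: non-finite draws")


def _substream(seed: int | None, label: str) -> np.random.Generator:
    # stable per-label stream: crc32 keys the label, independent of set order
    key = zlib.crc32(label.encode("utf-8"))
    entropy = [key] if seed is None else [seed, key]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def run_psa(
    params: Mapping[str, DistributionParams] | Sequence[DistributionParams],
    n_iterations: int = 10_000,
    seed: int | None = None,
) -> PSASample:
    """Draw R independent (cost, QALY) pairs per strategy.

    Deterministic under ``seed``; per-strategy substreams are keyed by the
    strategy label so the draw sequence of one strategy is invariant to
    which other strategies are present.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not isinstance(params, Mapping):
        params = {p.label: p for p in params}
    if not params:
        raise ValueError("run_psa needs at least one strategy")

    costs: dict[str, np.ndarray] = {}
    qalys: dict[str, np.ndarray] = {}
    for label, p in params.items():
        rng = _substream(seed, label)
        costs[label], qalys[label] = p.sample(n_iterations, rng)
    return PSASample(
        strategies=tuple(params),
        costs=costs,
        qalys=qalys,
        n_iterations=n_iterations,
        seed=seed,
    )


@dataclass(frozen=True)
class CEACResult:
    """Probability each strategy is cost-effective across a WTP grid."""

    wtp_grid: np.ndarray
    probabilities: Mapping[str, np.ndarray]  # per strategy, len(wtp_grid)
    mode: str  # "argmax" or "pairwise"
    comparator: str | None = None

    def as_matrix(self) -> np.ndarray:
        """(n_wtp, n_strategies) matrix in strategy insertion order."""
        return np.column_stack([self.probabilities[s] for s in self.probabilities])


def ceac(
    sample: PSASample,
    wtp_grid: Sequence[float] | np.ndarray | None = None,
    mode: str = "argmax",
    comparator: str | None = None,
) -> CEACResult:
    """Cost-effectiveness acceptability curves from a PSA sample.

    In ``argmax`` mode the cost-effective strategy of an iteration is the
    NMB argmax over the full strategy set (ties broken by lower cost in
    that iteration, then by strategy order), so probabilities sum to 1 at
    every WTP.  In ``pairwise`` mode each strategy is scored as
    P(NMB_s > NMB_comparator) independently.
    """
    grid = np.asarray(
        default_wtp_grid() if wtp_grid is None else wtp_grid, dtype=float
    )
    if grid.size == 0:
        raise ValueError("WTP grid must be non-empty")
    if np.any(grid < 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("WTP grid must be non-negative and strictly increasing")

    labels = sample.strategies
    cost = np.stack([sample.costs[s] for s in labels])  # (S, R)
    qaly = np.stack([sample.qalys[s] for s in labels])  # (S, R)
    R = sample.n_iterations

    probs: dict[str, np.ndarray]
    if mode == "argmax":
        probs = {s: np.empty(grid.size) for s in labels}
        for j, wtp in enumerate(grid):
            benefit = qaly * wtp - cost  # (S, R)
            best = benefit.max(axis=0)
            # ties: lowest cost that iteration, then first label in order
            masked_cost = np.where(benefit == best, cost, np.inf)
            winner = masked_cost.argmin(axis=0)
            counts = np.bincount(winner, minlength=len(labels))
            for i, s in enumerate(labels):
                probs[s][j] = counts[i] / R
    elif mode == "pairwise":
        if comparator is None or comparator not in labels:
            raise ValueError("pairwise mode needs a comparator present in the sample")
        ci = labels.index(comparator)
        probs = {}
        for i, s in enumerate(labels):
            if s == comparator:
                continue
            p = np.empty(grid.size)
            for j, wtp in enumerate(grid):
                p[j] = np.mean(
                    qaly[i] * wtp - cost[i] > qaly[ci] * wtp - cost[ci]
                )
            probs[s] = p
    else:
        raise ValueError(f"mode must be 'argmax' or 'pairwise', got {mode!r}")

    return CEACResult(wtp_grid=grid, probabilities=probs, mode=mode, comparator=comparator)


@dataclass(frozen=True)
class CEPlaneSummary:
    """Per-strategy quadrant frequencies of incremental draws vs the comparator.

    Quadrants follow the (delta QALY, delta cost) convention: NE more
    costly & more effective, NW more costly & less effective, SE cheaper &
    more effective (dominant), SW cheaper & less effective.  Boundary draws
    (a delta exactly zero) count toward the positive side.
    """

    comparator: str
    fractions: Mapping[str, Mapping[str, float]]  # strategy -> quadrant -> fraction


def ce_plane_quadrants(
    sample: PSASample,
    comparator: str,
    fixed_comparator: tuple[float, float] | None = None,
) -> CEPlaneSummary:
    """Tally CE-plane quadrant frequencies of every strategy vs the comparator.

    By default the comparator's uncertainty is sampled too: deltas are
    taken against the comparator draw of the same iteration.  Passing
    ``fixed_comparator=(cost, qaly)`` instead takes deltas against a fixed
    point (the comparator's expected values), the convention of analyses
    that leave the counterfactual arm unsampled; the two conventions give
    different quadrant spreads and the choice should be reported.
    """
    if fixed_comparator is not None:
        c_cost, c_qaly = fixed_comparator
    elif comparator in sample.strategies:
        c_cost = sample.costs[comparator]
        c_qaly = sample.qalys[comparator]
    else:
        raise ValueError(f"comparator {comparator!r} not in sample")
    fractions: dict[str, dict[str, float]] = {}
    for s in sample.strategies:
        if s == comparator:
            continue
        dc = sample.costs[s] - c_cost
        de = sample.qalys[s] - c_qaly
        more_costly = dc >= 0  # boundary to the positive side
        more_effective = de >= 0
        R = sample.n_iterations
        fractions[s] = {
            "NE": float(np.mean(more_costly & more_effective)),
            "NW": float(np.mean(more_costly & ~more_effective)),
            "SE": float(np.mean(~more_costly & more_effective)),
            "SW": float(np.mean(~more_costly & ~more_effective)),
        }
    return CEPlaneSummary(comparator=comparator, fractions=fractions)


def mean_nmb(sample: PSASample, wtp: float) -> dict[str, float]:
    """Expected net monetary benefit per strategy at one WTP threshold."""
    return {
        s: float(np.mean(nmb(sample.qalys[s], sample.costs[s], wtp)))
        for s in sample.strategies
    }


# ---------------------------------------------------------------------------
# Plotting (thin matplotlib wrappers)


def plot_ceac(result: CEACResult, ax=None):
    """Line plot of acceptability curves over the WTP grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for s, p in result.probabilities.items():
        ax.plot(result.wtp_grid, p, label=s)
    ax.set_xlabel("Willingness to pay (EUR/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax


def plot_ce_plane(sample: PSASample, comparator: str, ax=None, max_points: int = 2000):
    """Scatter of incremental (delta QALY, delta cost) draws vs the comparator."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    step = max(1, sample.n_iterations // max_points)
    for s in sample.strategies:
        if s == comparator:
            continue
        dc = (sample.costs[s] - sample.costs[comparator])[::step]
        de = (sample.qalys[s] - sample.qalys[comparator])[::step]
        ax.scatter(de, dc, s=4, alpha=0.4, label=s)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (EUR)")
    ax.legend()
    return ax
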