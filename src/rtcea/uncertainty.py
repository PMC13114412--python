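"""Parameter uncertainty: method-of-moments Gamma and Beta distributions.

Costs are continuous, non-negative and right-skewed, so each strategy's
cost is modelled as Gamma(k, theta) with

    k = (mean / SD)^2        theta = SD^2 / mean.

QALYs (utility-weighted time on a [0, 1] scale) are modelled as
Beta(alpha, beta) fitted by

    nu    = mean (1 - mean) / SD^2  -  1
    alpha = mean * nu                beta = (1 - mean) * nu,

which is feasible only when SD^2 < mean (1 - mean).  Observed arm-level
QALY moments can violate that bound (and means can fall outside (0, 1)
when worse-than-death utilities drag an arm negative); such inputs are
*repaired*: the mean is clamped into [eps, 1 - eps] if needed and the SD
is shrunk to a fixed fraction of the feasibility bound
sqrt(mean (1 - mean)), then the moment fit is recomputed.  The repair is
deterministic and fully recorded on the resulting parameter set.

A printed-override mode accepts explicit (alpha, beta), so a probabilistic
analysis can be run from an externally published parameter table whose own
adjustment rule is unknown.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

logger = logging.getLogger(__name__)

#: Clamp width for QALY means outside the open unit interval.
MEAN_EPS: float = 1e-3
#: Default SD shrink fraction of the Beta feasibility bound.
DEFAULT_SHRINK: float = 0.9


def fit_gamma_moments(mean: float, sd: float) -> tuple[float, float]:
    """Gamma shape k and scale theta matching the given mean and SD.

    Both inputs must be strictly positive; the fit is exact:
    k*theta = mean and k*theta^2 = sd^2.
    """
    if not (mean > 0 and sd > 0):
        raise ValueError(f"gamma moments need mean > 0 and sd > 0, got {mean}, {sd}")
    k = (mean / sd) ** 2
    theta = sd * sd / mean
    return k, theta


def fit_beta_moments(mean: float, sd: float) -> tuple[float, float] | None:
    """Beta shapes (alpha, beta) matching mean and SD, or None if infeasible.

    Infeasible when the mean lies outside (0, 1) or the variance reaches
    the Bernoulli bound mean*(1 - mean); the caller can then engage
    :func:`repair_beta`.
    """
    if sd <= 0:
        raise ValueError(f"beta moments need sd > 0, got {sd}")
    if not (0.0 < mean < 1.0):
        return None
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    if nu <= 0:
        return None
    return mean * nu, (1.0 - mean) * nu


class RepairedBeta(NamedTuple):
    alpha: float
    beta: float
    adjusted_sd: float
    adjusted_mean: float
    repaired: bool


def repair_beta(
    mean: float, sd: float, shrink: float = DEFAULT_SHRINK
) -> RepairedBeta:
    """Fit a Beta by moments, adjusting infeasible inputs deterministically.

    Feasible inputs pass through unchanged (``repaired=False``).  Otherwise
    the mean is clamped into [eps, 1-eps] if outside (0, 1), the SD is
    replaced by ``shrink * sqrt(mean*(1-mean))`` (a valid SD strictly inside
    the feasibility bound), and the moment fit is recomputed.  The adjusted
    moments are recorded so the intervention is auditable.
    """
    if not (0.0 < shrink < 1.0):
        raise ValueError(f"shrink must be in (0, 1), got {shrink}")
    fitted = fit_beta_moments(mean, sd) if sd > 0 else None
    if fitted is not None:
        return RepairedBeta(*fitted, adjusted_sd=sd, adjusted_mean=mean, repaired=False)

    adj_mean = min(max(mean, MEAN_EPS), 1.0 - MEAN_EPS)
    if adj_mean != mean:
        logger.warning(
            "beta repair: QALY mean %.4f outside (0, 1); clamped to %.4f "
            "before fitting", mean, adj_mean,
        )
    adj_sd = shrink * math.sqrt(adj_mean * (1.0 - adj_mean))
    fitted = fit_beta_moments(adj_mean, adj_sd)
    assert fitted is not None  # shrink < 1 guarantees feasibility
    logger.warning(
        "beta repair: (mean=%.4f, sd=%.4f) infeasible; refit with "
        "(mean=%.4f, sd=%.4f)", mean, sd, adj_mean, adj_sd,
    )
    return RepairedBeta(*fitted, adjusted_sd=adj_sd, adjusted_mean=adj_mean, repaired=True)


@dataclass(frozen=True)
class DistributionParams:
    """Fitted sampling distributions for one strategy's cost and QALY.

    Cost ~ Gamma(``gamma_k``, scale ``gamma_theta``); QALY ~
    Beta(``beta_alpha``, ``beta_beta``).  When the Beta fit needed repair,
    ``repaired`` is set and ``adjusted_sd``/``adjusted_mean`` record the
    moments actually fitted; when explicit shapes were supplied
    (``beta_overridden``), no moment relation to ``qaly_mean`` is implied.
    """

    label: str
    cost_mean: float
    cost_sd: float
    qaly_mean: float
    qaly_sd: float
    gamma_k: float
    gamma_theta: float
    beta_alpha: float
    beta_beta: float
    repaired: bool = False
    adjusted_sd: float | None = None
    adjusted_mean: float | None = None
    beta_overridden: bool = False

    def __post_init__(self) -> None:
        if self.gamma_k <= 0 or self.gamma_theta <= 0:
            raise ValueError(f"{self.label!r}: gamma parameters must be positive")
        if self.beta_alpha <= 0 or self.beta_beta <= 0:
            raise ValueError(f"{self.label!r}: beta parameters must be positive")

    @classmethod
    def from_moments(
        cls,
        label: str,
        cost_mean: float,
        cost_sd: float,
        qaly_mean: float,
        qaly_sd: float,
        shrink: float = DEFAULT_SHRINK,
        beta_override: tuple[float, float] | None = None,
    ) -> "DistributionParams":
        """Fit both distributions from arm-level moments.

        ``beta_override`` supplies explicit (alpha, beta) verbatim —
        printed-override mode for externally published parameter tables.
        """
        k, theta = fit_gamma_moments(cost_mean, cost_sd)
        if beta_override is not None:
            alpha, beta = beta_override
            return cls(
                label=label, cost_mean=cost_mean, cost_sd=cost_sd,
                qaly_mean=qaly_mean, qaly_sd=qaly_sd,
                gamma_k=k, gamma_theta=theta,
                beta_alpha=alpha, beta_beta=beta, beta_overridden=True,
            )
        rep = repair_beta(qaly_mean, qaly_sd, shrink=shrink)
        return cls(
            label=label, cost_mean=cost_mean, cost_sd=cost_sd,
            qaly_mean=qaly_mean, qaly_sd=qaly_sd,
            gamma_k=k, gamma_theta=theta,
            beta_alpha=rep.alpha, beta_beta=rep.beta,
            repaired=rep.repaired,
            adjusted_sd=rep.adjusted_sd if rep.repaired else None,
            adjusted_mean=rep.adjusted_mean if rep.repaired else None,
        )

    def sample(
        self, n: int, rng: np.random.Generator | int | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Draw n independent (cost, qaly) pairs; reproducible under a seed."""
        if n < 0:
            raise ValueError("n must be >= 0")
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        costs = rng.gamma(shape=self.gamma_k, scale=self.gamma_theta, size=n)
        qalys = rng.beta(self.beta_alpha, self.beta_beta, size=n)
        return costs, qalys

    @property
    def beta_mean(self) -> float:
        return self.beta_alpha / (self.beta_alpha + self.beta_beta)

    @property
    def beta_sd(self) -> float:
        a, b = self.beta_alpha, self.beta_beta
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
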