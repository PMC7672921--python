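"""Power / precision conversions for the treatment effect.

Normal-approximation power for a two-sided level-``alpha`` Wald test of the
treatment effect, with the minor tail ignored:

    power = Phi(|delta| * sqrt(precision) - z_{1 - alpha/2}),

where ``delta`` is the standardized effect size (in units of the residual SD)
and ``precision`` is the inverse treatment-effect variance on the sigma2 = 1
scale.  Inverting at a target power gives the precision a design must reach:

    precision >= ((z_{1 - alpha/2} + z_{power}) / delta) ** 2.

Variance components are treated as known (the GLS design framework), so no
small-sample degrees-of-freedom correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import InvalidDesignError
from .model import Design, Scenario, treatment_precision

__all__ = ["PowerSpec", "required_precision", "power_at_precision", "design_power"]


@dataclass(frozen=True)
class PowerSpec:
    """Standardized effect size, two-sided significance level and target power."""

    delta: float
    alpha: float = 0.05
    power: float = 0.90

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise InvalidDesignError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.power < 1.0:
            raise InvalidDesignError(f"power must lie in (0, 1), got {self.power}")


def required_precision(spec: PowerSpec) -> float:
    """Precision needed to detect ``delta`` with the requested power.

    Monotone decreasing in ``delta`` (quartering when ``delta`` doubles) and
    increasing in power.
    """
    if spec.delta <= 0:
        raise InvalidDesignError("delta must be positive for a target-precision conversion")
    z_alpha = norm.ppf(1.0 - spec.alpha / 2.0)
    z_power = norm.ppf(spec.power)
    return float(((z_alpha + z_power) / spec.delta) ** 2)


def power_at_precision(precision: float, delta: float, alpha: float = 0.05) -> float:
    """Power of a two-sided level-``alpha`` test given the design's precision.

    ``delta = 0`` returns ``alpha/2`` (the one-tail approximation used
    throughout: the contribution of the far tail is ignored).
    """
    if precision <= 0:
        raise InvalidDesignError(f"precision must be positive, got {precision}")
    z_alpha = norm.ppf(1.0 - alpha / 2.0)
    return float(norm.cdf(abs(delta) * np.sqrt(precision) - z_alpha))


def design_power(
    scenario: Scenario,
    design: Design,
    delta: float,
    alpha: float = 0.05,
    analysis_degree: int | None = None,
) -> float:
    """Power of a fixed design, optionally under a different analysis polynomial.

    ``analysis_degree`` overrides the scenario's time-effect degree, which is
    how the robustness of a design to misjudging the smoothness of the time
    effect is probed: the same schedule is evaluated under nested polynomial
    models (precision can only fall as the degree grows).
    """
    sc = scenario if analysis_degree is None else scenario.with_degree(analysis_degree)
    prec = treatment_precision(sc, design)
    return power_at_precision(prec, delta, alpha)
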