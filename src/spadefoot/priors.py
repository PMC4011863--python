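"""Node-age calibration priors and their quantile intervals.

Two prior families used to calibrate divergence times against the fossil
record:

* **offset lognormal** — a lognormal density shifted right by the minimum
  age of the oldest assignable fossil.  Parameterized BEAST-style with the
  *real-space* mean of the unshifted lognormal and the *log-space* standard
  deviation, so ``mu_log = ln(mean_real) - sdlog^2 / 2``.
* **normal** — a secondary calibration summarizing previous age estimates.

``prior_interval`` defaults to the 5th-95th percentile span, the span such
calibration setups conventionally print.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CalibrationPrior", "prior_quantile", "prior_cdf", "prior_interval", "quantile_table"]


@dataclass(frozen=True)
class CalibrationPrior:
    """A node-age prior in Myr.

    Use the :meth:`offset_lognormal` / :meth:`normal` constructors.
    """

    kind: str
    offset: float = 0.0
    mean_real: float | None = None
    sdlog: float | None = None
    mean: float | None = None
    sd: float | None = None

    @classmethod
    def offset_lognormal(
        cls, offset: float, mean_real: float, sdlog: float
    ) -> "CalibrationPrior":
        if offset < 0:
            raise ValueError("offset must be >= 0")
        if mean_real <= 0 or sdlog <= 0:
            raise ValueError("mean_real and sdlog must be > 0")
        return cls("offset_lognormal", offset=offset, mean_real=mean_real, sdlog=sdlog)

    @classmethod
    def normal(cls, mean: float, sd: float) -> "CalibrationPrior":
        if sd <= 0:
            raise ValueError("sd must be > 0")
        return cls("normal", mean=mean, sd=sd)

    @property
    def mu_log(self) -> float:
        """Log-space mean implied by the real-space mean of the unshifted part."""
        return math.log(self.mean_real) - self.sdlog**2 / 2.0

    def _frozen(self):
        if self.kind == "offset_lognormal":
            return stats.lognorm(s=self.sdlog, loc=self.offset, scale=math.exp(self.mu_log))
        return stats.norm(loc=self.mean, scale=self.sd)


def prior_quantile(prior: CalibrationPrior, q: float) -> float:
    """Age (Myr) at cumulative probability ``q`` in (0, 1)."""
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must be in (0, 1), got {q}")
    return float(prior._frozen().ppf(q))


def prior_cdf(prior: CalibrationPrior, age: float) -> float:
    """Cumulative probability at ``age`` (Myr)."""
    return float(prior._frozen().cdf(age))


def prior_interval(
    prior: CalibrationPrior, lower_q: float = 0.05, upper_q: float = 0.95
) -> tuple[float, float]:
    """Quantile interval ``(age at lower_q, age at upper_q)``, unrounded.

    Rounding (0.1 Myr) belongs at the presentation layer.
    """
    if not (0.0 < lower_q < upper_q < 1.0):
        raise ValueError("need 0 < lower_q < upper_q < 1")
    return prior_quantile(prior, lower_q), prior_quantile(prior, upper_q)


def quantile_table(prior: CalibrationPrior, qs=None) -> "list[tuple[float, float]]":
    """(q, age) pairs for a default or supplied grid of quantiles."""
    if qs is None:
        qs = [0.025, 0.05, 0.25, 0.5, 0.75, 0.95, 0.975]
    return [(float(q), prior_quantile(prior, q)) for q in np.asarray(qs, dtype=float)]
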