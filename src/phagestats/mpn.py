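"""Single-dilution most-probable-number estimation.

For a series of ``n`` vessels at one inoculation volume with ``x`` positives,
the maximum-likelihood Poisson rate per vessel is

    lam_hat = -ln((n - x) / n),

the MPN. Confidence intervals follow the Jarvis approach: a delta-method
interval on the log scale,

    SE(ln lam_hat) = sqrt((x / (n - x)) / n) / lam_hat,
    CI = lam_hat * exp(-+ z * SE),

with ``z`` the standard-normal quantile at ``(1 + conf) / 2``. Two edge
cases get special handling: zero positives report a point of 0 with a
one-sided upper bound ``-ln(1 - conf) / n`` (the rule-of-three-type bound),
and all-positive series are flagged non-computable rather than infinite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .poisson import AliquotSeries

__all__ = ["MPNEstimate", "mpn_point", "mpn_interval", "mpn_zero_upper"]


@dataclass(frozen=True)
class MPNEstimate:
    """MPN point estimate with optional confidence interval.

    ``point``/``ci_low``/``ci_high`` are per vessel at the series' stated
    volume. When ``computable`` is False (all vessels positive) the numeric
    fields are ``None``.
    """

    point: float | None
    ci_low: float | None
    ci_high: float | None
    conf_level: float = 0.95
    computable: bool = True

    def __post_init__(self) -> None:
        if self.computable and self.point is not None and self.ci_low is not None:
            if not (0 <= self.ci_low <= self.point <= self.ci_high):
                raise ValueError(
                    f"interval must satisfy 0 <= lo <= point <= hi, got "
                    f"({self.ci_low}, {self.point}, {self.ci_high})"
                )


def mpn_point(series: AliquotSeries) -> MPNEstimate:
    """MPN point estimate ``-ln((n - x) / n)``, without an interval.

    All-positive series return ``computable=False``.
    """
    if series.all_positive:
        return MPNEstimate(point=None, ci_low=None, ci_high=None, computable=False)
    point = -math.log((series.n_vessels - series.n_positive) / series.n_vessels)
    return MPNEstimate(point=point, ci_low=None, ci_high=None)


def mpn_zero_upper(n: int, conf_level: float = 0.95) -> float:
    """One-sided upper confidence bound on the rate when 0 of ``n`` are positive.

    If the true per-vessel rate were ``lam``, all ``n`` vessels stay negative
    with probability ``e^(-n lam)``; setting this to ``1 - conf`` gives
    ``lam_up = -ln(1 - conf) / n``, decreasing in ``n``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= conf_level < 1:
        raise ValueError(f"conf_level must lie in [0, 1), got {conf_level}")
    return -math.log1p(-conf_level) / n


def mpn_interval(series: AliquotSeries, conf_level: float = 0.95) -> MPNEstimate:
    """MPN with a Jarvis-approach confidence interval.

    Interior series (0 < x < n) get the log-scale delta-method interval.
    Zero-positive series report point 0 with interval (0, upper bound from
    :func:`mpn_zero_upper`). All-positive series are non-computable.
    """
    n, x = series.n_vessels, series.n_positive
    if series.all_positive:
        return MPNEstimate(
            point=None, ci_low=None, ci_high=None,
            conf_level=conf_level, computable=False,
        )
    if x == 0:
        return MPNEstimate(
            point=0.0, ci_low=0.0, ci_high=mpn_zero_upper(n, conf_level),
            conf_level=conf_level,
        )
    lam = -math.log((n - x) / n)
    se_log = math.sqrt((x / (n - x)) / n) / lam
    z = norm.ppf(0.5 + conf_level / 2)
    return MPNEstimate(
        point=lam,
        ci_low=lam * math.exp(-z * se_log),
        ci_high=lam * math.exp(z * se_log),
        conf_level=conf_level,
    )
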