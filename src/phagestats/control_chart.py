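"""Shewhart control charts for reference phage suspensions.

A baseline of repeated titrations of the same reference batch (nominally 20
vials counted on different days) fixes a center line at the baseline mean
and limits at +-2s (warning) and +-3s (control), with s the sample standard
deviation. Monitoring points are then checked against two out-of-control
rules:

* R1 — a single point beyond a control limit (+-3s);
* R2 — two out of any three consecutive points beyond the same warning
  limit (+-2s, same side).

Chart parameters scale linearly with the inoculated volume, so one
baseline serves every aliquot size via :func:`scale_chart`. Limits are
stored explicitly: charts built from a baseline carry exact symmetric
+-2s/+-3s limits, while :meth:`ControlChart.from_limits` admits published
charts whose rounded limits are slightly asymmetric about the center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .distfit import CountSample

__all__ = ["ControlChart", "Violation", "build_chart", "scale_chart", "check_rules"]


@dataclass(frozen=True)
class ControlChart:
    """Center line, sigma, and warning/control limits of a reference chart.

    ``lcl`` may be negative for low-count baselines; it is kept unclipped
    here, and any flooring at zero is a display decision.
    """

    center: float
    sigma: float
    lwl: float
    uwl: float
    lcl: float
    ucl: float
    baseline_n: int
    volume: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if not self.volume > 0:
            raise ValueError(f"volume must be positive, got {self.volume}")
        if not self.lcl <= self.lwl <= self.center <= self.uwl <= self.ucl:
            raise ValueError("limits must satisfy lcl <= lwl <= center <= uwl <= ucl")

    @classmethod
    def from_sigma(
        cls, center: float, sigma: float, baseline_n: int = 0, volume: float = 100.0
    ) -> "ControlChart":
        """Symmetric chart with limits at exactly center +- 2s and +- 3s."""
        return cls(
            center=center, sigma=sigma,
            lwl=center - 2 * sigma, uwl=center + 2 * sigma,
            lcl=center - 3 * sigma, ucl=center + 3 * sigma,
            baseline_n=baseline_n, volume=volume,
        )

    @classmethod
    def from_limits(
        cls,
        center: float,
        lcl: float,
        ucl: float,
        baseline_n: int = 0,
        volume: float = 100.0,
    ) -> "ControlChart":
        """Chart reconstructed from a published center and control limits.

        Rounded published limits may sit asymmetrically about the center;
        they are kept verbatim, sigma is set to their span over 6, and the
        warning limits are placed two-thirds of the way to each control
        limit (where +-2s sits relative to +-3s).
        """
        return cls(
            center=center, sigma=(ucl - lcl) / 6,
            lwl=center - 2 * (center - lcl) / 3,
            uwl=center + 2 * (ucl - center) / 3,
            lcl=lcl, ucl=ucl,
            baseline_n=baseline_n, volume=volume,
        )


@dataclass(frozen=True)
class Violation:
    """One out-of-control signal: rule id, 0-based point index, and side."""

    rule: str  # "R1" or "R2"
    index: int
    side: str  # "upper" or "lower"


def build_chart(baseline: CountSample) -> ControlChart:
    """Estimate chart parameters from a baseline of repeated counts.

    The center is the baseline mean and sigma the sample standard deviation
    (divisor n-1); limits are exactly center +- 2s and +- 3s. Baselines
    shorter than 20 points are accepted with a warning: the limits are then
    poorly estimated.
    """
    x = baseline.as_array()
    if x.size < 2:
        raise ValueError(f"baseline needs at least 2 counts, got {x.size}")
    if x.size < 20:
        warnings.warn(
            f"baseline has only {x.size} points (< 20); control limits will "
            "be imprecise",
            stacklevel=2,
        )
    return ControlChart.from_sigma(
        center=float(x.mean()),
        sigma=float(x.std(ddof=1)),
        baseline_n=x.size,
        volume=baseline.volume,
    )


def scale_chart(chart: ControlChart, factor: float) -> ControlChart:
    """Rescale a chart to a different inoculation volume.

    Center, sigma and all four limits are multiplied by ``factor`` (the
    ratio of the new volume to the chart's volume), so published asymmetric
    limits stay exactly proportional.
    """
    if not factor > 0:
        raise ValueError(f"factor must be positive, got {factor}")
    return ControlChart(
        center=chart.center * factor,
        sigma=chart.sigma * factor,
        lwl=chart.lwl * factor,
        uwl=chart.uwl * factor,
        lcl=chart.lcl * factor,
        ucl=chart.ucl * factor,
        baseline_n=chart.baseline_n,
        volume=chart.volume * factor,
    )


def check_rules(chart: ControlChart, series: Sequence[float]) -> list[Violation]:
    """Scan a monitoring series for out-of-control signals.

    R1 fires per point strictly beyond a control limit. R2 fires per window
    of three consecutive points in which at least two lie strictly beyond
    the same warning limit on the same side; the violation is indexed at
    the window's last point (for series shorter than three, the single
    short window is still checked). An empty result means in control.
    """
    if len(series) == 0:
        raise ValueError("monitoring series must be non-empty")
    violations: list[Violation] = []
    vals = [float(v) for v in series]
    for i, v in enumerate(vals):
        if v > chart.ucl:
            violations.append(Violation("R1", i, "upper"))
        elif v < chart.lcl:
            violations.append(Violation("R1", i, "lower"))
    windows = (
        [(len(vals) - 1, vals)]
        if len(vals) < 3
        else [(end, vals[end - 2 : end + 1]) for end in range(2, len(vals))]
    )
    for end, window in windows:
        if sum(v > chart.uwl for v in window) >= 2:
            violations.append(Violation("R2", end, "upper"))
        if sum(v < chart.lwl for v in window) >= 2:
            violations.append(Violation("R2", end, "lower"))
    return sorted(violations, key=lambda v: (v.index, v.rule, v.side))
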