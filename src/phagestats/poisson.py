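"""Poisson model linking phage concentration to presence/absence outcomes.

A vessel inoculated with a mean of ``lam`` plaque-forming units turns
positive exactly when it receives at least one phage, so under Poisson
sampling

    P(positive) = 1 - exp(-lam),      P(negative) = exp(-lam).

Rates are always stored together with the inoculation volume at which they
are expressed; converting between volumes goes through :func:`scale_rate`
so that per-aliquot and per-sample readings are never mixed silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "NonComputableError",
    "AliquotSeries",
    "PoissonRate",
    "prob_positive",
    "lambda_from_positive_fraction",
    "expected_positive_count",
    "scale_rate",
]


class NonComputableError(ValueError):
    """An estimate is undefined for the observed data.

    Raised when every vessel in a series is positive: the maximum-likelihood
    rate is unbounded and the estimate is reported as non-computable rather
    than infinite.
    """


@dataclass(frozen=True)
class AliquotSeries:
    """One presence/absence experiment at a single inoculation volume.

    Parameters
    ----------
    label : str
        Method name, e.g. ``"ISO-DAL"`` or ``"Bluephage"``.
    volume : float
        Volume of reference suspension inoculated per vessel, in µL.
        A volume of 0 marks a blank negative-control arm.
    n_vessels : int
        Number of vessels tested.
    n_positive : int
        Number of vessels scoring positive (at least one phage).
    """

    label: str
    volume: float
    n_vessels: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError(f"volume must be non-negative, got {self.volume}")
        if self.n_vessels < 1:
            raise ValueError(f"n_vessels must be >= 1, got {self.n_vessels}")
        if not 0 <= self.n_positive <= self.n_vessels:
            raise ValueError(
                f"n_positive must lie in [0, n_vessels], got "
                f"{self.n_positive}/{self.n_vessels}"
            )

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_vessels

    @property
    def all_positive(self) -> bool:
        return self.n_positive == self.n_vessels


@dataclass(frozen=True)
class PoissonRate:
    """Expected phage count per vessel, tied to an inoculation volume (µL)."""

    lam: float
    volume: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be non-negative, got {self.lam}")
        if not self.volume > 0:
            raise ValueError(f"volume must be positive, got {self.volume}")


def prob_positive(rate: PoissonRate) -> float:
    """Probability that a vessel at this rate turns positive, ``1 - e^-lam``.

    Strictly increasing in ``lam``; 0 at ``lam = 0`` and approaching (but
    never reaching) 1 as ``lam`` grows.
    """
    # -expm1(-x) = 1 - e^-x without cancellation at small lam
    return -math.expm1(-rate.lam)


def lambda_from_positive_fraction(p: float, volume: float = 1.0) -> PoissonRate:
    """Invert the zero-count relation: ``lam = -ln(1 - p)``.

    The fraction of negative vessels estimates ``P(count = 0) = e^-lam``,
    so the positive fraction ``p`` maps back to the Poisson rate.

    Raises
    ------
    NonComputableError
        If ``p >= 1`` (every vessel positive: the rate is unbounded).
    ValueError
        If ``p < 0``.
    """
    if p < 0:
        raise ValueError(f"positive fraction must be >= 0, got {p}")
    if p >= 1:
        raise NonComputableError(
            "all vessels positive: the Poisson rate is not computable"
        )
    return PoissonRate(lam=-math.log1p(-p), volume=volume)


def expected_positive_count(rate: PoissonRate, n: int) -> float:
    """Expected number of positive vessels among ``n``, ``n * (1 - e^-lam)``."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    return n * prob_positive(rate)


def scale_rate(rate: PoissonRate, to_volume: float) -> PoissonRate:
    """Re-express a rate at a different inoculation volume.

    Phage counts are proportional to the volume drawn from a well-mixed
    suspension, so the rate scales linearly: ``lam' = lam * to_volume / volume``.
    """
    if not to_volume > 0:
        raise ValueError(f"to_volume must be positive, got {to_volume}")
    return PoissonRate(lam=rate.lam * to_volume / rate.volume, volume=to_volume)
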