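"""Synthetic experiment generators with the structure the analysis assumes.

The generators emulate the validation study's design: a reference phage
suspension at 50-100 PFU/mL (default 70, putting the per-vessel mean at 7
for a 100 µL aliquot), aliquot volumes of 0/10/25/75/100 µL inoculated into
100 mL vessels, Poisson-distributed per-vessel counts with rate
``concentration * volume_ul / 1000``, presence/absence read-outs defined
exactly as count >= 1, and 20-vial control-chart baselines. Everything is
bit-reproducible under a fixed seed, with one spawned RNG stream per
volume so generation order across volumes does not matter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distfit import CountSample
from .fixture import ReferenceStudy, reference_study
from .poisson import AliquotSeries

__all__ = [
    "ExperimentDesign",
    "generate_detection_experiment",
    "generate_counts",
    "generate_baseline",
    "reference_study",
    "ReferenceStudy",
]

#: study conditions: suspension concentration (PFU/mL), aliquot volumes (µL)
#: and vessels per volume as in the original comparison
DEFAULT_CONCENTRATION = 70.0
DEFAULT_VOLUMES = (0.0, 10.0, 25.0, 75.0, 100.0)
DEFAULT_N_PER_VOLUME = (80, 42, 18, 10, 10)


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of a synthetic spiking experiment.

    ``concentration`` is the true titer of the reference suspension in
    PFU per mL; per vessel the expected count at volume ``v`` µL is
    ``concentration * v / 1000``.
    """

    concentration: float = DEFAULT_CONCENTRATION
    volumes: tuple[float, ...] = DEFAULT_VOLUMES
    n_per_volume: tuple[int, ...] = DEFAULT_N_PER_VOLUME
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.concentration > 0:
            raise ValueError(
                f"concentration must be positive, got {self.concentration}"
            )
        if len(self.volumes) != len(self.n_per_volume):
            raise ValueError("volumes and n_per_volume must align")
        if any(v < 0 for v in self.volumes):
            raise ValueError("volumes must be non-negative")
        if any(n < 1 for n in self.n_per_volume):
            raise ValueError("n_per_volume entries must be >= 1")

    def lam_at(self, volume_ul: float) -> float:
        return self.concentration * volume_ul / 1000.0


def generate_detection_experiment(
    design: ExperimentDesign,
    label: str = "synthetic",
) -> tuple[list[AliquotSeries], list[np.ndarray]]:
    """Simulate one spiking experiment: per-vessel counts and series.

    Per vessel the true count is Poisson(concentration * volume / 1000);
    a vessel is positive exactly when its count is >= 1. Returns the
    presence/absence series per volume together with the underlying true
    counts (one array per volume), so the classification can be
    cross-checked vessel by vessel.

    A volume of 0 µL is the negative-control arm: all counts are zero.
    """
    children = np.random.SeedSequence(design.seed).spawn(len(design.volumes))
    series: list[AliquotSeries] = []
    all_counts: list[np.ndarray] = []
    for child, vol, n in zip(children, design.volumes, design.n_per_volume):
        rng = np.random.default_rng(child)
        counts = rng.poisson(design.lam_at(vol), size=n)
        series.append(
            AliquotSeries(
                label=label,
                volume=vol,
                n_vessels=n,
                n_positive=int((counts >= 1).sum()),
            )
        )
        all_counts.append(counts)
    return series, all_counts


def generate_counts(
    lam: float,
    n: int,
    family: str = "poisson",
    dispersion: float | None = None,
    seed: int | None = None,
    volume: float = 10.0,
    label: str = "synthetic",
) -> CountSample:
    """Draw i.i.d. per-vessel counts from a Poisson or negative binomial.

    The negative binomial uses the (mean ``lam``, dispersion ``k``)
    parameterization with variance ``lam + lam^2 / k``; it supplies the
    overdispersed misspecification inputs for the distribution-fitting
    tests.
    """
    if lam < 0:
        raise ValueError(f"lam must be non-negative, got {lam}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    if family == "poisson":
        draws = rng.poisson(lam, size=n)
    elif family == "negative_binomial":
        if dispersion is None or dispersion <= 0:
            raise ValueError(
                f"negative binomial needs dispersion > 0, got {dispersion}"
            )
        if lam == 0:
            draws = np.zeros(n, dtype=np.int64)
        else:
            k = dispersion
            draws = rng.negative_binomial(k, k / (k + lam), size=n)
    else:
        raise ValueError(f"unknown family {family!r}")
    return CountSample(counts=tuple(int(c) for c in draws), volume=volume, label=label)


def generate_baseline(
    lam: float,
    n_vials: int = 20,
    seed: int | None = None,
    volume: float = 100.0,
    label: str = "reference-baseline",
) -> CountSample:
    """Poisson baseline counts for control-chart construction.

    Emulates enumerating ``n_vials`` vials of one reference batch on
    different days (the study's quality-control scheme uses 20).
    """
    if lam < 0:
        raise ValueError(f"lam must be non-negative, got {lam}")
    if n_vials < 2:
        raise ValueError(f"n_vials must be >= 2, got {n_vials}")
    rng = np.random.default_rng(seed)
    draws = rng.poisson(lam, size=n_vials)
    return CountSample(counts=tuple(int(c) for c in draws), volume=volume, label=label)
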