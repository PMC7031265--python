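"""Method-validation procedures for presence/absence phage detection.

Three analyses compare a qualitative (presence/absence) detection method
against a reference plaque titration carried out on the same series of
spiked vessels:

* a parametric bootstrap of **accuracy and specificity** — per-volume
  Poisson rates are estimated from the candidate method's own positive
  fractions via the zero-count relation, simulated runs of positive counts
  are drawn as Binomial(n, 1 - e^-lam), and each run is scored against the
  reference method's observed positives;
* a **lambda-equivalence interval** for the detection limit — the range of
  candidate Poisson rates whose simulated count samples a two-sample
  Kolmogorov-Smirnov test cannot distinguish from samples at the reference
  rate;
* a **two-proportion chi-squared test** (optionally Yates-corrected) for
  directly comparing positive fractions between methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2, ks_2samp

from .poisson import AliquotSeries, PoissonRate, lambda_from_positive_fraction

__all__ = [
    "ValidationResult",
    "EquivalenceInterval",
    "estimate_method_lambda",
    "simulate_run",
    "bootstrap_accuracy_specificity",
    "ks_rejection_fraction",
    "equivalence_interval",
    "two_proportion_test",
]


@dataclass(frozen=True)
class ValidationResult:
    """Accuracy/specificity point estimates with bootstrap percentile CIs.

    All values are percentages in [0, 100]. ``specificity_point`` and its
    CI are ``None`` when the reference observed no negative vessels.
    """

    accuracy_point: float
    accuracy_ci: tuple[float, float]
    specificity_point: float | None
    specificity_ci: tuple[float, float] | None
    runs: int
    seed: int | None


@dataclass(frozen=True)
class EquivalenceInterval:
    """Maximal contiguous range of Poisson rates indistinguishable from a
    reference rate under the two-sample KS criterion."""

    lam_low: float
    lam_high: float
    lam_reference: float
    alpha: float
    runs: int
    grid_step: float
    n: int
    seed: int | None

    def __post_init__(self) -> None:
        if not self.lam_low <= self.lam_reference <= self.lam_high:
            raise ValueError("interval must contain the reference rate")

    @property
    def width(self) -> float:
        return self.lam_high - self.lam_low


def estimate_method_lambda(series: AliquotSeries) -> PoissonRate:
    """Per-vessel Poisson rate from a series' positive fraction.

    Treats the negative fraction as the estimated probability of a zero
    count, so ``lam = -ln(1 - x/n)``. Raises :class:`NonComputableError`
    when every vessel is positive.
    """
    return lambda_from_positive_fraction(
        series.positive_fraction, volume=series.volume
    )


def simulate_run(
    rates: Sequence[PoissonRate],
    ns: Sequence[int],
    rng: np.random.Generator,
) -> list[int]:
    """Simulate one run of positive counts across volumes.

    A vessel at rate ``lam`` is positive with probability ``1 - e^-lam``
    (a Poisson count thresholded at >= 1), so the number of positives per
    volume is Binomial(n, 1 - e^-lam).
    """
    if len(rates) != len(ns):
        raise ValueError(
            f"rates and ns must align, got {len(rates)} vs {len(ns)}"
        )
    return [
        int(rng.binomial(n, -math.expm1(-r.lam))) for r, n in zip(rates, ns)
    ]


def bootstrap_accuracy_specificity(
    sim_series: Sequence[AliquotSeries],
    ref_positives: Sequence[int],
    runs: int = 10_000,
    seed: int | None = None,
    conf: float = 0.95,
) -> ValidationResult:
    """Parametric-bootstrap accuracy and specificity against a reference.

    Per volume ``v`` with ``n_v`` vessels, the candidate method's rate
    ``lam_v`` is estimated from its own positive fraction and the expected
    positives are ``E_v = n_v (1 - e^-lam_v)``; ``ref_v`` are the positives
    the reference method observed on the same vessels. With ``N = sum n_v``:

    * point accuracy  = 100 (N - sum_v |E_v - ref_v|) / N
    * point specificity = 100 sum_v min(n_v - E_v, n_v - ref_v)
      / sum_v (n_v - ref_v)

    Each bootstrap run redraws positives ``k_v ~ Binomial(n_v, 1-e^-lam_v)``
    and scores the same formulas with ``k_v`` in place of ``E_v``; the CIs
    are percentile intervals over the runs. Reruns at the same seed are
    identical, and each volume draws from its own spawned RNG stream so
    changing ``runs`` never reorders earlier draws.
    """
    if len(sim_series) != len(ref_positives):
        raise ValueError("sim_series and ref_positives must align")
    if runs < 1:
        raise ValueError(f"runs must be >= 1, got {runs}")
    ns = np.array([s.n_vessels for s in sim_series], dtype=float)
    refs = np.array(ref_positives, dtype=float)
    if np.any(refs < 0) or np.any(refs > ns):
        raise ValueError("reference positives must lie in [0, n_vessels]")
    lams = [estimate_method_lambda(s).lam for s in sim_series]
    probs = np.array([-math.expm1(-lam) for lam in lams])
    expected = ns * probs
    n_total = ns.sum()

    point_acc = 100.0 * (n_total - np.abs(expected - refs).sum()) / n_total

    # one spawned stream per volume
    children = np.random.SeedSequence(seed).spawn(len(sim_series))
    k = np.stack(
        [
            np.random.default_rng(child).binomial(int(n), p, size=runs)
            for child, n, p in zip(children, ns, probs)
        ],
        axis=1,
    ).astype(float)  # shape (runs, n_volumes)

    acc_runs = 100.0 * (n_total - np.abs(k - refs).sum(axis=1)) / n_total
    alpha = 1 - conf
    acc_ci = tuple(
        float(q) for q in np.percentile(acc_runs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    )

    neg_ref = (ns - refs).sum()
    if neg_ref == 0:
        spec_point, spec_ci = None, None
    else:
        spec_point = 100.0 * np.minimum(ns - expected, ns - refs).sum() / neg_ref
        spec_runs = 100.0 * np.minimum(ns - k, ns - refs).sum(axis=1) / neg_ref
        spec_ci = tuple(
            float(q)
            for q in np.percentile(spec_runs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        )
        spec_point = float(spec_point)

    return ValidationResult(
        accuracy_point=float(point_acc),
        accuracy_ci=acc_ci,
        specificity_point=spec_point,
        specificity_ci=spec_ci,
        runs=runs,
        seed=seed,
    )


def _candidate_seed(seed: int | None, grid_index: int) -> np.random.SeedSequence:
    # deterministic per-candidate stream, independent of scan order
    return np.random.SeedSequence([0 if seed is None else int(seed), grid_index])


def ks_rejection_fraction(
    lam_candidate: float,
    lam_reference: float,
    n: int,
    runs: int,
    alpha: float,
    seed_seq: np.random.SeedSequence | int | None = None,
) -> float:
    """Fraction of simulated sample pairs the two-sample KS test rejects.

    Draws ``runs`` pairs of size-``n`` Poisson samples at the candidate and
    reference rates and applies the two-sample KS test at level ``alpha``.
    Under the null (equal rates) the fraction is at most ``alpha`` up to
    Monte-Carlo noise (below it, in fact: KS is conservative on ties).
    """
    if not isinstance(seed_seq, np.random.SeedSequence):
        seed_seq = np.random.SeedSequence(seed_seq)
    rng = np.random.default_rng(seed_seq)
    a = rng.poisson(lam_candidate, size=(runs, n))
    b = rng.poisson(lam_reference, size=(runs, n))
    # asymptotic p-values throughout: counts are heavily tied, so the exact
    # two-sample method fails over to asymp anyway (with a warning)
    rejected = sum(
        ks_2samp(a[i], b[i], method="asymp").pvalue < alpha for i in range(runs)
    )
    return rejected / runs


def equivalence_interval(
    lam_reference: PoissonRate | float,
    n: int,
    runs: int = 300,
    grid_step: float = 0.02,
    alpha: float = 0.05,
    seed: int | None = None,
) -> EquivalenceInterval:
    """Detection-limit equivalence interval around a reference Poisson rate.

    Candidate rates on the grid ``[max(0, lam_ref - 1), lam_ref + 1]``
    (step ``grid_step``, anchored at ``lam_ref``) are accepted when their
    KS rejection fraction against the reference does not exceed
    ``alpha + 2 sqrt(alpha (1 - alpha) / runs)`` — the test's nominal level
    plus two Monte-Carlo standard errors. The interval is the maximal
    contiguous accepted region containing the reference rate, so the scan
    walks outward from the reference and stops at the first rejection on
    each side.
    """
    lam_ref = lam_reference.lam if isinstance(lam_reference, PoissonRate) else float(lam_reference)
    if not lam_ref > 0:
        raise ValueError(f"lam_reference must be positive, got {lam_ref}")
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    if not grid_step > 0:
        raise ValueError(f"grid_step must be positive, got {grid_step}")

    half = int(round(1.0 / grid_step))
    tol = alpha + 2 * math.sqrt(alpha * (1 - alpha) / runs)

    def accepted(offset: int) -> bool:
        lam_c = lam_ref + offset * grid_step
        if lam_c < 0:
            return False
        frac = ks_rejection_fraction(
            lam_c, lam_ref, n, runs, alpha,
            _candidate_seed(seed, offset + half),
        )
        return frac <= tol

    if not accepted(0):  # cannot occur beyond extreme Monte-Carlo noise
        raise RuntimeError(
            "reference rate rejected against itself; increase runs"
        )
    lo_off = 0
    while lo_off > -half and accepted(lo_off - 1):
        lo_off -= 1
    hi_off = 0
    while hi_off < half and accepted(hi_off + 1):
        hi_off += 1

    return EquivalenceInterval(
        lam_low=max(0.0, lam_ref + lo_off * grid_step),
        lam_high=lam_ref + hi_off * grid_step,
        lam_reference=lam_ref,
        alpha=alpha,
        runs=runs,
        grid_step=grid_step,
        n=n,
        seed=seed,
    )


def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int, continuity: bool = True
) -> tuple[float, float]:
    """Chi-squared test of equal proportions on the pooled 2x2 table.

    With ``continuity=True`` the Yates correction is applied (matching the
    default of the classical equal-proportions test). Without it the
    statistic is algebraically the square of the pooled two-sample z
    statistic. Returns ``(stat, p)``.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError(f"sample sizes must be positive, got {n}")
        if not 0 <= x <= n:
            raise ValueError(f"successes must lie in [0, n], got {x}/{n}")
    a, b = x1, n1 - x1
    c, d = x2, n2 - x2
    n_tot = n1 + n2
    pooled = (x1 + x2) / n_tot
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(0.0, diff - n_tot / 2)
    stat = n_tot * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(stat), float(chi2.sf(stat, 1))
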