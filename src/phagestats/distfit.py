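"""Count-distribution fitting, AIC selection and goodness of fit.

Plate-count titrations yield one PFU count per vessel. Three candidate
families are fitted by maximum likelihood — Poisson (rate ``lam``),
negative binomial (mean ``mu``, dispersion ``k``, variance
``mu + mu^2 / k``) and normal (``mu``, ``sigma``) — and compared by
AIC = 2 * n_params - 2 * loglik. Goodness of fit is assessed both by a
Pearson chi-squared test on pooled integer bins and by a Kolmogorov-Smirnov
statistic (conservative for the discrete families).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import kolmogorov
from scipy.stats import chi2, nbinom, norm, poisson

__all__ = [
    "CountSample",
    "FitResult",
    "fit_poisson",
    "fit_negative_binomial",
    "fit_normal",
    "select_by_aic",
    "chisq_gof",
    "ks_gof",
    "bootstrap_mean_ci",
]

# number of free parameters and tie-break order per family
_FAMILY_NPARAMS = {"poisson": 1, "negative_binomial": 2, "normal": 2}
_FAMILY_ORDER = {"poisson": 0, "negative_binomial": 1, "normal": 2}

# dispersion cap: at k = 1e6 the negative binomial is Poisson to ~1e-6 in
# log-likelihood for the rates seen here
_DISPERSION_CAP = 1e6


@dataclass(frozen=True)
class CountSample:
    """Per-vessel PFU counts from a plate-count titration."""

    counts: tuple[int, ...]
    volume: float
    label: str = ""

    def __post_init__(self) -> None:
        counts = tuple(self.counts)
        for c in counts:
            if c != int(c) or c < 0:
                raise ValueError(f"counts must be non-negative integers, got {c}")
        object.__setattr__(self, "counts", tuple(int(c) for c in counts))
        if not self.volume > 0:
            raise ValueError(f"volume must be positive, got {self.volume}")

    @property
    def n(self) -> int:
        return len(self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


@dataclass(frozen=True)
class FitResult:
    """A fitted family with its parameters, log-likelihood and AIC.

    ``gof_stat``/``gof_df``/``gof_p`` are filled in by :func:`chisq_gof`
    (via :meth:`with_gof`); ``boundary`` marks a negative-binomial fit that
    collapsed to the Poisson boundary (sample variance <= mean).
    """

    family: str
    params: dict[str, float]
    loglik: float
    aic: float
    boundary: bool = False
    gof_stat: float | None = None
    gof_df: int | None = None
    gof_p: float | None = None

    @property
    def n_params(self) -> int:
        return _FAMILY_NPARAMS[self.family]

    def with_gof(self, stat: float, df: int, p: float) -> "FitResult":
        return replace(self, gof_stat=stat, gof_df=df, gof_p=p)


def _require_fit_sample(sample: CountSample, min_n: int = 2) -> np.ndarray:
    x = sample.as_array()
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} counts, got {x.size}")
    return x


def fit_poisson(sample: CountSample) -> FitResult:
    """Poisson maximum-likelihood fit; the MLE rate is the sample mean."""
    x = _require_fit_sample(sample)
    lam = float(x.mean())
    loglik = float(poisson.logpmf(x, lam).sum()) if lam > 0 else 0.0
    return FitResult("poisson", {"lam": lam}, loglik, 2.0 - 2.0 * loglik)


def _nb_loglik(x: np.ndarray, mu: float, k: float) -> float:
    # scipy parameterization: n = k, p = k / (k + mu)
    return float(nbinom.logpmf(x, k, k / (k + mu)).sum())


def fit_negative_binomial(sample: CountSample) -> FitResult:
    """Negative-binomial MLE with the mean profiled at the sample mean.

    The dispersion ``k`` is found by a coarse search on a log grid followed
    by bounded local refinement. When the sample variance does not exceed
    the mean there is no interior optimum: the fit is returned at the
    dispersion cap (Poisson boundary) with ``boundary=True``.
    """
    x = _require_fit_sample(sample)
    mu = float(x.mean())
    var = float(x.var(ddof=0))
    params_at = lambda k: {"mu": mu, "k": k}

    if mu == 0:
        return FitResult(
            "negative_binomial", params_at(_DISPERSION_CAP), 0.0, 4.0, boundary=True
        )
    if var <= mu:
        # no interior optimum: the supremum is the k -> inf (Poisson) limit
        ll = float(poisson.logpmf(x, mu).sum())
        return FitResult(
            "negative_binomial", params_at(_DISPERSION_CAP), ll, 4.0 - 2.0 * ll,
            boundary=True,
        )

    # method-of-moments start: var = mu + mu^2/k
    k_mom = mu**2 / (var - mu)
    grid = np.exp(np.linspace(math.log(k_mom) - 3, math.log(k_mom) + 3, 25))
    lls = [_nb_loglik(x, mu, k) for k in grid]
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda logk: -_nb_loglik(x, mu, math.exp(logk)),
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    k_hat = min(math.exp(res.x), _DISPERSION_CAP)
    at_cap = k_hat >= _DISPERSION_CAP
    ll = float(poisson.logpmf(x, mu).sum()) if at_cap else _nb_loglik(x, mu, k_hat)
    return FitResult(
        "negative_binomial", params_at(k_hat), ll, 4.0 - 2.0 * ll, boundary=at_cap
    )


def fit_normal(sample: CountSample) -> FitResult:
    """Normal MLE: mean and the divisor-n standard deviation."""
    x = _require_fit_sample(sample)
    mu = float(x.mean())
    sigma = float(x.std(ddof=0))
    if sigma == 0:
        raise ValueError("normal fit requires non-zero spread")
    loglik = float(norm.logpdf(x, mu, sigma).sum())
    return FitResult("normal", {"mu": mu, "sigma": sigma}, loglik, 4.0 - 2.0 * loglik)


def select_by_aic(fits: list[FitResult]) -> FitResult:
    """Minimum-AIC fit; ties go to fewer parameters, then fixed family order."""
    if not fits:
        raise ValueError("need at least one fit to select from")
    return min(fits, key=lambda f: (f.aic, f.n_params, _FAMILY_ORDER[f.family]))


def _bin_probabilities(fit: FitResult, kmax: int) -> np.ndarray:
    """Probability of each integer bin 0..kmax-1 plus an open tail [kmax, inf)."""
    ks = np.arange(kmax)
    if fit.family == "poisson":
        probs = poisson.pmf(ks, fit.params["lam"])
        tail = poisson.sf(kmax - 1, fit.params["lam"])
    elif fit.family == "negative_binomial":
        mu, k = fit.params["mu"], fit.params["k"]
        p = k / (k + mu)
        probs = nbinom.pmf(ks, k, p)
        tail = nbinom.sf(kmax - 1, k, p)
    elif fit.family == "normal":
        mu, sigma = fit.params["mu"], fit.params["sigma"]
        edges = norm.cdf(ks + 0.5, mu, sigma)
        probs = np.diff(edges, prepend=0.0)  # bin 0 absorbs the lower tail
        tail = norm.sf(kmax - 0.5, mu, sigma)
    else:  # pragma: no cover
        raise ValueError(f"unknown family {fit.family!r}")
    return np.append(probs, tail)


def chisq_gof(sample: CountSample, fit: FitResult) -> tuple[float, int, float]:
    """Pearson chi-squared goodness of fit on pooled integer bins.

    Counts are binned at the integers with an open upper tail; bins are
    pooled from the top until every expected count is >= 1 and at most 20%
    of bins have expected counts below 5. Degrees of freedom are
    ``bins - 1 - n_params``; when df <= 0 (or fewer than 2 bins survive)
    the p-value is reported as NaN.
    """
    x = _require_fit_sample(sample)
    n = x.size
    kmax = int(x.max()) + 1
    probs = _bin_probabilities(fit, kmax)
    observed = np.bincount(x, minlength=kmax + 1).astype(float)

    expected = n * probs
    obs = observed.copy()
    # pool from the upper tail until the expected-count rules hold
    while len(expected) > 2 and (
        expected.min() < 1.0 or np.mean(expected < 5.0) > 0.2
    ):
        expected[-2] += expected[-1]
        obs[-2] += obs[-1]
        expected = expected[:-1]
        obs = obs[:-1]
    if len(expected) < 2 or expected.min() <= 0:
        return math.nan, 0, math.nan

    stat = float(((obs - expected) ** 2 / expected).sum())
    df = len(expected) - 1 - fit.n_params
    p = float(chi2.sf(stat, df)) if df > 0 else math.nan
    return stat, df, p


def ks_gof(sample: CountSample, fit: FitResult) -> tuple[float, float]:
    """Kolmogorov-Smirnov distance between the empirical and fitted CDFs.

    For the discrete families the supremum is taken over the integer
    support; the asymptotic Kolmogorov p-value is then conservative (the
    true null distribution of the statistic is stochastically smaller).
    For the normal fit the usual two-sided continuous statistic is used.
    """
    x = _require_fit_sample(sample)
    n = x.size

    if fit.family == "normal":
        mu, sigma = fit.params["mu"], fit.params["sigma"]
        xs = np.sort(x)
        cdf = norm.cdf(xs, mu, sigma)
        ecdf_hi = np.arange(1, n + 1) / n
        ecdf_lo = np.arange(0, n) / n
        stat = float(np.max(np.maximum(ecdf_hi - cdf, cdf - ecdf_lo)))
    else:
        if fit.family == "poisson":
            cdf_at = lambda ks: poisson.cdf(ks, fit.params["lam"])
            ppf_hi = poisson.ppf(1 - 1e-12, fit.params["lam"])
        else:
            mu, k = fit.params["mu"], fit.params["k"]
            cdf_at = lambda ks: nbinom.cdf(ks, k, k / (k + mu))
            ppf_hi = nbinom.ppf(1 - 1e-12, k, k / (k + mu))
        kmax = int(max(x.max(), ppf_hi)) + 1
        ks = np.arange(kmax + 1)
        ecdf = np.searchsorted(np.sort(x), ks, side="right") / n
        stat = float(np.max(np.abs(ecdf - cdf_at(ks))))

    p = float(kolmogorov(math.sqrt(n) * stat))
    return stat, p


def bootstrap_mean_ci(
    sample: CountSample,
    n_boot: int = 10_000,
    conf: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Nonparametric bootstrap percentile interval for the sample mean.

    Resamples the counts with replacement ``n_boot`` times and takes the
    ``(1 - conf) / 2`` and ``(1 + conf) / 2`` percentiles of the resampled
    means. Bit-reproducible for a fixed seed.
    """
    x = _require_fit_sample(sample)
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    rng = np.random.default_rng(seed)
    means = rng.choice(x, size=(n_boot, x.size), replace=True).mean(axis=1)
    alpha = 1 - conf
    lo, hi = np.percentile(means, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(x.mean()), float(lo), float(hi)
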