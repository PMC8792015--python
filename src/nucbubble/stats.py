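"""Per-condition nucleosome-count statistics.

Count histograms, Poisson maximum-likelihood fits, nonparametric
bootstrap confidence intervals for the mean, and an exact-Poisson
two-sample rate comparison (conditional binomial test).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "CountDistribution",
    "PoissonSummary",
    "histogram",
    "poisson_mle",
    "bootstrap_ci",
    "exact_poisson_test",
    "summarize",
]


@dataclass(frozen=True)
class CountDistribution:
    """Per-molecule nucleosome counts for one experimental condition."""

    condition_label: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("counts must be a nonempty 1D sequence")
        if not np.issubdtype(c.dtype, np.integer):
            if np.any(c != np.floor(c)):
                raise ValueError("counts must be integers")
            c = c.astype(np.int64)
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def n_molecules(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class PoissonSummary:
    """Poisson fit (lambda = mean bubbles per molecule) with bootstrap CI."""

    condition_label: str
    lambda_hat: float
    ci_low: float
    ci_high: float
    fitted_pmf: dict[int, float]
    n_molecules: int
    n_boot: int
    level: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.lambda_hat <= self.ci_high):
            raise ValueError("CI must bracket lambda_hat")


def histogram(d: CountDistribution) -> dict[int, float]:
    """Fraction of molecules per count value over support 0..max(count)."""
    support = int(d.counts.max())
    tally = np.bincount(d.counts, minlength=support + 1)
    frac = tally / d.n_molecules
    return {k: float(frac[k]) for k in range(support + 1)}


def poisson_mle(d: CountDistribution) -> float:
    """Poisson MLE of the rate: the sample mean."""
    return float(d.counts.mean())


def fitted_pmf(lambda_hat: float, support_max: int) -> dict[int, float]:
    """Poisson(lambda_hat) pmf over 0..support_max."""
    ks = np.arange(support_max + 1)
    if lambda_hat == 0.0:
        p = (ks == 0).astype(float)
    else:
        p = sps.poisson.pmf(ks, lambda_hat)
    return {int(k): float(v) for k, v in zip(ks, p)}


def bootstrap_ci(
    d: CountDistribution,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
    method: str = "percentile",
) -> tuple[float, float]:
    """Nonparametric bootstrap CI of the mean count.

    Percentile interval by default (BCa via method="bca").  Seeded and
    reproducible; n=1 gives the degenerate interval [mean, mean].
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    counts = d.counts.astype(float)
    n = counts.size
    if n == 1:
        warnings.warn("single observation: degenerate bootstrap interval")
        m = float(counts[0])
        return (m, m)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot_means = counts[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    if method == "percentile":
        lo, hi = np.quantile(boot_means, [alpha, 1.0 - alpha])
    elif method == "bca":
        theta = counts.mean()
        z0 = sps.norm.ppf(
            np.clip((boot_means < theta).mean() + 0.5 * (boot_means == theta).mean(),
                    1e-9, 1 - 1e-9)
        )
        jack = (counts.sum() - counts) / (n - 1)
        dj = jack.mean() - jack
        denom = 6.0 * (dj**2).sum() ** 1.5
        a = (dj**3).sum() / denom if denom > 0 else 0.0
        za, zb = sps.norm.ppf([alpha, 1.0 - alpha])
        qa = sps.norm.cdf(z0 + (z0 + za) / (1 - a * (z0 + za)))
        qb = sps.norm.cdf(z0 + (z0 + zb) / (1 - a * (z0 + zb)))
        lo, hi = np.quantile(boot_means, [qa, qb])
    else:
        raise ValueError(f"unknown method {method!r}")
    return (float(lo), float(hi))


def exact_poisson_test(
    a: CountDistribution,
    b: CountDistribution,
    alternative: str = "two-sided",
    two_sided: str = "doubling",
) -> float:
    """Exact comparison of two Poisson rates by conditioning on the total.

    Under H0 of equal rates, Ka | (Ka + Kb) ~ Binomial(Ka + Kb,
    na / (na + nb)).  Two-sided p by tail doubling (capped at 1) by
    default; two_sided="minlike" sums all outcomes no more likely than
    the observed one.
    """
    ka, kb = int(a.counts.sum()), int(b.counts.sum())
    na, nb = a.n_molecules, b.n_molecules
    total = ka + kb
    if total == 0:
        warnings.warn("no events in either condition; p = 1")
        return 1.0
    prop = na / (na + nb)
    if alternative == "less":
        return float(min(1.0, sps.binom.cdf(ka, total, prop)))
    if alternative == "greater":
        return float(min(1.0, sps.binom.sf(ka - 1, total, prop)))
    if alternative != "two-sided":
        raise ValueError(f"unknown alternative {alternative!r}")
    if two_sided == "doubling":
        lower = sps.binom.cdf(ka, total, prop)
        upper = sps.binom.sf(ka - 1, total, prop)
        return float(min(1.0, 2.0 * min(lower, upper)))
    if two_sided == "minlike":
        return float(sps.binomtest(ka, total, prop, alternative="two-sided").pvalue)
    raise ValueError(f"unknown two_sided convention {two_sided!r}")


def summarize(
    d: CountDistribution,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> PoissonSummary:
    """Poisson fit plus bootstrap CI in one record."""
    lam = poisson_mle(d)
    lo, hi = bootstrap_ci(d, n_boot=n_boot, level=level, seed=seed)
    return PoissonSummary(
        condition_label=d.condition_label,
        lambda_hat=lam,
        ci_low=lo,
        ci_high=hi,
        fitted_pmf=fitted_pmf(lam, int(d.counts.max())),
        n_molecules=d.n_molecules,
        n_boot=n_boot,
        level=level,
    )
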