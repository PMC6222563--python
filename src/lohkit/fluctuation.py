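"""Luria-Delbruck fluctuation analysis by the Lea-Coulson method of the median.

Parallel cultures grown from small inocula accumulate mutants (here, cells
that lost a counter-selectable cassette through loss of heterozygosity) in
a jackpot-prone distribution: an event early in the growth of a culture
founds a large resistant clone. The median mutant count r~ across cultures
is a robust summary; the Lea-Coulson estimator inverts the approximate
median relation

    r~/m - ln m = 1.24

to recover m, the expected number of mutational events per culture, and the
rate per cell division is mu = m / N, with N the number of cells per
culture at plating. Confidence intervals follow the FALCOR-style dispersion
of ln m, sigma = 1.225 * m**-0.315 / sqrt(C), for C parallel cultures.

The simulator implements the deterministic-growth ("quick") Luria-Delbruck
model: events per culture ~ Poisson(m), and each event founds a clone of
size floor(1/u), u ~ Uniform(0,1], capped at N. A stochastic clone-growth
variant (exponentially distributed clone-size multiplier) is available
behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import mannwhitneyu

__all__ = [
    "FluctuationExperiment",
    "RateEstimate",
    "IntervalRate",
    "counts_from_plating",
    "lc_median_m",
    "ci95_lnm",
    "loh_rate",
    "median_frequency",
    "estimate_rate",
    "compare_experiments",
    "normalized_rate_per_kb",
    "coincident_rate",
    "simulate_cultures",
]

LC_MEDIAN_CONSTANT = 1.24  # r~/m - ln m at the Luria-Delbruck median


@dataclass
class FluctuationExperiment:
    """Per-culture mutant counts and viable population sizes."""

    r: list[float]  # whole-culture selective (mutant) counts
    N: list[float]  # whole-culture viable cells (permissive plating)
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.r) != len(self.N) or not self.r:
            raise ValueError("r and N must be equal-length, non-empty")
        if any(ri < 0 for ri in self.r):
            raise ValueError("mutant counts must be >= 0")
        if any(ni <= 0 for ni in self.N):
            raise ValueError("population sizes must be > 0")

    @property
    def C(self) -> int:
        return len(self.r)

    def N_mean(self, use_median: bool = False) -> float:
        return float(np.median(self.N) if use_median else np.mean(self.N))

    def frequencies(self) -> np.ndarray:
        return np.asarray(self.r, dtype=float) / np.asarray(self.N, dtype=float)


@dataclass
class RateEstimate:
    r_median: float
    m: float
    N_mean: float
    mu: float
    ci_low: float | None
    ci_high: float | None
    sigma_lnm: float | None
    C: int

    def __post_init__(self) -> None:
        if self.ci_low is not None and not (self.ci_low <= self.mu <= self.ci_high):
            raise ValueError("CI does not bracket the point estimate")


@dataclass
class IntervalRate:
    mu: float
    cen_to_marker_kb: float
    mu_per_kb: float


def counts_from_plating(
    selective_count: int,
    selective_dilution: float,
    selective_plated_fraction: float,
    permissive_count: int,
    permissive_dilution: float,
    permissive_plated_fraction: float,
) -> tuple[int, float]:
    """Scale plate colony counts to whole-culture values (r_i, N_i).

    Each plate receives ``plated_fraction`` of the culture after a
    ``dilution``-fold dilution, so the whole-culture count is
    ``colonies * dilution / plated_fraction``. The mutant count r_i is
    rounded half-up to an integer; N_i is left fractional.
    """
    if selective_dilution < 1 or permissive_dilution < 1:
        raise ValueError("dilution factors must be >= 1")
    if not (0 < selective_plated_fraction <= 1 and 0 < permissive_plated_fraction <= 1):
        raise ValueError("plated fractions must be in (0, 1]")
    if selective_count < 0 or permissive_count < 0:
        raise ValueError("counts must be >= 0")
    if permissive_count == 0:
        raise ValueError("cannot estimate N: zero permissive count")
    r = selective_count * selective_dilution / selective_plated_fraction
    n = permissive_count * permissive_dilution / permissive_plated_fraction
    return int(math.floor(r + 0.5)), float(n)


def lc_median_m(r: list[float] | np.ndarray) -> float:
    """Solve r~/m - ln m = 1.24 for m from the median mutant count.

    The left side is strictly decreasing in m, so the root is unique; it is
    bracketed and found with Brent's method to 1e-9 relative tolerance.
    """
    r_med = float(np.median(r))
    if r_med <= 0:
        raise ValueError("median zero: method of the median undefined (consider the p0 method)")

    def f(m: float) -> float:
        return r_med / m - math.log(m) - LC_MEDIAN_CONSTANT

    lo = 1e-12
    hi = max(r_med, 2.0)
    while f(hi) > 0:
        hi *= 2.0
    return float(brentq(f, lo, hi, xtol=1e-15, rtol=1e-12))


def ci95_lnm(m: float, C: int) -> float:
    """FALCOR-style dispersion of ln m across C parallel cultures."""
    if C < 2:
        raise ValueError("need >= 2 cultures for a dispersion estimate")
    return 1.225 * m ** (-0.315) / math.sqrt(C)


def loh_rate(m: float, N_mean: float, C: int = 1, r_median: float | None = None) -> RateEstimate:
    """Convert expected events per culture into a per-division rate with CI.

    mu = m / N_mean; the 95% CI exponentiates ln m +/- 1.96 sigma and
    divides by N_mean. With fewer than two cultures the CI is undefined and
    only the point estimate is returned.
    """
    if N_mean <= 0:
        raise ValueError("N_mean must be > 0")
    mu = m / N_mean
    if C >= 2:
        sigma = ci95_lnm(m, C)
        ci_low = math.exp(math.log(m) - 1.96 * sigma) / N_mean
        ci_high = math.exp(math.log(m) + 1.96 * sigma) / N_mean
    else:
        sigma = ci_low = ci_high = None
    return RateEstimate(
        r_median=float(r_median) if r_median is not None else float("nan"),
        m=m,
        N_mean=N_mean,
        mu=mu,
        ci_low=ci_low,
        ci_high=ci_high,
        sigma_lnm=sigma,
        C=C,
    )


def median_frequency(r: list[float] | np.ndarray, N_mean: float) -> float:
    """Median mutant frequency f~ = median(r) / N_mean."""
    if N_mean <= 0:
        raise ValueError("N_mean must be > 0")
    return float(np.median(r)) / N_mean


def estimate_rate(exp: FluctuationExperiment, use_median_N: bool = False) -> RateEstimate:
    """Full Lea-Coulson chain for one experiment: r -> m -> mu with CI."""
    r_med = float(np.median(exp.r))
    m = lc_median_m(exp.r)
    return loh_rate(m, exp.N_mean(use_median=use_median_N), C=exp.C, r_median=r_med)


def compare_experiments(
    exp_a: FluctuationExperiment,
    exp_b: FluctuationExperiment,
    on: str = "frequency",
) -> float:
    """Two-sided Mann-Whitney (rank-sum) p-value between two experiments.

    Compares per-culture mutant frequencies r_i/N_i by default (``on`` may
    be ``"counts"`` to compare raw r_i). Exact null distribution when the
    combined sample has at most 20 untied values; normal approximation with
    tie correction otherwise. Degenerate all-tied data returns p = 1.
    """
    if exp_a.C < 3 or exp_b.C < 3:
        raise ValueError("need >= 3 cultures per experiment")
    if on == "frequency":
        a, b = exp_a.frequencies(), exp_b.frequencies()
    elif on == "counts":
        a, b = np.asarray(exp_a.r, float), np.asarray(exp_b.r, float)
    else:
        raise ValueError("on must be 'frequency' or 'counts'")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    return float(mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def normalized_rate_per_kb(mu: float, cen_to_marker_kb: float) -> IntervalRate:
    """Rate per kb of the centromere-to-cassette interval.

    Crossover/BIR-type events anywhere between the centromere and the
    selected cassette produce the selected LOH, so dividing the absolute
    rate by that distance makes intervals of different lengths comparable.
    """
    if cen_to_marker_kb <= 0:
        raise ValueError("cen_to_marker_kb must be > 0")
    return IntervalRate(mu=mu, cen_to_marker_kb=cen_to_marker_kb, mu_per_kb=mu / cen_to_marker_kb)


def coincident_rate(mu1: float, mu2: float) -> tuple[float, int | None]:
    """Predicted rate of two independent events, with its order of magnitude.

    Returns ``(mu1 * mu2, exponent)`` where the exponent is the nearest
    power of ten (``None`` for a zero product).
    """
    if mu1 < 0 or mu2 < 0:
        raise ValueError("rates must be >= 0")
    product = mu1 * mu2
    if product == 0:
        return 0.0, None
    return product, int(round(math.log10(product)))


def simulate_cultures(
    mu: float,
    N: float,
    C: int,
    seed: int | np.random.Generator | None = None,
    growth: str = "deterministic",
) -> np.ndarray:
    """Simulate mutant counts for C parallel Luria-Delbruck cultures.

    Events per culture ~ Poisson(m = mu * N). Under deterministic growth a
    clone founded when the culture still had to double 1/u-fold reaches
    size floor(1/u), u ~ Uniform(0,1]; under ``growth="stochastic"`` the
    clone size is floor(E/u) with E ~ Exponential(1), reflecting stochastic
    clone expansion. Clone sizes are capped at N and summed per culture.
    """
    if mu < 0 or N < 1 or C < 1:
        raise ValueError("require mu >= 0, N >= 1, C >= 1")
    m = mu * N
    if m > N / 10:
        raise ValueError("model invalid: mutations not rare (mu*N > N/10)")
    if growth not in ("deterministic", "stochastic"):
        raise ValueError("growth must be 'deterministic' or 'stochastic'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = rng.poisson(m, size=C)
    total = int(k.sum())
    if total == 0:
        return np.zeros(C, dtype=np.int64)
    u = 1.0 - rng.random(total)  # Uniform(0, 1]
    sizes = 1.0 / u
    if growth == "stochastic":
        sizes *= rng.exponential(1.0, size=total)
    sizes = np.minimum(np.floor(sizes), N)
    out = np.zeros(C, dtype=np.int64)
    np.add.at(out, np.repeat(np.arange(C), k), sizes.astype(np.int64))
    return out
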