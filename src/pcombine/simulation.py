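"""Type-I error and power study for the combination tests.

Each replicate simulates K independent two-group studies: group 1 from
N(0, sigma^2) and group 2 from N(mu_i, sigma^2), n observations per group,
and takes the one-sided pooled-variance two-sample t-test p-value (testing
mean_2 > mean_1) as that study's p_i.  Per-study sample sizes may be fixed
or Poisson(lambda) (floored at n_min by redraw), and the standard deviation
fixed or gamma(shape, scale) distributed.  The K p-values feed every
requested combiner, and the rejection proportion at level alpha is the
estimated type-I error (all mu_i = 0) or power.

The replicate loop is vectorized by sampling each study's t-statistic from
its sufficient statistics: the two group means are normal and the pooled
variance is a scaled chi-square with 2n-2 df, which reproduces the
two-sample t-statistic's sampling distribution exactly.  The scalar
:func:`simulate_study_pvalue` keeps the literal per-observation draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .combiners import gamma_upper_quantile
from .null_mc import NullStore, build_null_store

__all__ = [
    "SampleSizeSpec",
    "SigmaSpec",
    "Scenario",
    "PowerResult",
    "allocate_effects_ratio",
    "allocate_effects_sparse",
    "simulate_study_pvalue",
    "run_power_study",
    "SIMULATION_METHODS",
]

#: combiner tokens run_power_study understands
SIMULATION_METHODS = ("z", "z_n", "z_sqrt_n", "z_se", "fisher", "cn", "new")


@dataclass(frozen=True)
class SampleSizeSpec:
    """Per-group sample size: fixed n, or Poisson(lam) floored at n_min."""

    mode: str = "fixed"
    n: int = 20
    lam: float = 20.0
    n_min: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "poisson"):
            raise ValueError(f"unknown sample-size mode {self.mode!r}")
        if self.n_min < 2:
            raise ValueError("n_min must be at least 2 for a two-sample t-test")
        if self.mode == "fixed" and self.n < self.n_min:
            raise ValueError("fixed n below n_min")

    def draw(self, shape: Tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
        if self.mode == "fixed":
            return np.full(shape, self.n, dtype=np.int64)
        n = rng.poisson(self.lam, size=shape)
        while True:  # redraw below-floor sizes; Poi(20) < 2 has prob ~5e-8
            low = n < self.n_min
            if not low.any():
                return n
            n[low] = rng.poisson(self.lam, size=int(low.sum()))


@dataclass(frozen=True)
class SigmaSpec:
    """Per-study standard deviation: fixed, or gamma(shape, scale) distributed."""

    mode: str = "fixed"
    sigma: float = 1.0
    shape: float = 10.0
    scale: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "gamma"):
            raise ValueError(f"unknown sigma mode {self.mode!r}")
        if self.mode == "fixed" and self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def draw(self, shape: Tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
        if self.mode == "fixed":
            return np.full(shape, self.sigma, dtype=float)
        return rng.gamma(self.shape, self.scale, size=shape)


@dataclass(frozen=True)
class Scenario:
    """One simulation condition: K studies, their effects, designs, replicates."""

    K: int
    effects: Sequence[float]
    n_spec: SampleSizeSpec = SampleSizeSpec()
    sigma_spec: SigmaSpec = SigmaSpec()
    reps: int = 10_000
    alpha: float = 0.05
    seed: int = 1
    two_sided: bool = False  # sensitivity switch; one-sided is the default

    def __post_init__(self) -> None:
        if len(self.effects) != self.K:
            raise ValueError(f"effects length {len(self.effects)} != K={self.K}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be positive")


@dataclass(frozen=True)
class PowerResult:
    """Per-method rejection proportions with Monte-Carlo standard errors."""

    scenario: Scenario
    reps: int
    power: Dict[str, float]
    stderr: Dict[str, float]


def allocate_effects_ratio(total: float, ratio: float) -> Tuple[float, float]:
    """Split a total effect between K=2 studies with mu_1/mu_2 = ratio.

    ratio=0 puts everything on study 2 (maximal heterogeneity); ratio=1
    splits evenly.
    """
    if total <= 0:
        raise ValueError("total effect must be positive")
    if not (0.0 <= ratio <= 1.0):
        raise ValueError("ratio must lie in [0, 1]")
    mu2 = total / (1.0 + ratio)
    return (total - mu2, mu2)


def allocate_effects_sparse(K: int, total: float, i_active: int) -> np.ndarray:
    """First i_active studies each get total/i_active; the rest get zero."""
    if not (1 <= i_active <= K):
        raise ValueError(f"i_active={i_active} out of range 1..{K}")
    eff = np.zeros(K)
    eff[:i_active] = total / i_active
    return eff


def simulate_study_pvalue(n: int, mu: float, sigma: float, rng: np.random.Generator) -> float:
    """One study's p-value: literal two-sample draw + pooled one-sided t-test.

    Group 1 ~ N(0, sigma^2), group 2 ~ N(mu, sigma^2), n per group;
    alternative is mean_2 > mean_1.
    """
    if n < 2 or sigma <= 0:
        raise ValueError("need n >= 2 and sigma > 0")
    x = rng.normal(0.0, sigma, n)
    y = rng.normal(mu, sigma, n)
    df = 2 * n - 2
    sp2 = ((n - 1) * x.var(ddof=1) + (n - 1) * y.var(ddof=1)) / df
    t = (y.mean() - x.mean()) / np.sqrt(sp2 * 2.0 / n)
    return float(stats.t.sf(t, df))


def _simulate_pvalue_matrix(sc: Scenario, rng: np.random.Generator):
    """(reps, K) matrix of study p-values plus realized n and se arrays."""
    shape = (sc.reps, sc.K)
    n = sc.n_spec.draw(shape, rng)
    sigma = sc.sigma_spec.draw(shape, rng)
    mu = np.broadcast_to(np.asarray(sc.effects, dtype=float), shape)
    df = 2 * n - 2
    mean1 = rng.normal(0.0, sigma / np.sqrt(n))
    mean2 = rng.normal(mu, sigma / np.sqrt(n))
    sp2 = sigma**2 * rng.chisquare(df) / df
    se = np.sqrt(sp2 * 2.0 / n)
    t = (mean2 - mean1) / se
    if sc.two_sided:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        p = stats.t.sf(t, df)
    # guard against exact 0/1 from extreme draws so quantile transforms stay finite
    np.clip(p, 1e-300, 1.0 - 1e-16, out=p)
    return p, n, se


def _reject_matrix(method, p, n, se, alpha, store):
    """Boolean rejection vector over replicates for one combiner token."""
    reps, K = p.shape
    if method == "z":
        z = stats.norm.ppf(p).sum(axis=1) / np.sqrt(K)
        return stats.norm.cdf(z) < alpha
    if method in ("z_n", "z_sqrt_n", "z_se"):
        if method == "z_n":
            w = (2 * n).astype(float)  # realized total sample size per study
        elif method == "z_sqrt_n":
            w = np.sqrt(2.0 * n)
        else:
            w = 1.0 / se  # realized SE of the mean difference
        z = (w * stats.norm.ppf(p)).sum(axis=1) / np.sqrt((w**2).sum(axis=1))
        return stats.norm.cdf(z) < alpha
    if method == "fisher":
        t = -2.0 * np.log(p).sum(axis=1)
        return stats.chi2.sf(t, 2 * K) < alpha
    if method == "cn":
        t = stats.chi2.isf(p, 1).sum(axis=1)
        return stats.chi2.sf(t, K) < alpha
    if method == "new":
        t = gamma_upper_quantile(1.0 / p, p).sum(axis=1)
        exceed = store.N - np.searchsorted(store.samples, t, side="left")
        return (exceed + 1) / (store.N + 1) < alpha
    raise ValueError(f"unknown method token {method!r}")


def run_power_study(
    scenario: Scenario,
    methods: Sequence[str] = ("z", "z_n", "z_se", "fisher", "cn", "new"),
    null_n: int = 100_000,
    store: Optional[NullStore] = None,
) -> PowerResult:
    """Estimate each method's rejection proportion under one scenario.

    When the adaptive test ("new") is requested, one Monte-Carlo null store
    per (K, null_n) is built up front (seeded from the scenario seed) and
    shared across replicates; its draws are independent of the data loop.
    """
    if not methods:
        raise ValueError("need at least one method token")
    for m in methods:
        if m not in SIMULATION_METHODS:
            raise ValueError(f"unknown method token {m!r}")
    rng = np.random.default_rng(scenario.seed)
    if "new" in methods and store is None:
        # offset keeps the null draws decoupled from the data stream
        store = build_null_store(scenario.K, null_n, seed=scenario.seed + 999_983)
    p, n, se = _simulate_pvalue_matrix(scenario, rng)
    power, stderr = {}, {}
    for m in methods:
        rej = _reject_matrix(m, p, n, se, scenario.alpha, store)
        prop = float(rej.mean())
        power[m] = prop
        stderr[m] = float(np.sqrt(prop * (1.0 - prop) / scenario.reps))
    return PowerResult(scenario, scenario.reps, power, stderr)
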