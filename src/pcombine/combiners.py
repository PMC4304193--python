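"""Closed-form p-value combination tests and the adaptive-shape gamma statistic.

All combiners take a validated :class:`StudyPValues` vector of K per-study
p-values and return a :class:`CombineResult`.  The convention throughout is
*one-sided* p-values with "small = evidence for the common alternative": the
weighted z-statistic Z_W = sum_i w_i Phi^-1(p_i) / sqrt(sum_j w_j^2) is then
negative under the alternative and the combined p-value is Phi(Z_W), so that
combining a single p-value returns it unchanged.

The quantile-sum family works on the opposite tail: Fisher's statistic
-2 sum_i log p_i is the sum of upper chi-square(2) quantiles at the p_i,
Lancaster generalizes to per-study degrees of freedom d_i, and the gamma
combiner generalizes further to per-study gamma shapes.  The adaptive
statistic sets each shape to 1/p_i (scale 1), so a small p-value contributes
a term with a large expected value; its null has no closed form and is
handled by :mod:`pcombine.null_mc`.

No randomness anywhere in this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "StudyPValues",
    "WeightSpec",
    "DegreesOfFreedom",
    "GammaShapeSpec",
    "CombineResult",
    "validate_pvalues",
    "stouffer_combine",
    "weighted_z_combine",
    "fisher_combine",
    "lancaster_combine",
    "chen_nadarajah_combine",
    "gamma_combine",
    "adaptive_gamma_statistic",
    "gamma_upper_quantile",
    "METHOD_TOKENS",
    "WILSON_HILFERTY_SHAPE_THRESHOLD",
]

#: method name tokens used across the package (CLI, results tables)
METHOD_TOKENS = ("z", "z_n", "z_sqrt_n", "z_se", "fisher", "lancaster", "cn", "gamma", "new")

#: above this gamma shape the inverse incomplete gamma is replaced by the
#: Wilson-Hilferty cube-root normal approximation
WILSON_HILFERTY_SHAPE_THRESHOLD = 1e8

DEFAULT_EPSILON = 1e-15


@dataclass(frozen=True)
class StudyPValues:
    """Ordered per-study p-values; the universal combiner input."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    @property
    def K(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return self.K


@dataclass(frozen=True)
class WeightSpec:
    """Weights for the weighted z-test.

    ``mode`` selects how the weight vector is resolved:

    - ``unit``: all weights 1 (Stouffer),
    - ``sample_size``: w_i = n_i (Mosteller-Bush),
    - ``sqrt_sample_size``: w_i = sqrt(n_i),
    - ``inverse_se``: w_i = 1/se_i,
    - ``explicit``: user-supplied positive weights.
    """

    mode: str = "unit"
    weights: Optional[Sequence[float]] = None
    sample_sizes: Optional[Sequence[float]] = None
    standard_errors: Optional[Sequence[float]] = None

    def resolve(self, K: int) -> np.ndarray:
        if self.mode == "unit":
            w = np.ones(K)
        elif self.mode == "sample_size":
            if self.sample_sizes is None:
                raise ValueError("mode='sample_size' requires sample_sizes")
            w = np.asarray(self.sample_sizes, dtype=float)
        elif self.mode == "sqrt_sample_size":
            if self.sample_sizes is None:
                raise ValueError("mode='sqrt_sample_size' requires sample_sizes")
            w = np.sqrt(np.asarray(self.sample_sizes, dtype=float))
        elif self.mode == "inverse_se":
            if self.standard_errors is None:
                raise ValueError("mode='inverse_se' requires standard_errors")
            w = 1.0 / np.asarray(self.standard_errors, dtype=float)
        elif self.mode == "explicit":
            if self.weights is None:
                raise ValueError("mode='explicit' requires weights")
            w = np.asarray(self.weights, dtype=float)
        else:
            raise ValueError(f"unknown weight mode {self.mode!r}")
        if len(w) != K:
            raise ValueError(f"weight vector length {len(w)} != K={K}")
        if not np.all(np.isfinite(w)) or np.any(w <= 0):
            raise ValueError("all resolved weights must be positive and finite")
        return w


@dataclass(frozen=True)
class DegreesOfFreedom:
    """Per-study chi-square degrees of freedom for the Lancaster combiner."""

    dfs: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.dfs, dtype=float)
        if np.any(d <= 0) or not np.all(np.isfinite(d)):
            raise ValueError("all degrees of freedom must be positive and finite")
        object.__setattr__(self, "dfs", d)


@dataclass(frozen=True)
class GammaShapeSpec:
    """Per-study gamma shapes and a common scale for the gamma combiner."""

    shapes: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.shapes, dtype=float)
        if np.any(a <= 0) or not np.all(np.isfinite(a)):
            raise ValueError("all gamma shapes must be positive and finite")
        if not (self.scale > 0 and np.isfinite(self.scale)):
            raise ValueError("gamma scale must be positive and finite")
        object.__setattr__(self, "shapes", a)


@dataclass(frozen=True)
class CombineResult:
    """Outcome of one combination test."""

    method: str
    statistic: float
    null_description: str
    combined_p: float
    mc_stderr: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.combined_p <= 1.0):
            raise ValueError(f"combined_p={self.combined_p} outside [0, 1]")


def validate_pvalues(raw: Sequence[float], epsilon: float = DEFAULT_EPSILON) -> StudyPValues:
    """Validate raw per-study p-values and clip them into (0, 1).

    Raw values of exactly 0 or 1 are clipped to ``epsilon`` / ``1 - epsilon``
    (with a warning) so that quantile transforms stay finite.  Order is
    preserved; anything non-finite or outside [0, 1] is an error.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("no studies: need a non-empty 1-d sequence of p-values")
    bad = ~np.isfinite(arr) | (arr < 0) | (arr > 1)
    if np.any(bad):
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(f"invalid p-value at index {i}: {arr[i]!r}")
    lo, hi = epsilon, 1.0 - epsilon
    if np.any((arr < lo) | (arr > hi)):
        warnings.warn(
            f"{int(((arr < lo) | (arr > hi)).sum())} p-value(s) clipped into "
            f"[{lo:g}, {hi:g}]",
            stacklevel=2,
        )
    return StudyPValues(np.clip(arr, lo, hi))


def _as_pvalues(p) -> StudyPValues:
    return p if isinstance(p, StudyPValues) else validate_pvalues(p)


def stouffer_combine(p: StudyPValues) -> CombineResult:
    """Unweighted z-test (Stouffer): Z_W = sum Phi^-1(p_i) / sqrt(K)."""
    p = _as_pvalues(p)
    z = stats.norm.ppf(p.values).sum() / np.sqrt(p.K)
    return CombineResult("z", float(z), "standard normal", float(stats.norm.cdf(z)))


def weighted_z_combine(p: StudyPValues, w: WeightSpec) -> CombineResult:
    """Weighted z-test: Z_W = sum w_i Phi^-1(p_i) / sqrt(sum w_j^2).

    Only weight ratios matter; the weights are used exactly as resolved
    (no normalization).
    """
    p = _as_pvalues(p)
    wv = w.resolve(p.K)
    z = (wv * stats.norm.ppf(p.values)).sum() / np.sqrt((wv**2).sum())
    method = {"unit": "z", "sample_size": "z_n", "sqrt_sample_size": "z_sqrt_n", "inverse_se": "z_se"}.get(w.mode, "z_w")
    return CombineResult(method, float(z), "standard normal", float(stats.norm.cdf(z)))


def fisher_combine(p: StudyPValues) -> CombineResult:
    """Fisher's method: -2 sum log p_i against chi-square with 2K df."""
    p = _as_pvalues(p)
    t = -2.0 * np.log(p.values).sum()
    df = 2 * p.K
    return CombineResult("fisher", float(t), f"chi-square df={df}", float(stats.chi2.sf(t, df)))


def lancaster_combine(p: StudyPValues, d: DegreesOfFreedom) -> CombineResult:
    """Lancaster's method: sum of upper chi-square(d_i) quantiles at p_i.

    The statistic sum_i F_i^-1(1 - p_i), with F_i the chi-square CDF with
    d_i degrees of freedom, is chi-square with sum d_i df under the null.
    """
    p = _as_pvalues(p)
    if len(d.dfs) != p.K:
        raise ValueError(f"degrees-of-freedom length {len(d.dfs)} != K={p.K}")
    t = stats.chi2.isf(p.values, d.dfs).sum()
    df = d.dfs.sum()
    return CombineResult("lancaster", float(t), f"chi-square df={df:g}", float(stats.chi2.sf(t, df)))


def chen_nadarajah_combine(p: StudyPValues) -> CombineResult:
    """Chen-Nadarajah test: Lancaster with one degree of freedom per study."""
    p = _as_pvalues(p)
    res = lancaster_combine(p, DegreesOfFreedom(np.ones(p.K)))
    return CombineResult("cn", res.statistic, res.null_description, res.combined_p)


def gamma_combine(p: StudyPValues, spec: GammaShapeSpec) -> CombineResult:
    """Gamma-distribution combiner: T = sum G^-1_{a_i, b}(1 - p_i).

    With constant per-study shapes the null of T is gamma(sum a_i, b); the
    combined p-value is invariant to the scale b.  Shapes a_i = v/2 with
    scale 2 recover Lancaster with df v; a_i = 1, scale 2 is Fisher and
    a_i = 1/2, scale 2 is Chen-Nadarajah.
    """
    p = _as_pvalues(p)
    if len(spec.shapes) != p.K:
        raise ValueError(f"shape vector length {len(spec.shapes)} != K={p.K}")
    t = spec.scale * special.gammainccinv(spec.shapes, p.values).sum()
    a_tot = spec.shapes.sum()
    pv = float(special.gammaincc(a_tot, t / spec.scale))
    return CombineResult(
        "gamma", float(t), f"gamma(shape={a_tot:g}, scale={spec.scale:g})", pv
    )


def gamma_upper_quantile(shape, p):
    """Upper-tail gamma quantile x with SF_shape(x) = p, scale 1.

    Uses the inverse regularized incomplete gamma; for very large shapes
    (above ``WILSON_HILFERTY_SHAPE_THRESHOLD``) switches to the
    Wilson-Hilferty cube-root normal approximation
    ``a * (1 - 1/(9a) + z / (3 sqrt(a)))**3`` with z the standard-normal
    upper quantile at p, which stays accurate where the generic inversion
    may degrade.
    """
    shape = np.asarray(shape, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.empty(np.broadcast(shape, p).shape)
    shape_b = np.broadcast_to(shape, out.shape)
    p_b = np.broadcast_to(p, out.shape)
    big = shape_b > WILSON_HILFERTY_SHAPE_THRESHOLD
    if np.any(~big):
        out[~big] = special.gammainccinv(shape_b[~big], p_b[~big])
    if np.any(big):
        a = shape_b[big]
        z = stats.norm.isf(p_b[big])
        out[big] = a * (1.0 - 1.0 / (9.0 * a) + z / (3.0 * np.sqrt(a))) ** 3
    return out if out.ndim else float(out)


def adaptive_gamma_statistic(p: StudyPValues) -> float:
    """Adaptive-shape gamma statistic T = sum G^-1_{1/p_i, 1}(1 - p_i).

    Each study's shape is the inverse of its p-value, so smaller p-values
    contribute terms with larger expected value (the gamma mean at scale 1
    equals the shape).  Because the shapes are data-dependent, T is not
    gamma distributed; its p-value comes from the Monte-Carlo null in
    :mod:`pcombine.null_mc`.
    """
    p = _as_pvalues(p)
    terms = gamma_upper_quantile(1.0 / p.values, p.values)
    terms = np.atleast_1d(terms)
    if not np.all(np.isfinite(terms)):
        i = int(np.flatnonzero(~np.isfinite(terms))[0])
        raise ArithmeticError(
            f"gamma quantile evaluation failed for study index {i} (p={p.values[i]!r})"
        )
    return float(terms.sum())
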