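"""Monte-Carlo null distribution for the adaptive-shape gamma test.

Under the global null all K per-study p-values are i.i.d. Uniform(0,1), so
the null of T = sum_i G^-1_{1/p_i, 1}(1 - p_i) can be sampled directly:
draw K uniforms, evaluate T, repeat N times.  The p-value of an observed
statistic is its exceedance proportion in that sample, reported with the
add-one estimator (exceed + 1)/(N + 1) so it is valid (never zero) and
usable as a test at any level; the difference from the raw proportion is
O(1/N).

A :class:`NullStore` keeps the sorted sample keyed by (K, N, seed) and can
be persisted to a small binary cache (little-endian float64) so repeated
CLI runs do not resimulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .combiners import (
    CombineResult,
    StudyPValues,
    adaptive_gamma_statistic,
    gamma_upper_quantile,
    validate_pvalues,
)

__all__ = ["NullStore", "MCResult", "build_null_store", "mc_pvalue", "adaptive_gamma_combine"]

_BLOCK = 100_000  # draws generated per block to bound memory; internal constant


@dataclass(frozen=True)
class NullStore:
    """Sorted Monte-Carlo sample of the adaptive statistic's null for one K."""

    K: int
    N: int
    seed: int
    samples: np.ndarray  # sorted ascending, length N

    def cache_name(self) -> str:
        return f"null_K{self.K}_N{self.N}_seed{self.seed}.f64"

    def save(self, cache_dir) -> Path:
        path = Path(cache_dir) / self.cache_name()
        path.parent.mkdir(parents=True, exist_ok=True)
        self.samples.astype("<f8").tofile(path)
        return path

    @classmethod
    def load(cls, cache_dir, K: int, N: int, seed: int) -> Optional["NullStore"]:
        path = Path(cache_dir) / f"null_K{K}_N{N}_seed{seed}.f64"
        if not path.exists():
            return None
        samples = np.fromfile(path, dtype="<f8")
        if len(samples) != N:
            return None  # stale/corrupt cache: ignore
        return cls(K, N, seed, samples)


@dataclass(frozen=True)
class MCResult:
    """Monte-Carlo exceedance p-value with its sampling precision."""

    p_hat: float
    stderr: float
    N: int
    exceed_count: int


def build_null_store(K: int, N: int, seed: int, cache_dir=None) -> NullStore:
    """Draw N null statistics (K i.i.d. uniforms each), sorted; deterministic.

    If ``cache_dir`` is given, a matching cached store is loaded when present
    and the freshly built store is saved there otherwise.
    """
    if K < 1 or N < 1:
        raise ValueError("K and N must be positive integers")
    if cache_dir is not None:
        cached = NullStore.load(cache_dir, K, N, seed)
        if cached is not None:
            return cached
    rng = np.random.default_rng(seed)
    out = np.empty(N)
    pos = 0
    while pos < N:
        m = min(_BLOCK, N - pos)
        u = rng.random((m, K))
        out[pos : pos + m] = gamma_upper_quantile(1.0 / u, u).sum(axis=1)
        pos += m
    out.sort()
    store = NullStore(K, N, seed, out)
    if cache_dir is not None:
        store.save(cache_dir)
    return store


def mc_pvalue(t_obs: float, store: NullStore) -> MCResult:
    """Exceedance p-value of ``t_obs`` in the store's sorted null sample.

    Counts samples >= t_obs (inclusive ties, the conservative choice) by
    binary search and applies the add-one estimator.
    """
    if not np.isfinite(t_obs):
        raise ValueError("observed statistic must be finite")
    n = store.N
    exceed = n - int(np.searchsorted(store.samples, t_obs, side="left"))
    p_hat = (exceed + 1) / (n + 1)
    stderr = float(np.sqrt(p_hat * (1.0 - p_hat) / n))
    return MCResult(p_hat, stderr, n, exceed)


def adaptive_gamma_combine(
    p: StudyPValues,
    N: int = 1_000_000,
    seed: int = 1,
    store: Optional[NullStore] = None,
    cache_dir=None,
) -> CombineResult:
    """Adaptive-shape gamma test with Monte-Carlo p-value.

    Computes T, builds (or reuses) a null store of N draws for this K, and
    returns the exceedance p-value with its MC standard error.
    """
    p = p if isinstance(p, StudyPValues) else validate_pvalues(p)
    if store is not None and store.K != p.K:
        raise ValueError(f"null store built for K={store.K}, input has K={p.K}")
    if store is None:
        store = build_null_store(p.K, N, seed, cache_dir=cache_dir)
    t = adaptive_gamma_statistic(p)
    res = mc_pvalue(t, store)
    return CombineResult(
        method="new",
        statistic=t,
        null_description=f"MC null, {store.N} samples, seed {store.seed}",
        combined_p=res.p_hat,
        mc_stderr=res.stderr,
    )
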