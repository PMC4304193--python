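"""Per-study 2x2 case/control tests and the meta-analysis pipeline.

A :class:`CountTable` holds one row per study: event and total counts for
the case and control arms (subject counts).  Each study is tested with the
pooled two-proportion z-test (two-sided, no continuity correction); the
resulting per-study p-values — or externally supplied ones — are then fed
to any of the package's combiners.  For the sample-size-weighted z-test the
weight is the study's total sample size (case_total + control_total); for
the inverse-SE-weighted variant it is the reciprocal of the pooled
two-proportion standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportions_ztest

from . import combiners as cmb
from .combiners import CombineResult, StudyPValues, WeightSpec, validate_pvalues
from .null_mc import adaptive_gamma_combine

__all__ = ["CountTable", "two_proportion_pvalue", "pooled_se", "analyze_count_table"]


@dataclass(frozen=True)
class CountTable:
    """Per-study case/control event and total counts."""

    labels: Sequence[str]
    case_event: np.ndarray
    case_total: np.ndarray
    control_event: np.ndarray
    control_total: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("case_event", "case_total", "control_event", "control_total"):
            a = np.asarray(getattr(self, name))
            if a.size == 0:
                raise ValueError("no studies")
            if np.any(a < 0) or not np.issubdtype(a.dtype, np.integer):
                raise ValueError(f"{name} must be non-negative integers")
            arrays[name] = a
            object.__setattr__(self, name, a)
        if not (
            len(self.labels)
            == len(self.case_event)
            == len(self.case_total)
            == len(self.control_event)
            == len(self.control_total)
        ):
            raise ValueError("all count columns must have equal length")
        for arm in ("case", "control"):
            ev, tot = arrays[f"{arm}_event"], arrays[f"{arm}_total"]
            if np.any(tot < 1):
                raise ValueError(f"{arm} arm has a total below 1")
            if np.any(ev > tot):
                i = int(np.flatnonzero(ev > tot)[0])
                raise ValueError(
                    f"study {self.labels[i]!r}: {arm} events exceed the {arm} total"
                )

    @property
    def n_studies(self) -> int:
        return len(self.labels)

    def row(self, i: int) -> "CountTable":
        return CountTable(
            [self.labels[i]],
            self.case_event[i : i + 1],
            self.case_total[i : i + 1],
            self.control_event[i : i + 1],
            self.control_total[i : i + 1],
        )


def pooled_se(table: CountTable) -> np.ndarray:
    """Pooled two-proportion standard error per study."""
    pool = (table.case_event + table.control_event) / (
        table.case_total + table.control_total
    )
    return np.sqrt(pool * (1.0 - pool) * (1.0 / table.case_total + 1.0 / table.control_total))


def two_proportion_pvalue(study: CountTable) -> float:
    """Two-sided pooled two-proportion z-test p-value for a single study.

    Degenerate tables (all subjects events, or none) have an undefined
    pooled variance and raise, naming the study.
    """
    if study.n_studies != 1:
        raise ValueError("expects a single-study table; use CountTable.row")
    events = int(study.case_event[0] + study.control_event[0])
    total = int(study.case_total[0] + study.control_total[0])
    if events == 0 or events == total:
        raise ValueError(
            f"study {study.labels[0]!r}: degenerate table (pooled proportion 0 or 1)"
        )
    count = np.array([study.case_event[0], study.control_event[0]])
    nobs = np.array([study.case_total[0], study.control_total[0]])
    _, p = proportions_ztest(count, nobs, alternative="two-sided", prop_var=False)
    return float(p)


def study_pvalues(table: CountTable) -> StudyPValues:
    """Per-study two-proportion p-values for every row of the table."""
    return validate_pvalues([two_proportion_pvalue(table.row(i)) for i in range(table.n_studies)])


def analyze_count_table(
    table: CountTable,
    methods: Sequence[str] = ("z", "z_n", "z_se", "fisher", "cn", "new"),
    null_n: int = 1_000_000,
    seed: int = 1,
    pvalues: Optional[Sequence[float]] = None,
    cache_dir=None,
) -> List[CombineResult]:
    """Run the full meta-analysis: per-study tests, then every combiner.

    ``pvalues`` bypasses the per-study test with externally supplied
    (e.g. published) p-values; the counts still drive the weighted-z
    weights.
    """
    p = validate_pvalues(pvalues) if pvalues is not None else study_pvalues(table)
    if p.K != table.n_studies:
        raise ValueError("p-value count does not match the number of studies")
    n_total = table.case_total + table.control_total
    results: List[CombineResult] = []
    for m in methods:
        if m == "z":
            results.append(cmb.stouffer_combine(p))
        elif m == "z_n":
            results.append(cmb.weighted_z_combine(p, WeightSpec("sample_size", sample_sizes=n_total)))
        elif m == "z_sqrt_n":
            results.append(cmb.weighted_z_combine(p, WeightSpec("sqrt_sample_size", sample_sizes=n_total)))
        elif m == "z_se":
            results.append(cmb.weighted_z_combine(p, WeightSpec("inverse_se", standard_errors=pooled_se(table))))
        elif m == "fisher":
            results.append(cmb.fisher_combine(p))
        elif m == "cn":
            results.append(cmb.chen_nadarajah_combine(p))
        elif m == "new":
            results.append(adaptive_gamma_combine(p, N=null_n, seed=seed, cache_dir=cache_dir))
        else:
            raise ValueError(f"unknown method token {m!r}")
    return results
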