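"""File readers/writers and packaged fixtures.

Canonical dialect: TSV with a header row, UTF-8, LF line endings, '.'
decimal separator; commas are accepted by sniffing the header line.
P-value tables carry columns ``study, pvalue[, n, se]``; count tables carry
``study, case_event, case_total, control_event, control_total``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .combiners import CombineResult, StudyPValues, validate_pvalues
from .count_tests import CountTable

__all__ = [
    "PValueTable",
    "read_pvalue_table",
    "read_count_table",
    "write_results",
    "generate_fixtures",
    "packaged_fixture",
]

RESULT_COLUMNS = ("method", "statistic", "combined_p", "mc_stderr", "null_description")


@dataclass(frozen=True)
class PValueTable:
    """Parsed p-value table: validated p-values plus optional n/se columns."""

    pvalues: StudyPValues
    labels: Sequence[str]
    sample_sizes: Optional[np.ndarray] = None
    standard_errors: Optional[np.ndarray] = None


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = "," if header.count(",") > header.count("\t") else "\t"
    return pd.read_csv(path, sep=sep)


def read_pvalue_table(path) -> PValueTable:
    """Read a study/pvalue table; row order preserved, p-values validated."""
    df = _read_table(path)
    for col in ("study", "pvalue"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    raw = pd.to_numeric(df["pvalue"], errors="coerce").to_numpy()
    if np.any(~np.isfinite(raw)):
        row = int(np.flatnonzero(~np.isfinite(raw))[0]) + 1
        raise ValueError(f"unparsable or non-finite p-value at row {row}")
    bad = (raw < 0) | (raw > 1)
    if np.any(bad):
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(f"p-value outside [0, 1] at row {row}: {raw[row - 1]}")
    n = df["n"].to_numpy(dtype=float) if "n" in df.columns else None
    se = df["se"].to_numpy(dtype=float) if "se" in df.columns else None
    return PValueTable(validate_pvalues(raw), [str(s) for s in df["study"]], n, se)


def read_count_table(path) -> CountTable:
    """Read a per-study 2x2 count table."""
    df = _read_table(path)
    cols = ("study", "case_event", "case_total", "control_event", "control_total")
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    if len(df) == 0:
        raise ValueError("no studies")
    return CountTable(
        [str(s) for s in df["study"]],
        df["case_event"].to_numpy(dtype=np.int64),
        df["case_total"].to_numpy(dtype=np.int64),
        df["control_event"].to_numpy(dtype=np.int64),
        df["control_total"].to_numpy(dtype=np.int64),
    )


def _fmt(x: Optional[float]) -> str:
    # >= 4 significant digits so p-values of order 0.008 survive a round trip
    return "" if x is None else f"{x:.6g}"


def results_frame(results: Sequence[CombineResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": [r.method for r in results],
            "statistic": [r.statistic for r in results],
            "combined_p": [r.combined_p for r in results],
            "mc_stderr": [r.mc_stderr for r in results],
            "null_description": [r.null_description for r in results],
        }
    )


def write_results(results: Sequence[CombineResult], path, format: str = "tsv") -> None:
    """Write combiner results in request order as TSV or JSON."""
    if not results:
        raise ValueError("no results to write")
    path = Path(path)
    if format == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(RESULT_COLUMNS) + "\n")
            for r in results:
                fh.write(
                    "\t".join(
                        [r.method, _fmt(r.statistic), _fmt(r.combined_p), _fmt(r.mc_stderr), r.null_description]
                    )
                    + "\n"
                )
    elif format == "json":
        payload = [
            {
                "method": r.method,
                "statistic": r.statistic,
                "combined_p": r.combined_p,
                "mc_stderr": r.mc_stderr,
                "null_description": r.null_description,
            }
            for r in results
        ]
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def packaged_fixture(name: str) -> Path:
    """Path to a fixture shipped inside the package's data directory."""
    return Path(resources.files("pcombine") / "data" / name)


_TABLE1 = """study\tcase_event\tcase_total\tcontrol_event\tcontrol_total
1\t11\t270\t25\t630
2\t244\t1016\t282\t926
3\t49\t234\t35\t166
4\t79\t600\t76\t600
5\t71\t290\t86\t340
"""

_PVALUES = """study\tpvalue\tn
1\t0.94\t900
2\t0.0015\t1942
3\t0.97\t400
4\t0.79\t1200
5\t0.81\t630
"""


def _scenario_yaml(K, design, seed):
    doc = {
        "K": K,
        "alpha": 0.05,
        "reps": 2000,
        "seed": seed,
        "n_mode": "fixed",
        "n": 20,
        "sigma_mode": "fixed",
        "sigma": 1.0,
        "methods": ["z", "z_n", "z_se", "fisher", "cn", "new"],
    }
    doc.update(design)
    return yaml.safe_dump(doc, sort_keys=False)


def generate_fixtures(out_dir, seed: int = 1) -> List[Path]:
    """Write the packaged count/p-value fixtures plus three scenario configs.

    The scenario configs mirror the simulation designs: a K=2 effect-ratio
    sweep (total effect 1, ratios 0 to 1), a K=10 sparse-effects sweep and a
    K=100 sparse-effects sweep (total effect 2, i active studies), all at
    reduced replicate counts.  Deterministic given ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    def write(name: str, text: str) -> None:
        p = out / name
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(text)
        files.append(p)

    write("table1.tsv", _TABLE1)
    write("depression_pvalues.tsv", _PVALUES)
    write(
        "scenario_k2_ratio.yaml",
        _scenario_yaml(2, {"design": "ratio", "total_effect": 1.0, "ratios": [0, 0.01, 0.05, 0.1, 0.5, 1]}, seed),
    )
    write(
        "scenario_k10_sparse.yaml",
        _scenario_yaml(10, {"design": "sparse", "total_effect": 2.0, "i_active": list(range(1, 11))}, seed),
    )
    write(
        "scenario_k100_sparse.yaml",
        _scenario_yaml(100, {"design": "sparse", "total_effect": 2.0, "i_active": list(range(1, 11))}, seed),
    )
    return files
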