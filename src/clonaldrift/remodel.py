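"""Clonal instability index, tumour-pattern classification, cohort report.

The *clonal instability index* of a case is the mean absolute difference
between pre- and post-treatment exclusive clone fractions, taken over the
union of clones detected at either time point (absent clones contribute a
fraction of 0).  It is 0 for an unchanged monoclonal tumour and 1 for
completely unrelated tumours; 0.1 separates "stable" from "dynamic".

Cases fall into four genomic patterns: collision (two independent
tumours), clonally simple and treatment stable, clonally complex and
treatment stable, and clonally complex and treatment dynamic.  Cases whose
architecture resists automated inference are flagged ``manual``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

import numpy as np
import pandas as pd

from .vario import DETECTION_LIMIT

__all__ = [
    "RemodelResult",
    "ClinicalRecord",
    "PATTERNS",
    "STABILITY_CUTOFF",
    "timepoint_fractions",
    "instability_index",
    "classify_pattern",
    "ki67_response",
    "cohort_summary",
]

PATTERNS = ("collision", "simple_stable", "complex_stable", "complex_dynamic", "manual")

#: Boundary between "stable" and "dynamic" tumours (inclusive on the
#: stable side, so an index of exactly 0.1 is stable).
STABILITY_CUTOFF = 0.1

#: On-treatment Ki67 above this proportion marks endocrine-therapy
#: resistance (strict inequality; exactly 0.10 is sensitive).
KI67_RESISTANT_ABOVE = 0.10


@dataclass(frozen=True)
class RemodelResult:
    case_id: str
    instability_index: float | None  # None when not computable ("—")
    pattern: str
    n_clones: int
    fractions_baseline: dict = field(default_factory=dict)
    fractions_surgical: dict = field(default_factory=dict)
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class ClinicalRecord:
    case_id: str
    age: int | None = None
    subtype_baseline: str = ""
    subtype_surgical: str = ""
    ki67_baseline: float | None = None
    ki67_surgical: float | None = None
    ki67_response: str = ""  # "sensitive" | "resistant" | ""
    allred_baseline: int | None = None
    allred_surgical: int | None = None
    manual_pattern: str = ""


def timepoint_fractions(per_core_fractions: list[dict]) -> dict:
    """Average exclusive clone fractions across cores of one time point.

    ``per_core_fractions`` maps clone -> exclusive fraction for each core;
    a clone absent from a core contributes 0 there.
    """
    if not per_core_fractions:
        raise ValueError("time point has no cores")
    clones = set().union(*per_core_fractions)
    n = len(per_core_fractions)
    return {c: sum(f.get(c, 0.0) for f in per_core_fractions) / n for c in clones}


def instability_index(
    pre: dict, post: dict, *, lod: float = DETECTION_LIMIT
) -> float:
    """Mean absolute difference of clone fractions between time points.

    The mean runs over the union of clones detected (fraction >= lod) at
    either time point; a clone absent from a time point counts as 0 there.
    Both inputs should be exclusive-fraction maps summing to 1.
    """
    detected = {c for c, f in pre.items() if f >= lod} | {
        c for c, f in post.items() if f >= lod
    }
    if not detected:
        raise ValueError("no clones detected at either time point")
    diffs = [abs(pre.get(c, 0.0) - post.get(c, 0.0)) for c in sorted(detected, key=str)]
    return float(np.mean(diffs))


def classify_pattern(
    is_collision: bool,
    n_clones: int | None,
    index: float | None,
    *,
    manual: bool = False,
    cutoff: float = STABILITY_CUTOFF,
) -> str:
    """Assign one of the four genomic patterns (or ``manual``)."""
    if manual:
        return "manual"
    if is_collision:
        return "collision"
    if index is None:
        raise ValueError("undefined instability index without a manual flag")
    if n_clones == 1 and index <= cutoff:
        return "simple_stable"
    if index <= cutoff:
        return "complex_stable"
    return "complex_dynamic"


def ki67_response(ki67_surgical: float | None) -> str:
    """Label endocrine response from on-treatment Ki67 when no label exists."""
    if ki67_surgical is None or (isinstance(ki67_surgical, float) and np.isnan(ki67_surgical)):
        return "unknown"
    if not 0.0 <= ki67_surgical <= 1.0:
        raise ValueError("Ki67 is a proportion in [0, 1]")
    return "resistant" if ki67_surgical > KI67_RESISTANT_ABOVE else "sensitive"


# ---------------------------------------------------------------------------
# cohort report


def _exact_median(values) -> Fraction | None:
    """Median via exact rational arithmetic on the printed decimal values."""
    vals = sorted(Fraction(str(v)) for v in values)
    if not vals:
        return None
    n = len(vals)
    mid = n // 2
    if n % 2:
        return vals[mid]
    return (vals[mid - 1] + vals[mid]) / 2


def _round_frac(f: Fraction | None, ndigits: int) -> float | None:
    """Half-up decimal rounding of an exact rational (report convention)."""
    if f is None:
        return None
    d = Decimal(f.numerator) / Decimal(f.denominator)
    q = Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=ROUND_HALF_UP))


def cohort_summary(clinical: pd.DataFrame, results: pd.DataFrame) -> dict:
    """Summarise patterns, instability and Ki67 response across a cohort.

    Parameters
    ----------
    clinical
        One row per case with at least ``case``, ``ki67_surgical`` and
        ``ki67_response`` columns (see :func:`clonaldrift.datasets.load_table1`).
    results
        One row per case with ``case``, ``pattern`` and
        ``instability_index`` (NaN when undefined).

    Returns a dictionary with per-pattern counts, the computed-index
    median/min/max within the complex-dynamic group (two decimals,
    half-up) and the median/range of surgical Ki67 (percent, one decimal)
    per response label.
    """
    merged = results.merge(clinical, on="case", how="left", suffixes=("", "_clin"))

    pattern_counts = {p: int((merged["pattern"] == p).sum()) for p in PATTERNS}

    dyn = merged.loc[merged["pattern"] == "complex_dynamic"]
    dyn_idx = dyn["instability_index"].dropna()
    dyn_resp = dyn["ki67_response"].str.lower().value_counts().to_dict() if len(dyn) else {}

    summary: dict = {
        "n_cases": int(len(merged)),
        "pattern_counts": pattern_counts,
        "complex_dynamic": {
            "n": int(len(dyn)),
            "n_with_index": int(len(dyn_idx)),
            "response_counts": {k: int(v) for k, v in dyn_resp.items()},
            "index_median": _round_frac(_exact_median(dyn_idx), 2),
            "index_min": _round_frac(_exact_median([dyn_idx.min()]) if len(dyn_idx) else None, 2),
            "index_max": _round_frac(_exact_median([dyn_idx.max()]) if len(dyn_idx) else None, 2),
        },
        "ki67_surgical_pct": {},
    }

    for label, grp in merged.groupby(merged["ki67_response"].str.lower()):
        vals = grp["ki67_surgical"].dropna()
        if not len(vals):
            continue
        pct = [Fraction(str(v)) * 100 for v in vals]
        summary["ki67_surgical_pct"][label] = {
            "n": int(len(vals)),
            "median": _round_frac(_exact_median(vals) * 100 if len(vals) else None, 1),
            "min": _round_frac(min(pct), 1),
            "max": _round_frac(max(pct), 1),
        }
    return summary


def cohort_markdown(summary: dict) -> str:
    """Render the cohort summary as a small markdown report."""
    lines = ["# Cohort summary", ""]
    lines.append("| pattern | cases |")
    lines.append("|---|---|")
    for p, n in summary["pattern_counts"].items():
        lines.append(f"| {p} | {n} |")
    cd = summary["complex_dynamic"]
    lines += [
        "",
        f"Complex & dynamic: {cd['n']} cases "
        f"(computed index median {cd['index_median']}, "
        f"range {cd['index_min']}-{cd['index_max']}).",
        "",
    ]
    for label, stats in summary["ki67_surgical_pct"].items():
        lines.append(
            f"- {label}: median surgical Ki67 {stats['median']}% "
            f"(range {stats['min']}-{stats['max']}%, n={stats['n']})"
        )
    return "\n".join(lines) + "\n"
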