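"""Packaged cohort tables for examples, reports and tests.

Two small printed tables ship with the package: the whole-genome cohort
(case-level clinical markers, endocrine response and the clonal
instability index of each tumour) and the druggable-mutation table from
the targeted extension cohort (per-mutation baseline/surgical VAFs).
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .remodel import STABILITY_CUTOFF

__all__ = ["load_table1", "load_table3", "classify_cohort", "gene_vaf_shift"]


def _data(name: str):
    return resources.files("clonaldrift.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """WGS cohort: clinical markers, response and instability index.

    ``instability_index`` is NaN for the cases whose architecture was
    assigned manually (their ``manual_pattern`` column is set instead).
    """
    with resources.as_file(_data("table1.csv")) as path:
        df = pd.read_csv(path, dtype={"case": str, "manual_pattern": str})
    df["manual_pattern"] = df["manual_pattern"].fillna("")
    return df


def load_table3() -> pd.DataFrame:
    """Druggable mutations with baseline/surgical VAFs (percent)."""
    with resources.as_file(_data("table3.csv")) as path:
        return pd.read_csv(path, dtype={"sample": str, "wgs_case": str})


def classify_cohort(table: pd.DataFrame, *, cutoff: float = STABILITY_CUTOFF) -> pd.DataFrame:
    """Pattern per case from the printed instability index.

    The index column's own endpoints carry the classification: an index of
    1 means completely unrelated tumours (collision), 0 a monoclonal
    tumour with no shift (simple & stable); up to the stable/dynamic
    cutoff the tumour is complex & stable, above it complex & dynamic.
    Cases without a computed index take their ``manual_pattern``.
    """
    patterns = []
    for _, row in table.iterrows():
        idx = row.get("instability_index")
        if pd.isna(idx):
            patterns.append(row.get("manual_pattern") or "manual")
        elif idx == 1.0:
            patterns.append("collision")
        elif idx == 0.0:
            patterns.append("simple_stable")
        elif idx <= cutoff:
            patterns.append("complex_stable")
        else:
            patterns.append("complex_dynamic")
    out = table[["case", "instability_index"]].copy()
    out["pattern"] = patterns
    return out


def gene_vaf_shift(table3: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene mean VAF change (surgical - baseline, percent points)."""
    if table3 is None:
        table3 = load_table3()
    delta = table3["vaf_surgical_pct"] - table3["vaf_baseline_pct"]
    out = (
        table3.assign(delta_vaf_pct=delta)
        .groupby("gene")["delta_vaf_pct"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_delta_vaf_pct", "count": "n_mutations"})
    )
    out["mean_delta_vaf_pct"] = out["mean_delta_vaf_pct"].round(2)
    return out
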