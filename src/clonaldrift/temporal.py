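"""Temporal behaviour of variants between baseline and surgical samples.

Each variant's purity-corrected read counts are compared between every
baseline core and every surgical core with a two-sided Fisher's exact test;
calls with P < 0.05 are retained as changed.  Changed variants whose
corrected VAF in the *other* time point stays below 10% and that carry at
least one RNA-supporting read in their own time point are called
time-point-specific (baseline_specific / surgical_specific); changed
variants above 10% at both time points are enriched or depleted by
direction.  Everything else is shared_stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact

from .purity import correct_counts

__all__ = ["TemporalCall", "fisher_change_test", "classify_temporal"]

CATEGORIES = (
    "shared_stable",
    "enriched",
    "depleted",
    "baseline_specific",
    "surgical_specific",
)


@dataclass(frozen=True)
class TemporalCall:
    variant_key: tuple
    p_value: float
    direction: str  # "up" | "down" | "none"
    category: str
    vaf_baseline_corrected: float
    vaf_surgical_corrected: float
    rna_support_baseline: int
    rna_support_surgical: int
    flags: tuple[str, ...] = field(default=())


def fisher_change_test(
    baseline_counts: tuple[int, int], surgical_counts: tuple[int, int]
) -> float:
    """Two-sided Fisher's exact test on the 2x2 [ref,var] x [time] table.

    Counts should already be purity-corrected integers.  A degenerate
    all-zero table has no defined association and returns 1 with a warning.
    """
    b_ref, b_var = baseline_counts
    s_ref, s_var = surgical_counts
    if min(b_ref, b_var, s_ref, s_var) < 0:
        raise ValueError("counts must be non-negative")
    if b_ref + b_var + s_ref + s_var == 0:
        warnings.warn("all-zero contingency table; p-value undefined, using 1")
        return 1.0
    return float(fisher_exact([[b_ref, b_var], [s_ref, s_var]])[1])


def classify_temporal(
    baseline,
    surgical,
    purity: dict,
    *,
    alpha: float = 0.05,
    specific_vaf: float = 0.10,
    min_rna_reads: int = 1,
    variant_key: tuple = (),
) -> TemporalCall:
    """Classify one variant's behaviour between the two time points.

    Parameters
    ----------
    baseline, surgical
        Sequences of per-core observations
        ``(sample_id, ref_reads, var_reads, rna_var_reads)``; pass
        ``rna_var_reads = -1`` when no RNA data exist for the core.
    purity
        sample_id -> purity, required for every core.

    With several cores the test is run on every baseline x surgical pair;
    the minimum p-value is used and the direction is the majority sign of
    the corrected VAF change (the minimum-p pair breaks ties).
    """
    if not baseline or not surgical:
        raise ValueError("both time points need at least one observation")

    def corrected(obs):
        out = []
        for sample_id, ref, var, rna_var in obs:
            if sample_id not in purity:
                raise ValueError(f"missing purity for sample {sample_id}")
            adj_ref, cvaf = correct_counts(ref, var, purity[sample_id])
            out.append((adj_ref, int(var), cvaf, int(rna_var)))
        return out

    b = corrected(baseline)
    s = corrected(surgical)

    p_min, best_sign, signs = 1.0, 0.0, []
    for b_ref, b_var, b_vaf, _ in b:
        for s_ref, s_var, s_vaf, _ in s:
            p = fisher_change_test((b_ref, b_var), (s_ref, s_var))
            sign = np.sign(s_vaf - b_vaf)
            signs.append(sign)
            if p < p_min or (p == p_min and best_sign == 0.0):
                p_min, best_sign = p, sign
    majority = np.sign(sum(signs))
    sign = majority if majority != 0 else best_sign

    vaf_b = float(np.mean([x[2] for x in b]))
    vaf_s = float(np.mean([x[2] for x in s]))
    rna_b = max((x[3] for x in b), default=-1)
    rna_s = max((x[3] for x in s), default=-1)

    flags: list[str] = []
    if p_min >= alpha:
        category, direction = "shared_stable", "none"
    else:
        direction = "up" if sign > 0 else ("down" if sign < 0 else "none")
        if vaf_b >= specific_vaf and vaf_s >= specific_vaf:
            category = "enriched" if sign > 0 else "depleted"
        elif sign > 0 and vaf_b < specific_vaf:
            if rna_s >= min_rna_reads:
                category = "surgical_specific"
            else:
                category = "enriched"
                flags.append("rna_rule_failed")
        elif sign < 0 and vaf_s < specific_vaf:
            if rna_b >= min_rna_reads:
                category = "baseline_specific"
            else:
                category = "depleted"
                flags.append("rna_rule_failed")
        else:
            category = "enriched" if sign > 0 else "depleted"

    return TemporalCall(
        variant_key=variant_key,
        p_value=p_min,
        direction=direction,
        category=category,
        vaf_baseline_corrected=vaf_b,
        vaf_surgical_corrected=vaf_s,
        rna_support_baseline=rna_b,
        rna_support_surgical=rna_s,
        flags=tuple(flags),
    )
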