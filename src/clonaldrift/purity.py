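"""Tumour purity from SNV allele fractions, and the purity correction.

In a diploid, copy-number-neutral tumour a heterozygous founder mutation is
carried by every tumour cell, so its VAF is p/2 where p is the tumour-cell
fraction (purity) of the specimen.  Purity is therefore estimated as twice
the median VAF of the founder cluster, and observed read counts are
corrected by removing the expected normal-cell read mass (1-p) x depth from
the reference count — the unique linear rule that maps founder VAF p/2 back
to 50%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .vario import vaf

__all__ = [
    "PurityEstimate",
    "PurityError",
    "estimate_purity",
    "correct_counts",
    "correct_vaf",
]

MIN_VARIANTS = 20
MIN_DEPTH = 20


class PurityError(ValueError):
    """Too little usable signal; supply purity explicitly instead."""


@dataclass(frozen=True)
class PurityEstimate:
    sample_id: str
    purity: float  # in (0, 1]
    method: str  # "supplied" | "founder_cluster"
    founder_median_vaf: float


def _upper_mode_median(vafs: np.ndarray) -> float:
    """Median VAF of the upper mode of a kernel-smoothed VAF histogram.

    Used when no cluster hint is available: the founder clone forms the
    highest-VAF mode.  Variants are attributed to the upper mode down to
    the density minimum separating it from the next mode.
    """
    if np.ptp(vafs) < 1e-6:
        return float(np.median(vafs))
    kde = gaussian_kde(vafs)
    grid = np.linspace(0.0, max(0.55, vafs.max() + 0.02), 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = grid[1:-1][interior]
    if len(peaks) == 0:
        return float(np.median(vafs))
    top = peaks.max()
    # boundary: density minimum between the top mode and the next lower one
    lower_peaks = peaks[peaks < top - 1e-9]
    if len(lower_peaks) == 0:
        members = vafs
    else:
        lo, hi = lower_peaks.max(), top
        window = (grid >= lo) & (grid <= hi)
        boundary = grid[window][np.argmin(dens[window])]
        members = vafs[vafs >= boundary]
    return float(np.median(members)) if len(members) else float(np.median(vafs))


def estimate_purity(
    sample_df: pd.DataFrame,
    cluster_hint=None,
    *,
    min_variants: int = MIN_VARIANTS,
    min_depth: int = MIN_DEPTH,
    lod: float = 0.01,
) -> PurityEstimate:
    """Estimate purity of one sample from copy-number-neutral VAFs.

    Parameters
    ----------
    sample_df
        Variant rows of a single sample (CN-neutral, post-filter).
    cluster_hint
        Optional fitted :class:`~clonaldrift.cluster.ClusterSet`; when given
        the founder is the cluster with the highest median VAF among those
        detected in this sample, which is more robust than the
        kernel-density fallback.
    """
    sample_ids = sample_df["sample"].unique()
    if len(sample_ids) != 1:
        raise ValueError("estimate_purity expects variants of exactly one sample")
    sample_id = sample_ids[0]
    depth = sample_df["dna_ref_reads"] + sample_df["dna_var_reads"]
    usable = sample_df.loc[depth >= min_depth]
    if len(usable) < min_variants:
        raise PurityError(
            f"sample {sample_id}: only {len(usable)} variants with depth >= "
            f"{min_depth} (need {min_variants}); supply purity explicitly"
        )
    vafs = vaf(usable["dna_var_reads"], usable["dna_ref_reads"])

    founder_median = None
    if cluster_hint is not None:
        medians = cluster_hint.median_vaf_for_sample(sample_id)
        detected = {k: m for k, m in medians.items() if m >= lod}
        if detected:
            founder_median = max(detected.values())
    if founder_median is None:
        founder_median = _upper_mode_median(np.asarray(vafs, dtype=float))

    purity = min(1.0, 2.0 * founder_median)
    if purity <= 0:
        raise PurityError(f"sample {sample_id}: founder median VAF is zero")
    return PurityEstimate(
        sample_id=str(sample_id),
        purity=purity,
        method="founder_cluster",
        founder_median_vaf=float(founder_median),
    )


def correct_counts(ref_reads: int, var_reads: int, purity: float) -> tuple[int, float]:
    """Purity-correct a (ref, var) count pair.

    Removes the expected normal-cell contribution (1 - purity) x depth from
    the reference reads (clipped at zero, rounded half-up to keep integer
    counts for Fisher's exact test downstream) and returns
    ``(adjusted_ref, corrected_vaf)``.  Purity 1 is the identity.
    """
    if purity <= 0 or purity > 1:
        raise ValueError("purity must lie in (0, 1]")
    if ref_reads < 0 or var_reads < 0:
        raise ValueError("counts must be non-negative")
    depth = ref_reads + var_reads
    if depth == 0:
        raise ValueError("depth must be positive")
    raw = ref_reads - (1.0 - purity) * depth
    adjusted_ref = int(max(0, np.floor(raw + 0.5)))  # half-up
    denom = var_reads + adjusted_ref
    corrected = var_reads / denom if denom > 0 else 0.0
    return adjusted_ref, corrected


def correct_vaf(v, purity: float):
    """Purity correction on the VAF scale: min(1, v / purity) (vectorised).

    Continuous limit of :func:`correct_counts`; used for cluster medians
    where no integer counts are needed.
    """
    if purity <= 0 or purity > 1:
        raise ValueError("purity must lie in (0, 1]")
    return np.minimum(1.0, np.asarray(v, dtype=float) / purity)
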