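"""Variant tables, somatic filtering and copy-number-neutral masking.

The atomic unit of the pipeline is a per-sample observation of a somatic
variant: DNA reference/variant read counts in a tumour sample, the matched
normal counts, and (optionally) RNA-seq support reads at the same locus.
Collections of observations are carried as :class:`pandas.DataFrame` in the
column layout of :data:`VARIANT_COLUMNS`; :class:`VariantRecord` is the
scalar view of one row.

Three gatekeeping operations live here:

* :func:`llr_somatic_filter` — a three-hypothesis binomial log-likelihood
  ratio separating somatic calls from germline-heterozygous and wild-type
  explanations, with the conventional depth >= 10 requirement in both the
  tumour and the matched normal, retaining calls with LLR > 3.
* :func:`cn_neutral_mask` — restricts to loci that are copy-number neutral
  (|CN - 2| <= margin, default 0.25) in *every* sample of a case, the
  precondition for interpreting VAF as purity x prevalence / 2.
* :func:`apply_detection_limit` — the ~1% VAF limit of detection below
  which a variant (or clone) is reported absent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

__all__ = [
    "VARIANT_COLUMNS",
    "DETECTION_LIMIT",
    "VariantRecord",
    "CNSegment",
    "VariantTableError",
    "read_variant_table",
    "write_variant_table",
    "read_vcf",
    "read_segments",
    "write_segments",
    "llr_somatic_filter",
    "llr_somatic_filter_table",
    "cn_neutral_mask",
    "apply_detection_limit",
    "vaf",
]

#: Column layout of the variant TSV dialect.  ``normal_ref_reads`` /
#: ``normal_var_reads`` carry the matched-normal counts used by the somatic
#: filter; RNA counts of -1 mean "no RNA data for this sample".
VARIANT_COLUMNS = [
    "case",
    "sample",
    "timepoint",
    "chrom",
    "pos",
    "ref",
    "alt",
    "dna_ref_reads",
    "dna_var_reads",
    "normal_ref_reads",
    "normal_var_reads",
    "rna_ref_reads",
    "rna_var_reads",
    "gene",
    "aa_change",
    "tier",
]

_COUNT_COLUMNS = [
    "dna_ref_reads",
    "dna_var_reads",
    "normal_ref_reads",
    "normal_var_reads",
]

TIMEPOINTS = ("baseline", "surgical", "eot")

#: Limit of detection on the VAF scale (~1%): a variant or clone with VAF
#: below this is reported absent.
DETECTION_LIMIT = 0.01


class VariantTableError(ValueError):
    """Malformed variant table (missing columns, negative counts, ...)."""


@dataclass(frozen=True)
class VariantRecord:
    """One per-sample observation of a somatic variant."""

    case_id: str
    sample_id: str
    timepoint: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    dna_counts: tuple[int, int]  # (ref_reads, var_reads)
    normal_counts: tuple[int, int] = (0, 0)
    rna_counts: tuple[int, int] | None = None
    gene: str = ""
    aa_change: str = ""
    tier: int = 1
    manually_flagged: bool = False

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        """Identity of the variant within a case: (case, chrom, pos, ref, alt)."""
        return (self.case_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def vaf(self) -> float:
        ref, var = self.dna_counts
        depth = ref + var
        if depth == 0:
            raise ZeroDivisionError("VAF undefined at zero depth")
        return var / depth


@dataclass(frozen=True)
class CNSegment:
    """A copy-number segment (0-based half-open), consumed not computed."""

    chrom: str
    start: int
    end: int
    sample_id: str
    copy_number: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")
        if self.copy_number < 0:
            raise ValueError("copy number must be >= 0")


def vaf(var_reads, ref_reads):
    """Variant allele fraction; 0 where depth is 0 (vectorised)."""
    var_reads = np.asarray(var_reads, dtype=float)
    depth = var_reads + np.asarray(ref_reads, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(depth > 0, var_reads / np.maximum(depth, 1e-300), 0.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# table IO


def _validate(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"{origin}: missing mandatory column(s) {missing}")
    for col in _COUNT_COLUMNS + ["pos", "tier"]:
        try:
            values = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise VariantTableError(f"{origin}: non-numeric values in {col}: {exc}") from exc
        df[col] = values.astype(int)
    for col in _COUNT_COLUMNS:
        bad = df.index[df[col] < 0]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise VariantTableError(f"{origin}: negative counts in {col} at line(s) {rows}")
    bad_tier = df.index[~df["tier"].isin([1, 2, 3])]
    if len(bad_tier):
        raise VariantTableError(
            f"{origin}: tier outside 1-3 at line(s) "
            + ", ".join(str(i + 2) for i in bad_tier[:5])
        )
    bad_tp = df.index[~df["timepoint"].isin(TIMEPOINTS)]
    if len(bad_tp):
        raise VariantTableError(
            f"{origin}: unknown timepoint at line(s) "
            + ", ".join(str(i + 2) for i in bad_tp[:5])
        )
    return df


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read the tab-separated variant table, validating counts and columns.

    RNA read columns may hold -1, meaning RNA data are unavailable for that
    sample (distinct from an observed 0).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str, "aa_change": str})
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing mandatory column(s) {missing}")
    df["gene"] = df["gene"].fillna("")
    df["aa_change"] = df["aa_change"].fillna("")
    df["rna_ref_reads"] = df["rna_ref_reads"].fillna(-1).astype(int)
    df["rna_var_reads"] = df["rna_var_reads"].fillna(-1).astype(int)
    return _validate(df, str(path))


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write the variant table in the canonical TSV dialect (lossless)."""
    out = df.loc[:, VARIANT_COLUMNS].copy()
    out.to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path, case_id: str, *, normal_sample: str = "NORMAL",
             timepoints: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read variants from a VCF with per-sample AD (ref,alt depths).

    Multi-allelic records are split into one row per alternate allele.
    Tumour samples are every sample other than ``normal_sample``;
    ``timepoints`` maps tumour sample name -> timepoint label (default
    "baseline").  RNA counts are absent in VCF input and set to -1.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        tumours = [s for s in samples if s != normal_sample]
        for rec in vf:
            for ai, alt in enumerate(rec.alts or ()):
                normal_ad = (0, 0)
                if normal_sample in samples:
                    ad = rec.samples[normal_sample].get("AD")
                    if ad is not None:
                        normal_ad = (int(ad[0]), int(ad[ai + 1]))
                for s in tumours:
                    ad = rec.samples[s].get("AD")
                    if ad is None:
                        continue
                    rows.append(
                        {
                            "case": case_id,
                            "sample": s,
                            "timepoint": (timepoints or {}).get(s, "baseline"),
                            "chrom": rec.chrom,
                            "pos": rec.pos,
                            "ref": rec.ref,
                            "alt": alt,
                            "dna_ref_reads": int(ad[0]),
                            "dna_var_reads": int(ad[ai + 1]),
                            "normal_ref_reads": normal_ad[0],
                            "normal_var_reads": normal_ad[1],
                            "rna_ref_reads": -1,
                            "rna_var_reads": -1,
                            "gene": "",
                            "aa_change": "",
                            "tier": 1,
                        }
                    )
    return _validate(pd.DataFrame(rows, columns=VARIANT_COLUMNS), str(path))


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read copy-number segments from a BED-like table.

    Columns: chrom, start, end, sample, copy_number (0-based half-open).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=["chrom", "start", "end", "sample", "copy_number"],
        dtype={"chrom": str, "sample": str},
        comment="#",
    )
    if (df["start"] >= df["end"]).any():
        raise VariantTableError(f"{path}: segment with start >= end")
    return df


def write_segments(df: pd.DataFrame, path: str | Path) -> None:
    df.loc[:, ["chrom", "start", "end", "sample", "copy_number"]].to_csv(
        path, sep="\t", index=False, header=False
    )


# ---------------------------------------------------------------------------
# somatic LLR filter


def _binom_loglik(var, depth, p):
    # log C(depth, var) omitted: identical across the three hypotheses.
    return xlogy(var, p) + xlogy(depth - var, 1.0 - p)


def llr_somatic_filter(
    tumour_counts: tuple[int, int],
    normal_counts: tuple[int, int],
    error_rate: float = 0.001,
    *,
    min_llr: float = 3.0,
    min_depth: int = 10,
) -> tuple[float, bool]:
    """Score a tumour/normal count pair with the somatic binomial LLR.

    The somatic hypothesis places the normal sample at the sequencing error
    rate and the tumour at its maximum-likelihood allele fraction (floored
    at the error rate).  It is compared against the better of two germline
    hypotheses: heterozygous (both samples at 0.5) and wild-type (both at
    the error rate).  Natural logarithms.

    Returns ``(llr, retained)`` where ``retained`` additionally requires at
    least ``min_depth`` coverage in both samples.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 0.5)")
    t_ref, t_var = tumour_counts
    n_ref, n_var = normal_counts
    if min(t_ref, t_var, n_ref, n_var) < 0:
        raise ValueError("read counts must be non-negative")
    llr, retained = llr_somatic_filter_table(
        np.array([t_ref]), np.array([t_var]), np.array([n_ref]), np.array([n_var]),
        error_rate, min_llr=min_llr, min_depth=min_depth,
    )
    return float(llr[0]), bool(retained[0])


def llr_somatic_filter_table(
    t_ref, t_var, n_ref, n_var, error_rate: float = 0.001,
    *, min_llr: float = 3.0, min_depth: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`llr_somatic_filter` over count arrays."""
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 0.5)")
    t_ref = np.asarray(t_ref, dtype=float)
    t_var = np.asarray(t_var, dtype=float)
    n_ref = np.asarray(n_ref, dtype=float)
    n_var = np.asarray(n_var, dtype=float)
    t_depth = t_ref + t_var
    n_depth = n_ref + n_var
    with np.errstate(invalid="ignore", divide="ignore"):
        t_mle = np.where(t_depth > 0, t_var / np.maximum(t_depth, 1), 0.0)
    t_mle = np.maximum(t_mle, error_rate)
    ll_somatic = _binom_loglik(t_var, t_depth, t_mle) + _binom_loglik(
        n_var, n_depth, error_rate
    )
    ll_het = _binom_loglik(t_var, t_depth, 0.5) + _binom_loglik(n_var, n_depth, 0.5)
    ll_wt = _binom_loglik(t_var, t_depth, error_rate) + _binom_loglik(
        n_var, n_depth, error_rate
    )
    llr = ll_somatic - np.maximum(ll_het, ll_wt)
    retained = (t_depth >= min_depth) & (n_depth >= min_depth) & (llr > min_llr)
    return llr, retained


def apply_somatic_filter(
    df: pd.DataFrame, error_rate: float = 0.001, *, min_llr: float = 3.0,
    min_depth: int = 10,
) -> pd.DataFrame:
    """Keep variants retained by the LLR filter in at least one tumour sample.

    A variant is a case-level object observed in several samples; mirroring
    a union-of-evidence calling strategy, passing the somatic filter in any
    one tumour sample keeps the variant (all its per-sample rows).
    """
    _, retained = llr_somatic_filter_table(
        df["dna_ref_reads"], df["dna_var_reads"],
        df["normal_ref_reads"], df["normal_var_reads"],
        error_rate, min_llr=min_llr, min_depth=min_depth,
    )
    keys = df.loc[retained, ["case", "chrom", "pos", "ref", "alt"]]
    keep = pd.MultiIndex.from_frame(df[["case", "chrom", "pos", "ref", "alt"]]).isin(
        pd.MultiIndex.from_frame(keys)
    )
    return df.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# copy-number-neutral mask


def cn_neutral_mask(
    df: pd.DataFrame,
    segments: pd.DataFrame | None,
    margin: float = 0.25,
    *,
    default_copy_number: float = 2.0,
) -> pd.DataFrame:
    """Restrict to loci copy-number neutral in every sample of each case.

    A locus is kept iff ``|copy_number - 2| <= margin`` holds for the
    covering segment of *every* sample present for the case (closed
    boundary).  Loci not covered by any segment take
    ``default_copy_number`` (diploid) and are kept.  Overlapping segments
    with contradictory copy number for one sample raise a validation error.
    """
    if segments is None or len(segments) == 0:
        return df.copy()

    # per (sample, chrom): sorted interval arrays for bisection
    lookup: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for (sample, chrom), seg in segments.groupby(["sample", "chrom"], sort=False):
        seg = seg.sort_values("start")
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        cns = seg["copy_number"].to_numpy(dtype=float)
        overlap = starts[1:] < ends[:-1]
        if overlap.any():
            i = int(np.argmax(overlap))
            if not math.isclose(cns[i], cns[i + 1]):
                raise VariantTableError(
                    f"contradictory overlapping segments for sample {sample} "
                    f"on {chrom} near {starts[i + 1]}"
                )
        lookup[(sample, chrom)] = (starts, ends, cns)

    def copy_number_at(sample: str, chrom: str, pos1: int) -> float:
        entry = lookup.get((sample, chrom))
        if entry is None:
            return default_copy_number
        starts, ends, cns = entry
        pos0 = pos1 - 1
        i = np.searchsorted(starts, pos0, side="right") - 1
        if i >= 0 and pos0 < ends[i]:
            return float(cns[i])
        return default_copy_number

    neutral = np.array(
        [
            abs(copy_number_at(s, c, p) - 2.0) <= margin
            for s, c, p in zip(df["sample"], df["chrom"], df["pos"])
        ]
    )
    df = df.copy()
    df["_neutral"] = neutral
    ok_per_variant = df.groupby(["case", "chrom", "pos", "ref", "alt"])["_neutral"].transform("all")
    out = df.loc[ok_per_variant].drop(columns="_neutral").reset_index(drop=True)
    return out


def apply_detection_limit(vaf_value: float, lod: float = DETECTION_LIMIT) -> bool:
    """Presence call at the limit of detection: present iff VAF >= lod."""
    if not 0.0 <= vaf_value <= 1.0:
        raise ValueError("VAF must lie in [0, 1]")
    return vaf_value >= lod
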