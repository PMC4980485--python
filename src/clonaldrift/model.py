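"""Model/results interface tying the pipeline stages together.

:class:`ClonalRemodeling` is built from the data of one case — per-variant
read counts for all baseline and surgical samples, optional copy-number
segments, optional known purities — and :meth:`ClonalRemodeling.fit` runs
the full inference: somatic LLR filtering, copy-number-neutral masking,
joint binomial-mixture clustering of VAFs, purity estimation from the
founder cluster, sum-rule tree enumeration, collision detection, exclusive
clone fractions, the clonal instability index and the four-way pattern
classification.  The returned :class:`ClonalRemodelingResults` carries the
estimates with a ``summary()`` table, temporal variant calls on demand,
and a clonality scatter plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import remodel as _remodel
from . import tree as _tree
from . import vario as _vario
from .purity import PurityEstimate, estimate_purity
from .temporal import TemporalCall, classify_temporal

__all__ = ["CaseBundle", "ClonalRemodeling", "ClonalRemodelingResults"]


@dataclass
class CaseBundle:
    """All inputs for one patient: variants, segments, clinical, purity."""

    case_id: str
    variants: pd.DataFrame
    segments: pd.DataFrame | None = None
    clinical: _remodel.ClinicalRecord | None = None
    purity: dict | None = None  # sample -> known purity, optional
    truth: object | None = None  # planted TruthSet for simulated cases

    @classmethod
    def from_directory(cls, directory: str | Path) -> "CaseBundle":
        """Load a fixture directory (variants.tsv, segments.bed, truth.json)."""
        directory = Path(directory)
        variants = _vario.read_variant_table(directory / "variants.tsv")
        case_id = str(variants["case"].iloc[0])
        segments = None
        if (directory / "segments.bed").exists():
            segments = _vario.read_segments(directory / "segments.bed")
        truth = None
        if (directory / "truth.json").exists():
            from .simdata import read_truth

            truth = read_truth(directory / "truth.json")
        return cls(case_id=case_id, variants=variants, segments=segments, truth=truth)

    @property
    def timepoints(self) -> dict:
        return dict(
            self.variants.drop_duplicates("sample")[["sample", "timepoint"]].itertuples(
                index=False, name=None
            )
        )


class ClonalRemodeling:
    """Clonal-architecture model for one case across two time points.

    Parameters
    ----------
    case
        A :class:`CaseBundle` (or build one via :meth:`from_dataframe`).
    somatic_filter
        Apply the binomial LLR somatic filter before clustering (needs
        matched-normal counts).
    error_rate, min_llr, min_depth
        Somatic filter settings.
    cn_margin
        Copy-number-neutral margin |CN - 2| <= margin.
    lod
        VAF limit of detection (~1%).
    alpha, specific_vaf, min_rna_reads
        Temporal classification settings.
    stability_cutoff
        Stable/dynamic boundary on the instability index.
    """

    def __init__(
        self,
        case: CaseBundle,
        *,
        somatic_filter: bool = True,
        error_rate: float = 0.001,
        min_llr: float = 3.0,
        min_depth: int = 10,
        cn_margin: float = 0.25,
        lod: float = _vario.DETECTION_LIMIT,
        alpha: float = 0.05,
        specific_vaf: float = 0.10,
        min_rna_reads: int = 1,
        stability_cutoff: float = _remodel.STABILITY_CUTOFF,
    ) -> None:
        self.case = case
        self.somatic_filter = somatic_filter
        self.error_rate = error_rate
        self.min_llr = min_llr
        self.min_depth = min_depth
        self.cn_margin = cn_margin
        self.lod = lod
        self.alpha = alpha
        self.specific_vaf = specific_vaf
        self.min_rna_reads = min_rna_reads
        self.stability_cutoff = stability_cutoff

    @classmethod
    def from_dataframe(
        cls,
        variants: pd.DataFrame,
        *,
        segments: pd.DataFrame | None = None,
        purity: dict | None = None,
        **kwargs,
    ) -> "ClonalRemodeling":
        case_id = str(variants["case"].iloc[0])
        bundle = CaseBundle(
            case_id=case_id, variants=variants, segments=segments, purity=purity
        )
        return cls(bundle, **kwargs)

    @classmethod
    def from_directory(cls, directory: str | Path, **kwargs) -> "ClonalRemodeling":
        return cls(CaseBundle.from_directory(directory), **kwargs)

    # ------------------------------------------------------------------
    def fit(
        self,
        *,
        k_max: int = 10,
        n_restarts: int = 10,
        min_members: int = 5,
        seed: int | None = 0,
    ) -> "ClonalRemodelingResults":
        """Run the full inference; deterministic under a fixed seed."""
        case = self.case
        notes: list[str] = []

        df = case.variants
        if self.somatic_filter and (df["normal_ref_reads"] + df["normal_var_reads"]).gt(0).any():
            df = _vario.apply_somatic_filter(
                df, self.error_rate, min_llr=self.min_llr, min_depth=self.min_depth
            )
            if len(df) == 0:
                raise ValueError("no variants survive the somatic filter")
        neutral = _vario.cn_neutral_mask(df, case.segments, self.cn_margin)

        timepoints = case.timepoints
        try:
            clusters = _cluster.cluster_vafs(
                neutral, k_max=k_max, seed=seed,
                n_restarts=n_restarts, min_members=min_members,
            )
        except _cluster.ClusteringError as err:
            notes.append(str(err))
            return ClonalRemodelingResults(
                model=self, variants=df, neutral=neutral, clusters=None,
                purity={}, prevalence=None, trees=[], collision=None,
                fractions_baseline={}, fractions_surgical={},
                instability_index=None, pattern="manual", n_clones=0,
                notes=tuple(notes),
            )
        if clusters.low_separation:
            notes.append("clusters with <0.05 VAF separation in all samples")

        # purity: supplied wins; otherwise founder-cluster estimate per sample
        purity: dict[str, PurityEstimate] = {}
        for sample_id in clusters.sample_ids:
            if case.purity and sample_id in case.purity:
                purity[sample_id] = PurityEstimate(
                    sample_id, float(case.purity[sample_id]), "supplied", float("nan")
                )
            else:
                purity[sample_id] = estimate_purity(
                    neutral.loc[neutral["sample"] == sample_id],
                    cluster_hint=clusters,
                    lod=self.lod,
                )
        purity_values = {s: p.purity for s, p in purity.items()}

        prev, se = _tree.prevalence_matrix(clusters, purity_values, lod=self.lod)
        prevalence = pd.DataFrame(
            prev, index=clusters.cluster_ids, columns=clusters.sample_ids
        )
        trees = _tree.enumerate_trees(prev, clusters.sample_ids, se=se)
        if not trees:
            # retry at a relaxed tolerance before treating the case as
            # unexplainable by a single tumour
            trees = _tree.enumerate_trees(
                prev, clusters.sample_ids,
                epsilon=3.0 * (_tree.EPSILON_FIXED + se),
            )
            if trees:
                notes.append("sum rule satisfied only at relaxed tolerance")
        collision = _tree.detect_collision(
            clusters, purity_values, timepoints, trees, lod=self.lod
        )

        fractions_b: dict = {}
        fractions_s: dict = {}
        n_clones = clusters.k
        if collision.is_collision:
            index: float | None = 1.0  # unrelated tumours, by definition
            pattern = "collision"
            notes.append(f"collision evidence: {collision.evidence}")
        elif not trees:
            index, pattern = None, "manual"
            notes.append("no feasible tree and no collision evidence")
        else:
            best = trees[0]
            frac = _tree.exclusive_fractions(best)
            per_core = {"baseline": [], "surgical": []}
            for s, sample_id in enumerate(best.sample_ids):
                per_core[timepoints[sample_id]].append(
                    {node: float(frac[i, s]) for i, node in enumerate(best.nodes)}
                )
            fractions_b = _remodel.timepoint_fractions(per_core["baseline"])
            fractions_s = _remodel.timepoint_fractions(per_core["surgical"])
            index = _remodel.instability_index(fractions_b, fractions_s, lod=self.lod)
            # clones of the architecture = those detected at either time point
            n_clones = len(
                {
                    c
                    for c in set(fractions_b) | set(fractions_s)
                    if max(fractions_b.get(c, 0.0), fractions_s.get(c, 0.0)) >= self.lod
                }
            )
            pattern = _remodel.classify_pattern(
                False, n_clones, index, cutoff=self.stability_cutoff
            )

        return ClonalRemodelingResults(
            model=self, variants=df, neutral=neutral, clusters=clusters,
            purity=purity, prevalence=prevalence, trees=trees,
            collision=collision, fractions_baseline=fractions_b,
            fractions_surgical=fractions_s, instability_index=index,
            pattern=pattern, n_clones=n_clones, notes=tuple(notes),
        )


@dataclass
class ClonalRemodelingResults:
    """Fitted clonal architecture and remodelling statistics for one case."""

    model: ClonalRemodeling
    variants: pd.DataFrame
    neutral: pd.DataFrame
    clusters: _cluster.ClusterSet | None
    purity: dict
    prevalence: pd.DataFrame | None
    trees: list
    collision: _tree.CollisionCall | None
    fractions_baseline: dict
    fractions_surgical: dict
    instability_index: float | None
    pattern: str
    n_clones: int
    notes: tuple = ()

    @property
    def case_id(self) -> str:
        return self.model.case.case_id

    @property
    def tree(self):
        """Most parsimonious feasible clone tree (None for collisions)."""
        return self.trees[0] if self.trees else None

    @property
    def remodel_result(self) -> _remodel.RemodelResult:
        return _remodel.RemodelResult(
            case_id=self.case_id,
            instability_index=self.instability_index,
            pattern=self.pattern,
            n_clones=self.n_clones,
            fractions_baseline=self.fractions_baseline,
            fractions_surgical=self.fractions_surgical,
            notes=self.notes,
        )

    # ------------------------------------------------------------------
    def temporal_calls(self) -> list[TemporalCall]:
        """Per-variant temporal classification (Fisher on corrected counts)."""
        m = self.model
        timepoints = m.case.timepoints
        purity_values = {s: p.purity for s, p in self.purity.items()}
        calls = []
        for key, grp in self.variants.groupby(["chrom", "pos", "ref", "alt"]):
            obs = {"baseline": [], "surgical": []}
            for row in grp.itertuples(index=False):
                tp = timepoints[row.sample]
                if tp in obs:
                    obs[tp].append(
                        (row.sample, row.dna_ref_reads, row.dna_var_reads, row.rna_var_reads)
                    )
            if not obs["baseline"] or not obs["surgical"]:
                continue
            calls.append(
                classify_temporal(
                    obs["baseline"], obs["surgical"], purity_values,
                    alpha=m.alpha, specific_vaf=m.specific_vaf,
                    min_rna_reads=m.min_rna_reads, variant_key=key,
                )
            )
        return calls

    def summary(self) -> str:
        """Human-readable fit report."""
        from statsmodels.iolib.table import SimpleTable

        idx = "—" if self.instability_index is None else f"{self.instability_index:.3f}"
        header = [
            ["case", self.case_id],
            ["variants (somatic / CN-neutral)", f"{self.variants[['chrom','pos','ref','alt']].drop_duplicates().shape[0]} / {self.neutral[['chrom','pos','ref','alt']].drop_duplicates().shape[0]}"],
            ["clones (K)", str(self.n_clones)],
            ["pattern", self.pattern],
            ["clonal instability index", idx],
            ["collision evidence", self.collision.evidence if self.collision else "n/a"],
        ]
        parts = [
            str(SimpleTable(header, title="Clonal remodelling fit"))
        ]
        if self.clusters is not None:
            rows = []
            for k in self.clusters.cluster_ids:
                rows.append(
                    [str(k), str(int(self.clusters.counts[k]))]
                    + [f"{v:.3f}" for v in self.clusters.median_vaf[k]]
                    + [
                        f"{self.fractions_baseline.get(k, 0.0):.3f}",
                        f"{self.fractions_surgical.get(k, 0.0):.3f}",
                    ]
                )
            headers = (
                ["cluster", "n"]
                + [f"medVAF[{s}]" for s in self.clusters.sample_ids]
                + ["frac BL", "frac SURG"]
            )
            parts.append(str(SimpleTable(rows, headers=headers, title="Subclonal clusters")))
        if self.purity:
            rows = [
                [s, f"{p.purity:.3f}", p.method]
                for s, p in sorted(self.purity.items())
            ]
            parts.append(
                str(SimpleTable(rows, headers=["sample", "purity", "method"], title="Purity"))
            )
        if self.notes:
            parts.append("Notes: " + "; ".join(self.notes))
        return "\n\n".join(parts)

    def plot_clonality(self, baseline_sample=None, surgical_sample=None, ax=None):
        """Baseline-vs-surgical VAF scatter coloured by cluster."""
        import matplotlib.pyplot as plt

        if self.clusters is None:
            raise ValueError("no clustering available for this case")
        timepoints = self.model.case.timepoints
        samples = self.clusters.sample_ids
        if baseline_sample is None:
            baseline_sample = next(s for s in samples if timepoints[s] == "baseline")
        if surgical_sample is None:
            surgical_sample = next(s for s in samples if timepoints[s] == "surgical")
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        piv = self.neutral.assign(
            vaf=_vario.vaf(self.neutral["dna_var_reads"], self.neutral["dna_ref_reads"])
        ).pivot_table(index=["chrom", "pos", "ref", "alt"], columns="sample", values="vaf")
        piv = piv.loc[self.clusters.variant_keys]
        ax.scatter(
            piv[baseline_sample], piv[surgical_sample],
            c=self.clusters.assignments, cmap="tab10", s=12, alpha=0.8,
        )
        ax.set_xlabel(f"VAF {baseline_sample} (baseline)")
        ax.set_ylabel(f"VAF {surgical_sample} (surgical)")
        ax.set_title(f"{self.case_id}: pattern {self.pattern}")
        return ax
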