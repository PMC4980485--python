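"""Synthetic two-time-point tumour sequencing data with a known truth set.

The generator emulates the statistical structure the downstream analysis
assumes: a rooted clonal phylogeny per tumour, per-sample exclusive clone
fractions that sum to 1 over tumour cells, copy-number-neutral heterozygous
variants whose expected VAF is ``purity x prevalence / 2``, binomial read
sampling at Poisson-distributed depth, RNA support reads at lower depth, a
matched normal carrying only sequencing error, and tumour purities spanning
the 12-100% range seen in practice.

Five scenarios control the pre -> post composition shift:

* ``stable`` — per-clone shifts bounded by 0.05.
* ``dynamic`` — the dominant subclone collapses and a rare one takes over
  (at least one shift >= 0.5).
* ``emergent`` — a clone below the ~1% VAF detection limit at baseline
  becomes dominant at surgery.
* ``collision`` — two disjoint clonal trees sharing no variants, one per
  time point: two independent tumours at one site.
* ``monoclonal`` — a single founder, unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import remodel
from .vario import VARIANT_COLUMNS, write_segments, write_variant_table

__all__ = [
    "SCENARIOS",
    "SimulationConfig",
    "TruthSet",
    "simulate_phylogeny",
    "simulate_reads",
    "simulate_case",
    "write_fixture",
    "read_truth",
]

SCENARIOS = ("stable", "dynamic", "emergent", "collision", "monoclonal")

PURITY_RANGE = (0.12, 1.0)  # observed range of tumour purities
STABLE_MAX_SHIFT = 0.05
DYNAMIC_MIN_SHIFT = 0.4
ERROR_RATE = 0.001  # per-allele substitution error, typical short-read value

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults emulate the study conditions."""

    n_clones: int = 3
    scenario: str = "stable"
    purity_by_sample: dict | float | None = None  # None: drawn in [0.12, 1]
    depth_mean: float = 80.0  # combined discovery+validation coverage scale
    n_variants_per_clone: int = 50
    n_cores_per_timepoint: int = 1
    rna_depth_mean: float = 30.0
    seed: int | None = 0
    error_rate: float = ERROR_RATE
    core_jitter: float | None = None  # Dirichlet concentration; None = off
    case_id: str = "SIM01"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.scenario == "monoclonal":
            self.n_clones = 1
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")


@dataclass
class TruthSet:
    """Planted ground truth for one simulated case."""

    case_id: str
    scenario: str
    tree_parent: dict  # clone -> parent clone (roots map to None)
    exclusive_fraction: pd.DataFrame  # clones x samples, sums to 1 per sample
    variant_assignment: dict = field(default_factory=dict)  # variant id -> clone
    true_purity: dict = field(default_factory=dict)  # sample -> purity
    timepoints: dict = field(default_factory=dict)  # sample -> timepoint

    @property
    def clones(self) -> list[int]:
        return list(self.exclusive_fraction.index)

    @property
    def samples(self) -> list[str]:
        return list(self.exclusive_fraction.columns)

    def prevalence(self, clone: int, sample: str) -> float:
        """Cellular prevalence: summed exclusive fractions of the subtree."""
        total = self.exclusive_fraction.loc[clone, sample]
        for child in (c for c, p in self.tree_parent.items() if p == clone):
            total += self.prevalence(child, sample)
        return float(total)

    def timepoint_fractions(self, timepoint: str) -> dict:
        cores = [s for s in self.samples if self.timepoints[s] == timepoint]
        per_core = [self.exclusive_fraction[s].to_dict() for s in cores]
        return remodel.timepoint_fractions(per_core)

    @property
    def planted_index(self) -> float:
        """Instability index implied by the planted fractions.

        Collision cases are by construction completely unrelated tumours
        and take the index's defining value of 1.
        """
        if self.scenario == "collision":
            return 1.0
        return remodel.instability_index(
            self.timepoint_fractions("baseline"),
            self.timepoint_fractions("surgical"),
        )

    @property
    def planted_pattern(self) -> str:
        if self.scenario == "collision":
            return "collision"
        n_detected = len(
            {
                c
                for c, f in self.timepoint_fractions("baseline").items()
                if f >= 0.01
            }
            | {
                c
                for c, f in self.timepoint_fractions("surgical").items()
                if f >= 0.01
            }
        )
        return remodel.classify_pattern(False, n_detected, self.planted_index)

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "scenario": self.scenario,
            "tree_parent": {str(c): p for c, p in self.tree_parent.items()},
            "exclusive_fraction": {
                s: {str(c): float(self.exclusive_fraction.loc[c, s]) for c in self.clones}
                for s in self.samples
            },
            "variant_assignment": {v: int(c) for v, c in self.variant_assignment.items()},
            "true_purity": {s: float(p) for s, p in self.true_purity.items()},
            "timepoints": dict(self.timepoints),
            "planted_index": self.planted_index,
            "planted_pattern": self.planted_pattern,
        }


def _random_tree(n: int, rng, offset: int = 0) -> dict:
    parent = {offset: None}
    for i in range(1, n):
        parent[offset + i] = offset + int(rng.integers(0, i))
    return parent


def _dirichlet(n: int, rng) -> np.ndarray:
    return rng.dirichlet(np.ones(n))


def _scenario_fractions(n: int, scenario: str, rng) -> tuple[np.ndarray, np.ndarray]:
    """Time-point-level exclusive fractions (pre, post) over n clones."""
    if scenario == "monoclonal":
        return np.ones(1), np.ones(1)
    pre = _dirichlet(n, rng)
    if scenario == "stable":
        delta = rng.uniform(-STABLE_MAX_SHIFT, STABLE_MAX_SHIFT, n)
        delta -= delta.mean()
        post = np.clip(pre + delta, 0.0, None)
        post /= post.sum()
        return pre, post
    if scenario == "dynamic":
        # dominant subclone collapses, a rare clone takes over
        dom, rare = int(np.argmax(pre)), int(np.argmin(pre))
        if dom == rare:
            rare = (dom + 1) % n
        pre[dom] = rng.uniform(0.6, 0.9)
        pre[rare] = rng.uniform(0.0, 0.03)
        others = [i for i in range(n) if i not in (dom, rare)]
        if others:
            rest = _dirichlet(len(others), rng) * (1.0 - pre[dom] - pre[rare])
            pre[others] = rest
        else:
            pre /= pre.sum()
        post = pre.copy()
        post[dom], post[rare] = pre[rare], pre[dom]
        return pre, post
    if scenario == "emergent":
        emergent = n - 1  # a leaf by construction order
        pre[emergent] = 0.005
        others = [i for i in range(n) if i != emergent]
        pre[others] = _dirichlet(len(others), rng) * (1.0 - pre[emergent])
        post = np.zeros(n)
        post[emergent] = rng.uniform(0.5, 0.8)
        post[others] = _dirichlet(len(others), rng) * (1.0 - post[emergent])
        return pre, post
    raise ValueError(f"unknown scenario {scenario!r}")


#: Spaced exclusive fractions for up to four children of a star tree:
#: adjacent values differ by >= 0.3 of prevalence in at least one time
#: point, i.e. >= 0.1 expected VAF at purity >= 0.7.
_LADDER = np.array([0.65, 0.30, 0.0, 0.0])


def _ladder_composition(n: int, scenario: str, rng) -> tuple[dict, np.ndarray, np.ndarray]:
    """Star-tree composition with guaranteed clone separation."""
    if n > len(_LADDER) + 1:
        raise ValueError(f"ladder fallback supports at most {len(_LADDER) + 1} clones")
    parent = {0: None} | {i: 0 for i in range(1, n)}
    children_pre = _LADDER[: n - 1]
    if scenario == "stable":
        # chain topology: spaced prevalences avoid zero-prevalence clones
        chain_prev = {2: [1.0, 0.65], 3: [1.0, 0.65, 0.30], 4: [1.0, 0.70, 0.40, 0.10]}
        prev = np.array(chain_prev[n])
        parent = {0: None} | {i: i - 1 for i in range(1, n)}
        excl = np.append(prev[:-1] - prev[1:], prev[-1])
        delta = rng.uniform(0.0, STABLE_MAX_SHIFT / 2, n)
        post = np.clip(excl + delta - delta.mean(), 0.01, None)
        post /= post.sum()
        return parent, excl, post
    elif scenario == "dynamic":
        # hand-spaced post compositions: every clone pair keeps >= 0.3
        # prevalence separation in one time point and the dominant
        # subclone shifts by >= 0.4
        post_by_n = {
            2: [0.05],
            3: [0.05, 0.90],
            4: [0.0, 0.30, 0.65],
            5: [0.0, 0.05, 0.30, 0.60],
        }
        children_post = np.array(post_by_n[n])
    elif scenario == "collision":
        half = (n + 1) // 2
        parent = {0: None} | {i: 0 for i in range(1, half)}
        parent |= {half: None} | {i: half for i in range(half + 1, n)}
        pre = np.zeros(n)
        post = np.zeros(n)
        pre[:half] = np.concatenate([[1.0 - _LADDER[: half - 1].sum()], _LADDER[: half - 1]])
        post[half:] = np.concatenate([[1.0 - _LADDER[: n - half - 1].sum()], _LADDER[: n - half - 1]])
        return parent, pre, post
    else:
        raise ValueError(f"no ladder fallback for scenario {scenario!r}")
    pre = np.concatenate([[1.0 - children_pre.sum()], children_pre])
    post = np.concatenate([[1.0 - children_post.sum()], children_post])
    return parent, pre, post


def _prevalences(parent: dict, fractions: pd.DataFrame) -> pd.DataFrame:
    prev = fractions.copy()
    # accumulate children into parents, deepest first
    def depth_of(c):
        d, p = 0, parent[c]
        while p is not None:
            d, p = d + 1, parent[p]
        return d

    for clone in sorted(parent, key=depth_of, reverse=True):
        p = parent[clone]
        if p is not None:
            prev.loc[p] += prev.loc[clone]
    return prev


def _vaf_separation_ok(
    parent: dict, fractions: pd.DataFrame, purity: dict, min_sep: float
) -> bool:
    prev = _prevalences(parent, fractions)
    p = np.array([purity[s] for s in fractions.columns])
    vafs = prev.to_numpy() * p[None, :] / 2.0
    n = vafs.shape[0]
    for a in range(n):
        for b in range(a + 1, n):
            if np.abs(vafs[a] - vafs[b]).max() < min_sep:
                return False
    return True


def simulate_phylogeny(
    n_clones: int,
    scenario: str,
    seed: int | None = None,
    *,
    n_cores_per_timepoint: int = 1,
    purity: dict | float | None = None,
    core_jitter: float | None = None,
    min_vaf_separation: float | None = None,
    case_id: str = "SIM01",
    rng: np.random.Generator | None = None,
    max_tries: int = 5000,
) -> TruthSet:
    """Plant a clonal phylogeny with per-sample exclusive fractions.

    Samples are named ``B1..Bm`` (baseline cores) and ``S1..Sm`` (surgical
    cores).  ``purity`` may be a scalar, a per-sample mapping, or None to
    draw uniformly from the 12-100% range.  ``core_jitter`` is a Dirichlet
    concentration perturbing fractions between concurrent cores (spatial
    heterogeneity); ``min_vaf_separation`` re-draws compositions until all
    clone pairs differ by at least that much expected VAF in some sample.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if scenario == "monoclonal":
        n_clones = 1
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)

    m = n_cores_per_timepoint
    samples = [f"B{i + 1}" for i in range(m)] + [f"S{i + 1}" for i in range(m)]
    timepoints = {s: ("baseline" if s.startswith("B") else "surgical") for s in samples}

    if isinstance(purity, dict):
        true_purity = {s: float(purity[s]) for s in samples}
    elif purity is not None:
        true_purity = {s: float(purity) for s in samples}
    else:
        true_purity = {s: float(rng.uniform(*PURITY_RANGE)) for s in samples}

    for attempt in range(max_tries):
        if scenario == "collision":
            if n_clones < 2:
                raise ValueError("collision needs at least 2 clones (one per tumour)")
            n_a = (n_clones + 1) // 2
            n_b = n_clones - n_a
            parent = _random_tree(n_a, rng) | _random_tree(max(n_b, 1), rng, offset=n_a)
            pre = np.concatenate([_dirichlet(n_a, rng), np.zeros(n_b)])
            post = np.concatenate([np.zeros(n_a), _dirichlet(max(n_b, 1), rng)])
        else:
            parent = _random_tree(n_clones, rng)
            pre, post = _scenario_fractions(n_clones, scenario, rng)

        frac = {}
        for s in samples:
            base = pre if timepoints[s] == "baseline" else post
            if core_jitter is not None and base.sum() > 0:
                support = base > 1e-12
                jittered = np.zeros_like(base)
                jittered[support] = rng.dirichlet(core_jitter * base[support] + 1e-3)
                frac[s] = jittered
            else:
                frac[s] = base
        fractions = pd.DataFrame(frac, index=sorted(parent))

        if min_vaf_separation is None or _vaf_separation_ok(
            parent, fractions, true_purity, min_vaf_separation
        ):
            break
    else:
        # random draws cannot always realise the separation (K clusters in
        # a VAF range of width purity/2); fall back to a star tree with
        # deterministically spaced child fractions
        parent, pre, post = _ladder_composition(n_clones, scenario, rng)
        frac = {
            s: (pre if timepoints[s] == "baseline" else post) for s in samples
        }
        fractions = pd.DataFrame(frac, index=sorted(parent))
        if not _vaf_separation_ok(parent, fractions, true_purity, min_vaf_separation):
            raise RuntimeError(
                f"VAF separation >= {min_vaf_separation} unattainable for "
                f"{n_clones} clones at purity {min(true_purity.values()):.2f}"
            )

    return TruthSet(
        case_id=case_id,
        scenario=scenario,
        tree_parent=parent,
        exclusive_fraction=fractions,
        true_purity=true_purity,
        timepoints=timepoints,
    )


def simulate_reads(
    truth: TruthSet,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-variant read counts for every sample of a planted case.

    For variant v of clone c in sample s the expected VAF is
    ``purity_s x prevalence(c, s) / 2`` (copy-number-neutral heterozygous
    model); DNA depth is Poisson(depth_mean) floored at 1, variant reads
    binomial, with a symmetric per-allele error rate.  RNA counts use
    ``rna_depth_mean`` (unfloored: 0 depth = untranscribed locus); the
    matched normal carries error-rate reads only.  Deterministic for a
    fixed config seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    e = config.error_rate
    prev = _prevalences(truth.tree_parent, truth.exclusive_fraction)

    rows = []
    pos = 10_000
    for clone in truth.clones:
        for j in range(config.n_variants_per_clone):
            ref_base, alt_base = rng.choice(4, size=2, replace=False)
            vid = f"1:{pos}:{_BASES[ref_base]}:{_BASES[alt_base]}"
            truth.variant_assignment[vid] = int(clone)
            normal_depth = max(1, int(rng.poisson(config.depth_mean)))
            normal_var = int(rng.binomial(normal_depth, e))
            for s in truth.samples:
                vaf_true = truth.true_purity[s] * prev.loc[clone, s] / 2.0
                p_read = vaf_true * (1 - e) + (1 - vaf_true) * e
                depth = max(1, int(rng.poisson(config.depth_mean)))
                var_reads = int(rng.binomial(depth, p_read))
                if config.rna_depth_mean > 0:
                    rna_depth = int(rng.poisson(config.rna_depth_mean))
                    rna_var = int(rng.binomial(rna_depth, p_read)) if rna_depth else 0
                    rna_ref = rna_depth - rna_var
                else:
                    rna_ref = rna_var = -1
                rows.append(
                    (
                        truth.case_id,
                        s,
                        truth.timepoints[s],
                        "1",
                        pos,
                        str(_BASES[ref_base]),
                        str(_BASES[alt_base]),
                        depth - var_reads,
                        var_reads,
                        normal_depth - normal_var,
                        normal_var,
                        rna_ref,
                        rna_var,
                        "",
                        "",
                        1,
                    )
                )
            pos += 1000
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def simulate_case(config: SimulationConfig, **phylo_kwargs) -> tuple[TruthSet, pd.DataFrame]:
    """Convenience: phylogeny + reads from one config (single seed)."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_phylogeny(
        config.n_clones,
        config.scenario,
        n_cores_per_timepoint=config.n_cores_per_timepoint,
        purity=config.purity_by_sample,
        core_jitter=config.core_jitter,
        case_id=config.case_id,
        rng=rng,
        **phylo_kwargs,
    )
    reads = simulate_reads(truth, config, rng=rng)
    return truth, reads


def write_fixture(records: pd.DataFrame, truth: TruthSet, directory: str | Path) -> dict:
    """Write variants.tsv, segments.bed, clinical.csv and truth.json.

    The emitted files round-trip losslessly through the package readers.
    Returns the path map.
    """
    if len(records) == 0:
        raise ValueError("no records to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": directory / "variants.tsv",
        "segments": directory / "segments.bed",
        "clinical": directory / "clinical.csv",
        "truth": directory / "truth.json",
    }
    write_variant_table(records, paths["variants"])

    end = int(records["pos"].max()) + 1000
    segments = pd.DataFrame(
        {
            "chrom": "1",
            "start": 0,
            "end": end,
            "sample": list(truth.samples),
            "copy_number": 2.0,
        }
    )
    write_segments(segments, paths["segments"])

    clinical = pd.DataFrame(
        [
            {
                "case": truth.case_id,
                "age": "",
                "subtype_baseline": "",
                "subtype_surgical": "",
                "ki67_baseline": "",
                "ki67_surgical": "",
                "ki67_response": "",
                "allred_baseline": "",
                "allred_surgical": "",
                "manual_pattern": "",
            }
        ]
    )
    clinical.to_csv(paths["clinical"], index=False)

    with open(paths["truth"], "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    return paths


def read_truth(path: str | Path) -> TruthSet:
    with open(path) as fh:
        d = json.load(fh)
    clones = sorted(int(c) for c in d["tree_parent"])
    samples = list(d["exclusive_fraction"])
    frac = pd.DataFrame(
        {s: [d["exclusive_fraction"][s][str(c)] for c in clones] for s in samples},
        index=clones,
    )
    return TruthSet(
        case_id=d["case_id"],
        scenario=d["scenario"],
        tree_parent={int(c): p for c, p in d["tree_parent"].items()},
        exclusive_fraction=frac,
        variant_assignment={v: int(c) for v, c in d["variant_assignment"].items()},
        true_purity=d["true_purity"],
        timepoints=d["timepoints"],
    )
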