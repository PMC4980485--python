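"""Joint multi-sample VAF clustering into subclonal clusters.

Copy-number-neutral heterozygous variants belonging to one clone share a
single underlying allele fraction per sample, so the read counts of a case
with S samples follow an S-dimensional binomial mixture: variant i in
component k has ``var_{is} ~ Binomial(depth_{is}, theta_{ks})``.  The
mixture is fitted by expectation-maximization for K = 1..k_max with
multiple seeded restarts, K is selected by the Bayesian information
criterion, and each variant is assigned to its maximum-posterior component.
Variants with maximum posterior below 0.8 are flagged as outliers but keep
their assignment; components with fewer than ``min_members`` hard members
are dissolved and their members reassigned.

The per-sample *median VAF* of a cluster — the quantity handed to the tree
stage — is recomputed from member VAFs, not read off the fitted theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp, xlogy

from .vario import DETECTION_LIMIT, vaf

__all__ = ["ClusterSet", "ClusteringError", "cluster_vafs", "cluster_presence"]

MIN_VARIANTS = 10
OUTLIER_POSTERIOR = 0.8
SEPARATION_FLAG = 0.05


class ClusteringError(ValueError):
    """Too few variants (or otherwise unclusterable); flag the case manual."""


@dataclass
class ClusterSet:
    """Result of the mixture fit for one case.

    Attributes
    ----------
    variant_keys : list of tuple
        (chrom, pos, ref, alt) per variant, aligned with ``assignments``.
    sample_ids : list of str
    assignments : ndarray of int
        Cluster index per variant (max-posterior).
    outlier : ndarray of bool
        True where the maximum posterior is below 0.8.
    theta : ndarray (K, S)
        Fitted per-cluster per-sample success probabilities.
    median_vaf : ndarray (K, S)
        Median of member VAFs per sample (the subclone summary statistic).
    """

    variant_keys: list
    sample_ids: list
    assignments: np.ndarray
    outlier: np.ndarray
    theta: np.ndarray
    median_vaf: np.ndarray
    counts: np.ndarray
    k: int
    log_likelihood: float
    bic: float
    low_separation: bool = False
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    total_depth: np.ndarray | None = None  # (K, S) summed member depth

    @property
    def cluster_ids(self) -> list[int]:
        return list(range(self.k))

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == cluster)

    def median_vaf_for_sample(self, sample_id: str) -> dict[int, float]:
        s = self.sample_ids.index(sample_id)
        return {kk: float(self.median_vaf[kk, s]) for kk in range(self.k)}

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [key[0] for key in self.variant_keys],
                "pos": [key[1] for key in self.variant_keys],
                "ref": [key[2] for key in self.variant_keys],
                "alt": [key[3] for key in self.variant_keys],
                "cluster": self.assignments,
                "outlier": self.outlier,
            }
        )


def _log_binom_const(var, depth):
    return gammaln(depth + 1) - gammaln(var + 1) - gammaln(depth - var + 1)


def _component_loglik(var, depth, theta):
    """(n, K) log-likelihood of each variant under each component."""
    v = var[:, None, :]
    d = depth[:, None, :]
    t = theta[None, :, :]
    return (xlogy(v, t) + xlogy(d - v, 1.0 - t)).sum(axis=2)


def _em_fit(var, depth, k, rng, *, max_iter=500, tol=1e-8):
    n, S = var.shape
    # quantile-spaced initialisation on mean VAF rank + per-sample jitter
    mean_vaf = vaf(var.sum(axis=1), (depth - var).sum(axis=1))
    order = np.argsort(mean_vaf)
    groups = np.array_split(order, k)
    theta = np.empty((k, S))
    for kk, idx in enumerate(groups):
        if len(idx) == 0:
            theta[kk] = rng.uniform(0.02, 0.5, size=S)
            continue
        tot_var = var[idx].sum(axis=0)
        tot_depth = depth[idx].sum(axis=0)
        theta[kk] = (tot_var + 0.5) / (tot_depth + 1.0)
    theta = np.clip(theta + rng.normal(0.0, 0.01, size=theta.shape), 1e-4, 1 - 1e-4)
    pi = np.full(k, 1.0 / k)

    const = _log_binom_const(var, depth).sum(axis=1)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        log_comp = _component_loglik(var, depth, theta) + np.log(pi)[None, :]
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum() + const.sum())
        trace.append(ll)
        gamma = np.exp(log_comp - log_norm[:, None])
        nk = gamma.sum(axis=0)
        pi = np.maximum(nk, 1e-12) / n
        pi /= pi.sum()
        denom = gamma.T @ depth
        theta = (gamma.T @ var) / np.maximum(denom, 1e-12)
        theta = np.clip(theta, 1e-6, 1 - 1e-6)
        if ll - prev < tol * max(1.0, abs(ll)):
            break
        prev = ll
    log_comp = _component_loglik(var, depth, theta) + np.log(pi)[None, :]
    log_norm = logsumexp(log_comp, axis=1)
    ll = float(log_norm.sum() + const.sum())
    posterior = np.exp(log_comp - log_norm[:, None])
    return theta, pi, ll, posterior, np.asarray(trace)


def _case_matrices(df: pd.DataFrame):
    """Pivot a case's variant rows to (keys, sample_ids, var, depth) matrices."""
    df = df.copy()
    df["depth"] = df["dna_ref_reads"] + df["dna_var_reads"]
    var_piv = df.pivot_table(
        index=["chrom", "pos", "ref", "alt"], columns="sample",
        values="dna_var_reads", aggfunc="sum",
    )
    depth_piv = df.pivot_table(
        index=["chrom", "pos", "ref", "alt"], columns="sample",
        values="depth", aggfunc="sum",
    )
    if var_piv.isna().any().any():
        raise ClusteringError("every variant needs counts in every sample")
    keys = list(var_piv.index)
    sample_ids = list(var_piv.columns)
    return keys, sample_ids, var_piv.to_numpy(float), depth_piv.to_numpy(float)


def cluster_vafs(
    df: pd.DataFrame,
    k_max: int = 10,
    seed: int | None = 0,
    *,
    n_restarts: int = 10,
    min_members: int = 5,
) -> ClusterSet:
    """Cluster a case's copy-number-neutral variants across all its samples.

    Parameters
    ----------
    df
        Variant rows of one case in the canonical column layout; every
        variant must be observed (possibly with zero reads) in every
        sample.
    k_max, n_restarts, min_members
        Model-search breadth; see module docstring.
    seed
        Seeds initialisation jitter — a fixed seed makes the fit
        deterministic.

    Raises
    ------
    ClusteringError
        With fewer than 10 variants; such cases are reported for manual
        review rather than force-fitted.
    """
    keys, sample_ids, var, depth = _case_matrices(df)
    n, S = var.shape
    if n < MIN_VARIANTS:
        raise ClusteringError(
            f"{n} variants < {MIN_VARIANTS}; case must be reviewed manually"
        )
    rng = np.random.default_rng(seed)
    k_max = min(k_max, n // max(min_members, 1)) or 1

    best = None
    for k in range(1, k_max + 1):
        for _ in range(n_restarts if k > 1 else 1):
            theta, pi, ll, posterior, trace = _em_fit(var, depth, k, rng)
            n_params = k * S + (k - 1)
            bic = -2.0 * ll + n_params * np.log(n)
            if best is None or bic < best[0]:
                best = (bic, k, theta, pi, ll, posterior, trace)

    bic, k, theta, pi, ll, posterior, trace = best

    # dissolve under-populated clusters, reassigning members
    while k > 1:
        assignments = posterior.argmax(axis=1)
        sizes = np.bincount(assignments, minlength=k)
        if sizes.min() >= min_members:
            break
        drop = int(sizes.argmin())
        keep = [i for i in range(k) if i != drop]
        theta = theta[keep]
        pi = pi[keep]
        pi /= pi.sum()
        k -= 1
        const = _log_binom_const(var, depth).sum(axis=1)
        log_comp = _component_loglik(var, depth, theta) + np.log(pi)[None, :]
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum() + const.sum())
        bic = -2.0 * ll + (k * S + k - 1) * np.log(n)
        posterior = np.exp(log_comp - log_norm[:, None])

    assignments = posterior.argmax(axis=1)
    # tie-break identical posteriors to the lowest index (argmax already does)
    outlier = posterior.max(axis=1) < OUTLIER_POSTERIOR

    median_vaf = np.zeros((k, S))
    counts = np.zeros(k, dtype=int)
    total_depth = np.zeros((k, S))
    vafs = vaf(var, depth - var)
    for kk in range(k):
        idx = assignments == kk
        counts[kk] = int(idx.sum())
        if counts[kk]:
            median_vaf[kk] = np.median(vafs[idx], axis=0)
            total_depth[kk] = depth[idx].sum(axis=0)
        else:
            median_vaf[kk] = theta[kk]

    low_sep = False
    if k > 1:
        for a in range(k):
            for b in range(a + 1, k):
                if np.all(np.abs(theta[a] - theta[b]) < SEPARATION_FLAG):
                    low_sep = True

    return ClusterSet(
        variant_keys=keys,
        sample_ids=sample_ids,
        assignments=assignments,
        outlier=outlier,
        theta=theta,
        median_vaf=median_vaf,
        counts=counts,
        k=int(k),
        log_likelihood=ll,
        bic=float(bic),
        low_separation=low_sep,
        loglik_trace=trace,
        total_depth=total_depth,
    )


def cluster_presence(
    clusters: ClusterSet,
    cluster: int,
    sample_id: str,
    *,
    purity: float = 1.0,
    lod: float = DETECTION_LIMIT,
) -> bool:
    """Presence of a cluster in a sample: corrected median VAF >= lod."""
    s = clusters.sample_ids.index(sample_id)
    corrected = min(1.0, clusters.median_vaf[cluster, s] / purity)
    return bool(corrected >= lod)
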