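"""Clonal evolution trees over subclonal clusters.

Clusters become clones in a rooted tree whose root is the founder clone.
The tree must obey the *sum rule* in every sample: a parent's cellular
prevalence (fraction of tumour cells carrying its mutations) is at least
the sum of its children's prevalences, since each child's cells are a
subset of the parent's.  Trees are enumerated exhaustively over all parent
assignments rooted at the founder, keeping those feasible within a
tolerance ``epsilon`` (a fixed slack plus the binomial standard error of
the cluster prevalence), ordered most-parsimonious-first by total sum-rule
slack.

From a feasible tree, *exclusive clone fractions* — the fraction of tumour
cells whose most-derived clone is the given clone — are the prevalence
residuals after subtracting children, clipped at zero and normalized to
sum to 1 per sample (founder prevalence is taken as 1 after purity
correction).

Two independent tumours occupying one site (a *collision tumour*) betray
themselves either by sharing no clusters across time points or by a
prevalence pattern that no single-origin tree can explain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vario import DETECTION_LIMIT

__all__ = [
    "CloneTree",
    "CollisionCall",
    "prevalence_from_cluster",
    "prevalence_matrix",
    "enumerate_trees",
    "exclusive_fractions",
    "detect_collision",
]

EPSILON_FIXED = 0.05


@dataclass
class CloneTree:
    """A rooted clone tree with per-sample prevalences and fractions."""

    parent: dict  # node -> parent node; root maps to None
    root: int
    nodes: list
    sample_ids: list
    prevalence: np.ndarray  # (n_nodes, S)
    epsilon: np.ndarray  # per (node, sample) tolerance used
    feasible: bool = True
    slack: float = 0.0
    exclusive: np.ndarray | None = None  # (n_nodes, S), filled on demand

    def children(self, node) -> list:
        return [n for n, p in self.parent.items() if p == node]

    def to_dict(self) -> dict:
        return {
            "root": self.root,
            "parent": {str(n): (None if p is None else int(p)) for n, p in self.parent.items()},
            "samples": list(self.sample_ids),
            "prevalence": {str(n): self.prevalence[i].tolist() for i, n in enumerate(self.nodes)},
            "exclusive": None
            if self.exclusive is None
            else {str(n): self.exclusive[i].tolist() for i, n in enumerate(self.nodes)},
            "feasible": bool(self.feasible),
            "slack": float(self.slack),
        }

    def to_dot(self) -> str:
        lines = ["digraph clones {"]
        for i, n in enumerate(self.nodes):
            prev = ", ".join(f"{v:.2f}" for v in self.prevalence[i])
            lines.append(f'  c{n} [label="clone {n}\\n[{prev}]"];')
        for n, p in self.parent.items():
            if p is not None:
                lines.append(f"  c{p} -> c{n};")
        lines.append("}")
        return "\n".join(lines)


@dataclass(frozen=True)
class CollisionCall:
    is_collision: bool
    evidence: str  # "disjoint_variants" | "no_feasible_tree" | "none"
    shared_cluster_count: int


def prevalence_from_cluster(median_vaf: float, purity: float, *, lod: float = DETECTION_LIMIT) -> float:
    """Cellular prevalence of a cluster in one sample.

    Under the copy-number-neutral heterozygous model prevalence is twice
    the purity-corrected median VAF, capped at 1.  Clusters below the
    detection limit get prevalence 0 rather than their noisy raw estimate.
    """
    corrected = min(1.0, median_vaf / purity)
    if corrected < lod:
        return 0.0
    return min(1.0, 2.0 * corrected)


def prevalence_matrix(clusters, purity: dict, *, lod: float = DETECTION_LIMIT):
    """(K, S) prevalences and their binomial standard errors from a fit.

    ``purity`` maps sample_id -> purity.  The standard error of the
    prevalence is propagated from the binomial error of the cluster mean
    VAF: se = 2/p * sqrt(v(1-v) / total member depth).
    """
    K, S = clusters.median_vaf.shape
    prev = np.zeros((K, S))
    se = np.zeros((K, S))
    for s, sid in enumerate(clusters.sample_ids):
        p = purity[sid]
        for k in range(K):
            v = clusters.median_vaf[k, s]
            prev[k, s] = prevalence_from_cluster(v, p, lod=lod)
            if clusters.total_depth is not None:
                d = max(float(clusters.total_depth[k, s]), 1.0)
            else:
                d = max(int(clusters.counts[k]), 1) * 100.0
            se[k, s] = 2.0 / p * np.sqrt(max(v * (1 - v), 1e-4) / d)
    return prev, se


def _founder_candidates(prev: np.ndarray, eps: np.ndarray) -> list[int]:
    """Nodes maximal in every sample, within the sum-rule tolerance.

    Candidates are ordered by total prevalence, highest first; allowing
    near-ties up to eps keeps finite-depth noise from rejecting the true
    founder.
    """
    maxima = prev.max(axis=0)
    dominant = np.all(prev >= maxima[None, :] - eps, axis=1)
    idx = np.flatnonzero(dominant)
    return sorted((int(i) for i in idx), key=lambda i: -prev[i].sum())


def enumerate_trees(
    prev: np.ndarray,
    sample_ids: list,
    *,
    epsilon: float | np.ndarray | None = None,
    se: np.ndarray | None = None,
    nodes: list | None = None,
    max_nodes: int = 10,
) -> list[CloneTree]:
    """Enumerate all sum-rule-feasible clone trees rooted at the founder.

    Parameters
    ----------
    prev : (n, S) array
        Cellular prevalence of each cluster in each sample.
    epsilon
        Per-(node, sample) slack tolerated in the sum rule.  Default is
        0.05 plus one binomial standard error of the cluster prevalence
        (``se``) when given.
    max_nodes
        Guard for the exhaustive search (n^(n-1) candidate parent maps).

    Returns feasible trees ordered by total slack, most parsimonious
    first.  An empty list means no single-origin tree explains the data —
    the signature evaluated by :func:`detect_collision`.
    """
    prev = np.asarray(prev, dtype=float)
    n, S = prev.shape
    if nodes is None:
        nodes = list(range(n))
    if n > max_nodes:
        raise ValueError(f"{n} clusters exceed the exhaustive bound of {max_nodes}")
    if epsilon is None:
        eps = np.full((n, S), EPSILON_FIXED)
        if se is not None:
            eps = eps + np.asarray(se, dtype=float)
    else:
        eps = np.broadcast_to(np.asarray(epsilon, dtype=float), (n, S)).copy()

    roots = _founder_candidates(prev, eps)
    if not roots:
        return []
    if n == 1:
        return [
            CloneTree(
                parent={nodes[0]: None}, root=nodes[0], nodes=list(nodes),
                sample_ids=list(sample_ids), prevalence=prev, epsilon=eps,
            )
        ]

    found: list[tuple[float, int, dict]] = []
    for root in roots:
        others = [i for i in range(n) if i != root]
        child_sum = np.zeros((n, S))
        parents: dict = {}

        def violates(i: int) -> bool:
            return bool(np.any(child_sum[i] > prev[i] + eps[i]))

        def assign(pos: int) -> None:
            if pos == len(others):
                # reject parent maps with cycles (no path to root)
                for start in others:
                    seen = set()
                    node = start
                    while node != root:
                        if node in seen:
                            return
                        seen.add(node)
                        node = parents[node]
                slack = float(np.maximum(child_sum - prev, 0.0).sum())
                found.append((slack, root, dict(parents)))
                return
            child = others[pos]
            for cand in range(n):
                if cand == child:
                    continue
                parents[child] = cand
                child_sum[cand] += prev[child]
                if not violates(cand):
                    assign(pos + 1)
                child_sum[cand] -= prev[child]
            parents.pop(child, None)

        assign(0)

    def canonical(entry):
        # label-free tie-break: order equal-slack trees by the multiset of
        # (child, parent) prevalence profiles so that cluster relabelling
        # cannot change which tree ranks first
        slack, root, pmap = entry
        edges = sorted((tuple(prev[c]), tuple(prev[p])) for c, p in pmap.items())
        return (slack, tuple(prev[root]), edges)

    found.sort(key=canonical)

    trees = []
    for slack, root, pmap in found:
        parent = {nodes[root]: None}
        for c, p in pmap.items():
            parent[nodes[c]] = nodes[p]
        trees.append(
            CloneTree(
                parent=parent, root=nodes[root], nodes=list(nodes),
                sample_ids=list(sample_ids), prevalence=prev, epsilon=eps,
                feasible=True, slack=slack,
            )
        )
    return trees


def exclusive_fractions(tree: CloneTree, sample_id=None) -> np.ndarray:
    """Per-clone exclusive fractions for one sample (or all samples).

    The founder's prevalence is taken as 1 (the whole tumour-cell
    population, after purity correction); each node's raw fraction is its
    prevalence minus the sum of its children's, clipped at zero; the
    vector is normalized to sum to 1.
    """
    idx = {n: i for i, n in enumerate(tree.nodes)}
    prev = tree.prevalence.copy()
    prev[idx[tree.root]] = 1.0
    child_sum = np.zeros_like(prev)
    for node, parent in tree.parent.items():
        if parent is not None:
            child_sum[idx[parent]] += prev[idx[node]]
    raw = np.clip(prev - child_sum, 0.0, None)
    totals = raw.sum(axis=0)
    frac = np.where(totals > 0, raw / np.maximum(totals, 1e-300), 0.0)
    tree.exclusive = frac
    if sample_id is None:
        return frac
    return frac[:, tree.sample_ids.index(sample_id)]


def detect_collision(
    clusters,
    purity: dict,
    timepoints: dict,
    trees: list[CloneTree] | None = None,
    *,
    lod: float = DETECTION_LIMIT,
) -> CollisionCall:
    """Decide whether a case is a collision of two independent tumours.

    Parameters
    ----------
    clusters
        Fitted :class:`~clonaldrift.cluster.ClusterSet`.
    timepoints
        sample_id -> "baseline" | "surgical".
    trees
        Output of :func:`enumerate_trees` for the case (computed here if
        omitted).

    Evidence ``disjoint_variants``: no cluster is detected (corrected
    median VAF >= lod) in both a baseline and a surgical sample — the two
    time points share no somatic variants.  Evidence ``no_feasible_tree``:
    clusters are shared but no single-origin tree satisfies the sum rule.
    """
    tps = {timepoints[s] for s in clusters.sample_ids}
    if not {"baseline", "surgical"} <= tps:
        raise ValueError("collision evaluation needs both time points")

    shared = 0
    for k in range(clusters.k):
        present_tp = set()
        for s, sid in enumerate(clusters.sample_ids):
            corrected = min(1.0, clusters.median_vaf[k, s] / purity[sid])
            if corrected >= lod:
                present_tp.add(timepoints[sid])
        if {"baseline", "surgical"} <= present_tp:
            shared += 1
    if shared == 0:
        return CollisionCall(True, "disjoint_variants", 0)

    prev, se = prevalence_matrix(clusters, purity, lod=lod)
    if trees is None:
        trees = enumerate_trees(prev, clusters.sample_ids, se=se)
    if len(trees) == 0:
        # a collision claim demands gross sum-rule violations, not noise:
        # only sustained infeasibility at a generous tolerance qualifies
        relaxed = enumerate_trees(
            prev, clusters.sample_ids, epsilon=3.0 * (EPSILON_FIXED + se)
        )
        if len(relaxed) == 0:
            return CollisionCall(True, "no_feasible_tree", shared)
    return CollisionCall(False, "none", shared)
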