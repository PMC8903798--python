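"""Alignment-free homology clustering of a family's protein sequences.

Each protein is summarized by a pooled dictionary of amino-acid k-mer
counts for k in {1,2,3}.  Pairwise Bray-Curtis distances

    d(s,t) = 1 - 2 * sum_w min(f(s,w), f(t,w)) / (sum f(s,.) + sum f(t,.))

are embedded in the plane (t-SNE, or deterministic classical scaling) and
clustered hierarchically with Ward linkage.  The dendrogram cut height is
chosen to balance two scores: E1, the mean per-genome proportion of
singleton cluster assignments, against E2, the mean per-cluster occupancy
across genomes, minimizing (E1 - E2)^2.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar


@dataclass(frozen=True)
class KmerProfile:
    counts: Mapping[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class DistanceMatrix:
    labels: List[str]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0,1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        self.values = v


@dataclass
class ClusterAssignment:
    """ORF -> cluster map plus the genome x cluster count matrix f(i,j)."""

    orf_to_cluster: Dict[str, int]
    f: pd.DataFrame  # index: accession, columns: cluster id, values: counts
    cutoff_height: float

    @property
    def K(self) -> int:
        return len(set(self.orf_to_cluster.values()))


def kmer_profile(seq: str) -> KmerProfile:
    """Pooled k-mer counts for k in {1,2,3}.

    A sequence of length L >= 3 has total 3L-3 words; shorter sequences
    contribute only the k-mers that exist.  Stop (*) and X are kept as
    ordinary symbols.
    """
    if not seq:
        raise ValueError("empty sequence has no k-mer profile")
    counts: Counter = Counter()
    for k in (1, 2, 3):
        for i in range(len(seq) - k + 1):
            counts[seq[i : i + k]] += 1
    return KmerProfile(counts)


def bray_curtis(p: KmerProfile, q: KmerProfile) -> float:
    """Bray-Curtis (intersection) distance between two k-mer profiles."""
    if not p.counts or not q.counts:
        raise ValueError("profiles must be non-empty")
    shared = sum(min(p.counts[w], q.counts[w]) for w in p.counts.keys() & q.counts.keys())
    return 1.0 - 2.0 * shared / (p.total + q.total)


def pairwise_distance_matrix(
    seqs: Mapping[str, str],
    distance: Callable[[KmerProfile, KmerProfile], float] = bray_curtis,
) -> DistanceMatrix:
    """All-pairs distances; the distance function is pluggable."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    labels = sorted(seqs)
    profiles = {lab: kmer_profile(seqs[lab]) for lab in labels}
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = distance(profiles[labels[i]], profiles[labels[j]])
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels=labels, values=D)


def _classical_scaling(D: np.ndarray, ndim: int = 2) -> np.ndarray:
    """Torgerson classical scaling: deterministic metric embedding."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:ndim]
    w_top = np.clip(w[order], 0.0, None)
    coords = V[:, order] * np.sqrt(w_top)
    # Fix sign convention so the embedding is reproducible across BLAS builds.
    for d in range(coords.shape[1]):
        col = coords[:, d]
        idx = np.argmax(np.abs(col))
        if col[idx] < 0:
            coords[:, d] = -col
    return coords


def embed_2d(
    D: DistanceMatrix,
    method: str = "tsne",
    seed: int = 0,
    perplexity: Optional[float] = None,
) -> pd.DataFrame:
    """Project a distance matrix to 2-D.

    ``tsne`` uses the stochastic neighbour embedding with a fixed seed;
    ``metric_mds`` is a deterministic classical-scaling fallback for
    reproducible tests.  Default perplexity is 30, reduced automatically
    for small inputs; an explicitly passed infeasible perplexity raises.
    """
    n = len(D.labels)
    if method == "metric_mds":
        coords = _classical_scaling(D.values)
    elif method == "tsne":
        from sklearn.manifold import TSNE

        if n < 4:
            raise ValueError(f"t-SNE needs n >= 4 points, got {n}")
        max_ok = (n - 1) / 3.0
        if perplexity is None:
            px = min(30.0, np.floor(max_ok)) or 1.0
        else:
            px = float(perplexity)
            if px >= max_ok:
                raise ValueError(
                    f"perplexity {px} too large for n={n}; try <= {np.floor(max_ok)}"
                )
        tsne = TSNE(
            n_components=2, metric="precomputed", init="random",
            random_state=seed, perplexity=px,
        )
        coords = tsne.fit_transform(D.values)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=D.labels, columns=["x", "y"])


def hierarchical_cluster(points: pd.DataFrame) -> np.ndarray:
    """Ward-linkage dendrogram (scipy linkage matrix) on planar points."""
    if len(points) < 2:
        raise ValueError("need at least 2 points")
    return linkage(points[["x", "y"]].to_numpy(), method="ward")


def cut_tree(
    dendrogram: np.ndarray,
    height: float,
    labels: List[str],
    orf_to_accession: Mapping[str, str],
) -> ClusterAssignment:
    """Flat clusters from merges at or below ``height``; tabulates f(i,j)."""
    if height < 0:
        raise ValueError("height must be >= 0")
    flat = fcluster(dendrogram, t=height, criterion="distance")
    orf_to_cluster = {lab: int(c) for lab, c in zip(labels, flat)}
    rows = [
        dict(accession=orf_to_accession[lab], cluster=c)
        for lab, c in orf_to_cluster.items()
    ]
    df = pd.DataFrame(rows)
    f = pd.crosstab(df["accession"], df["cluster"])
    return ClusterAssignment(orf_to_cluster=orf_to_cluster, f=f, cutoff_height=height)


def balance_scores(assignment: ClusterAssignment, n_genomes: Optional[int] = None) -> Tuple[float, float]:
    """(E1, E2) cutoff-selection scores.

    E1 = mean over genomes of (#clusters with exactly one member in the
    genome) / (#clusters present in the genome); genomes with no clustered
    ORFs are excluded from the E1 average.  E2 = mean over clusters of the
    mean count per genome, zeros included, with N defaulting to the number
    of genomes in the f table.
    """
    f = assignment.f.to_numpy()
    N = n_genomes if n_genomes is not None else f.shape[0]
    if N < 1 or f.shape[1] < 1:
        raise ValueError("need at least one genome and one cluster")
    present = (f > 0).sum(axis=1)
    unique = (f == 1).sum(axis=1)
    mask = present > 0
    e1 = float(np.mean(unique[mask] / present[mask])) if mask.any() else 0.0
    K = f.shape[1]
    e2 = float(f.sum() / (K * N))
    return e1, e2


def optimize_cutoff(
    dendrogram: np.ndarray,
    labels: List[str],
    orf_to_accession: Mapping[str, str],
    n_genomes: Optional[int] = None,
) -> Tuple[float, ClusterAssignment]:
    """Choose the cut height minimizing (E1 - E2)^2.

    The objective is piecewise-constant in height, so a grid over the
    dendrogram's merge heights (plus zero) is scanned first and a bounded
    scalar minimization refines within the best bracket; ties take the
    smallest height (more clusters, favouring ORFan separation).
    """

    def objective(h: float) -> float:
        a = cut_tree(dendrogram, max(h, 0.0), labels, orf_to_accession)
        e1, e2 = balance_scores(a, n_genomes=n_genomes)
        return (e1 - e2) ** 2

    heights = sorted(set([0.0] + [float(h) for h in dendrogram[:, 2]]))
    values = [objective(h) for h in heights]
    best_i = int(np.argmin(values))  # argmin takes the first (smallest) height on ties
    best_h, best_v = heights[best_i], values[best_i]
    lo = heights[best_i - 1] if best_i > 0 else 0.0
    hi = heights[best_i + 1] if best_i + 1 < len(heights) else heights[-1] * 1.05
    if hi > lo:
        res = minimize_scalar(objective, bounds=(lo, hi), method="bounded")
        if res.fun < best_v:
            best_h, best_v = float(res.x), float(res.fun)
    assignment = cut_tree(dendrogram, best_h, labels, orf_to_accession)
    return best_h, assignment


def cluster_table(assignment: ClusterAssignment, orf_to_accession: Mapping[str, str]) -> pd.DataFrame:
    rows = [
        dict(orf_id=orf, accession=orf_to_accession[orf], cluster_id=c)
        for orf, c in sorted(assignment.orf_to_cluster.items())
    ]
    return pd.DataFrame(rows, columns=["orf_id", "accession", "cluster_id"])
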