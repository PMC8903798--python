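"""Dual-edge cluster graphs: gene-order adjacency and overlap edges.

Nodes are homology clusters; a directed adjacency edge (u, v) is weighted
by the number of genomes in which a u-member is immediately followed by a
v-member in sorted genome order, and the companion overlap edge counts the
genomes in which that adjacent pair overlaps.  An overlap edge can never
outweigh its adjacency edge.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .overlap import OverlapRecord, sort_orfs
from .records import GenomeRecord

Edge = Tuple[int, int]


@dataclass
class AdjacencyGraph:
    sizes: Dict[int, int] = field(default_factory=dict)  # cluster -> ORF count
    label_counts: Dict[int, Counter] = field(default_factory=dict)
    n_genomes: Dict[int, int] = field(default_factory=dict)  # genomes containing cluster
    adj_edges: Dict[Edge, int] = field(default_factory=dict)
    ovl_edges: Dict[Edge, int] = field(default_factory=dict)
    ovl_length_sums: Dict[Edge, int] = field(default_factory=dict)

    @property
    def nodes(self) -> List[int]:
        return sorted(self.sizes)

    def mean_overlap_length(self, edge: Edge) -> float:
        return self.ovl_length_sums[edge] / self.ovl_edges[edge]

    def validate(self) -> None:
        for e, w in self.ovl_edges.items():
            if w > self.adj_edges.get(e, 0):
                raise AssertionError(f"overlap edge {e} outweighs adjacency edge")


def build_adjacency_graph(
    family: Sequence[GenomeRecord],
    orf_to_cluster: Mapping[str, int],
    overlaps: Mapping[str, Sequence[OverlapRecord]],
) -> AdjacencyGraph:
    """Accumulate adjacency/overlap edge weights over a family.

    ``overlaps`` maps accession to that genome's overlap records (the
    adjacent-pair scan).  Every consecutive pair in sorted order counts
    one adjacency; duplicated cluster pairs within a genome each count.
    """
    g = AdjacencyGraph()
    for genome in family:
        ordered = sort_orfs(genome)
        clusters = []
        for cds in ordered:
            if cds.key not in orf_to_cluster:
                raise KeyError(f"ORF {cds.key} has no cluster assignment")
            clusters.append(orf_to_cluster[cds.key])
        seen_here = set()
        for cds, c in zip(ordered, clusters):
            g.sizes[c] = g.sizes.get(c, 0) + 1
            g.label_counts.setdefault(c, Counter())[cds.product.lower()] += 1
            if c not in seen_here:
                g.n_genomes[c] = g.n_genomes.get(c, 0) + 1
                seen_here.add(c)
        ov_pairs = defaultdict(list)
        for o in overlaps.get(genome.accession, ()):
            ov_pairs[(o.cds_a, o.cds_b)].append(o)
            ov_pairs[(o.cds_b, o.cds_a)].append(o)
        for (a, ca), (b, cb) in zip(
            zip(ordered, clusters), zip(ordered[1:], clusters[1:])
        ):
            e = (ca, cb)
            g.adj_edges[e] = g.adj_edges.get(e, 0) + 1
            hits = ov_pairs.get((a.id, b.id), [])
            if hits:
                g.ovl_edges[e] = g.ovl_edges.get(e, 0) + 1
                g.ovl_length_sums[e] = g.ovl_length_sums.get(e, 0) + hits[0].overlap_length
    g.validate()
    return g


def render_dot(
    graph: AdjacencyGraph,
    min_weight: int = 5,
    edge_scale: float = 0.1,
    node_scale: float = 0.15,
    width_by: str = "count",
) -> str:
    """Serialize to Graphviz DOT, byte-stable for a fixed graph.

    Nodes are sized in proportion to cluster size; adjacency edges are
    grey, overlap edges blue, with pen widths proportional to weight (or
    to mean overlap length when ``width_by='mean_len'``).  Edges whose
    weight falls below ``min_weight`` are suppressed.
    """
    if width_by not in ("count", "mean_len"):
        raise ValueError(f"unknown width_by {width_by!r}")
    lines = ["digraph family {", "  node [shape=circle, style=filled, fillcolor=lightgrey];"]
    for node in graph.nodes:
        w = max(0.3, graph.sizes[node] * node_scale)
        lines.append(f'  n{node} [label="{node}", width={w:.2f}];')
    for (u, v), w in sorted(graph.adj_edges.items()):
        if w < min_weight:
            continue
        lines.append(
            f'  n{u} -> n{v} [color=grey, penwidth={w * edge_scale:.3f}, weight={w}];'
        )
    for (u, v), w in sorted(graph.ovl_edges.items()):
        if w < min_weight:
            continue
        pw = graph.mean_overlap_length((u, v)) if width_by == "mean_len" else w
        lines.append(
            f'  n{u} -> n{v} [color=blue, penwidth={pw * edge_scale:.3f}, weight={w}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def synteny_table(
    family: Sequence[GenomeRecord], orf_to_cluster: Mapping[str, int]
) -> pd.DataFrame:
    """Per-genome gene-order segments rescaled to [0,1] by genome length."""
    rows = []
    for genome in family:
        L = float(genome.length)
        for cds in sort_orfs(genome):
            rows.append(
                dict(
                    accession=genome.accession,
                    cluster=orf_to_cluster.get(cds.key),
                    start=cds.start / L,
                    end=cds.end / L,
                    strand=cds.strand,
                )
            )
    return pd.DataFrame(rows, columns=["accession", "cluster", "start", "end", "strand"])


def label_summary(graph: AdjacencyGraph, cluster: int) -> List[Tuple[str, int]]:
    """Product-label frequencies for one cluster, most frequent first.

    Empty labels are kept as "" and reported; nothing is relabelled.
    """
    if cluster not in graph.label_counts:
        raise KeyError(f"unknown cluster {cluster}")
    counts = graph.label_counts[cluster]
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def edge_table(graph: AdjacencyGraph) -> pd.DataFrame:
    rows = []
    for (u, v), w in sorted(graph.adj_edges.items()):
        ow = graph.ovl_edges.get((u, v), 0)
        rows.append(
            dict(u=u, v=v, adj_weight=w, ovl_weight=ow,
                 mean_overlap_len=graph.mean_overlap_length((u, v)) if ow else None)
        )
    return pd.DataFrame(rows, columns=["u", "v", "adj_weight", "ovl_weight", "mean_overlap_len"])


def plot_synteny(table: pd.DataFrame, path: str) -> None:
    """Draw stacked per-genome segment maps coloured by cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    accs = list(dict.fromkeys(table["accession"]))
    clusters = sorted(c for c in table["cluster"].dropna().unique())
    cmap = plt.get_cmap("tab20")
    fig, ax = plt.subplots(figsize=(8, 0.3 * len(accs) + 1))
    for yi, acc in enumerate(accs):
        sub = table[table["accession"] == acc]
        for _, row in sub.iterrows():
            color = cmap(clusters.index(row["cluster"]) % 20) if row["cluster"] in clusters else "grey"
            ax.plot([row["start"], row["end"]], [yi, yi], lw=6, color=color, solid_capstyle="butt")
    ax.set_yticks(range(len(accs)), accs, fontsize=6)
    ax.set_xlim(0, 1)
    ax.set_xlabel("relative genome position")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
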