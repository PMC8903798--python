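"""End-to-end orchestration: scan -> cluster -> graph -> stats.

Every output table carries a provenance header (package version, seed,
config hash) and the run writes a machine-readable manifest.  Outputs are
byte-identical across reruns with the same configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import __version__
from .genome_io import family_proteins, parse_feature_table, parse_genbank
from .graph import build_adjacency_graph, edge_table, render_dot, synteny_table
from .kmer import (
    cluster_table,
    embed_2d,
    hierarchical_cluster,
    optimize_cutoff,
    pairwise_distance_matrix,
)
from .overlap import detect_overlaps, genome_summary, overlap_table, summary_table, write_tsv
from .records import GenomeRecord
from .stats import CANDIDATE_COVARIATES, edge_covariates, fit_report, node_metrics, stepwise_select


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class RunConfig:
    genomes: List[str] = field(default_factory=list)  # GenBank or feature-table paths
    proteins: Optional[str] = None  # protein FASTA
    family: str = "family"
    mode: str = "adjacent_pairs"
    drop_plus0: bool = False
    drop_spliced: bool = False
    embed_method: str = "tsne"
    embed_seed: int = 0
    perplexity: Optional[float] = None
    min_weight: int = 5
    covariates: List[str] = field(default_factory=lambda: list(CANDIDATE_COVARIATES))
    outdir: str = "ovrfgraph_out"

    @classmethod
    def from_dict(cls, data: Dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        payload = asdict(self)
        payload.pop("outdir")
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def validate_paths(self) -> None:
        for p in self.genomes:
            if not Path(p).exists():
                raise ValueError(f"genome input does not exist: {p}")
        if self.proteins and not Path(self.proteins).exists():
            raise ValueError(f"protein FASTA does not exist: {self.proteins}")


def load_genomes(paths: Sequence[str], family: Optional[str] = None) -> List[GenomeRecord]:
    genomes: List[GenomeRecord] = []
    for p in paths:
        text = Path(p).read_text()
        if text.startswith("LOCUS"):
            genomes.extend(parse_genbank(text, family=family))
        else:
            g = parse_feature_table(text)
            g.family = family
            genomes.append(g)
    return genomes


def run_family_analysis(config: RunConfig) -> Dict[str, str]:
    """Run all stages; returns a manifest of output paths.

    Aborts with :class:`PipelineError` naming the failing stage.
    """
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [
        f"ovrfgraph {__version__}",
        f"seed={config.embed_seed}",
        f"config_hash={config.config_hash()}",
    ]
    manifest: Dict[str, str] = {}

    def emit(name: str, df) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            write_tsv(df, fh, header_lines=header)
        manifest[name] = str(path)

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return _Ctx()

    with stage("scan"):
        genomes = load_genomes(config.genomes, family=config.family)
        overlaps = {g.accession: detect_overlaps(g, mode=config.mode) for g in genomes}
        all_ov = [o for g in genomes for o in overlaps[g.accession]]
        emit("overlaps.tsv", overlap_table(all_ov))
        summaries = [
            genome_summary(g, overlaps[g.accession],
                           drop_plus0=config.drop_plus0, drop_spliced=config.drop_spliced)
            for g in genomes
        ]
        emit("summary.tsv", summary_table(summaries))

    with stage("cluster"):
        if not config.proteins:
            raise ValueError("clustering requires a protein FASTA")
        seqs = family_proteins(genomes, Path(config.proteins).read_text())
        D = pairwise_distance_matrix(seqs)
        coords = embed_2d(D, method=config.embed_method, seed=config.embed_seed,
                          perplexity=config.perplexity)
        Z = hierarchical_cluster(coords)
        orf_to_acc = {k: k.split("|", 1)[0] for k in D.labels}
        height, assignment = optimize_cutoff(Z, D.labels, orf_to_acc, n_genomes=len(genomes))
        emit("embedding.tsv", coords.rename_axis("orf_id").reset_index())
        emit("clusters.tsv", cluster_table(assignment, orf_to_acc))

    with stage("graph"):
        graph = build_adjacency_graph(genomes, assignment.orf_to_cluster, overlaps)
        emit("edges.tsv", edge_table(graph))
        emit("synteny.tsv", synteny_table(genomes, assignment.orf_to_cluster))
        dot_path = outdir / "family.dot"
        dot_path.write_text(render_dot(graph, min_weight=config.min_weight))
        manifest["family.dot"] = str(dot_path)

    with stage("stats"):
        metrics = node_metrics(graph)
        emit("node_metrics.tsv", metrics.reset_index())
        edges = edge_covariates(graph, metrics)
        step = stepwise_select(edges, candidates=config.covariates)
        emit("fit_report.tsv", fit_report(step, candidates=config.covariates))
        emit("aic_trace.tsv", step.trace_table())

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(
        json.dumps(
            dict(version=__version__, seed=config.embed_seed,
                 config_hash=config.config_hash(), family=config.family,
                 n_genomes=len(genomes), n_overlaps=len(all_ov),
                 n_clusters=assignment.K, cutoff_height=height,
                 selected_terms=list(step.terms), outputs=sorted(manifest)),
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    manifest["manifest.json"] = str(manifest_path)
    return manifest
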