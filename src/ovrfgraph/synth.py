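"""Seeded toy virus families with planted clusters, gene order and overlaps.

The generator emulates the structure the pipeline consumes: K ancestral
proteins ("clusters") drawn i.i.d. over the 20 amino acids, N genomes
each carrying a point-mutated copy of the core clusters in conserved
order plus Bernoulli accessory genes, and junction overlaps of chosen
lengths and frameshifts realized exactly in the nucleotide coordinates.

Geometry constraint: with complete CDSs (codon_start=1) whose lengths are
multiples of three, an overlap of L nt between consecutive genes forces
the frameshift (-L) mod 3 (same strand) and the antisense shift of the
same magnitude when the downstream gene is reversed.  Sampled overlap
lengths are therefore rounded up by at most 2 nt to the nearest length
consistent with the sampled shift; the ground truth records realized
values.  It is not a realism benchmark: no phylogeny, no indels.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Tuple

import numpy as np

from .records import CodingSequence, GenomeRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Frameshift mix loosely following the observed census: +2 dominant
# (driven by 1 nt and 4 nt junctions), +1 next, antisense rare.
DEFAULT_FRAMESHIFT_DIST: Dict[str, float] = {
    "+2": 0.60, "+1": 0.28, "+0": 0.02, "-0": 0.03, "-1": 0.03, "-2": 0.04,
}


def default_overlap_length(rng: np.random.Generator) -> int:
    """Short-overlap mixture: mostly 1 or 4 nt, geometric tail otherwise."""
    if rng.random() < 0.5:
        return int(rng.choice([1, 4]))
    return int(rng.geometric(0.08))


@dataclass
class FamilySpec:
    n_genomes: int = 20
    n_core_clusters: int = 8
    n_accessory_clusters: int = 4
    accessory_presence_prob: float = 0.5
    gene_length_range: Tuple[int, int] = (80, 250)  # amino acids
    aa_mutation_rate: float = 0.05
    overlap_prob_per_junction: float = 0.4
    frameshift_distribution: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRAMESHIFT_DIST)
    )
    overlap_length_distribution: Callable[[np.random.Generator], int] = default_overlap_length
    n_spliced_per_genome: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("accessory_presence_prob", "aa_mutation_rate", "overlap_prob_per_junction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.aa_mutation_rate >= 1.0:
            raise ValueError("aa_mutation_rate must be < 1")
        lo, hi = self.gene_length_range
        if lo < 3 or hi < lo:
            raise ValueError("gene_length_range must be [lo, hi] with lo >= 3")
        total = sum(self.frameshift_distribution.values())
        if not np.isclose(total, 1.0):
            raise ValueError("frameshift_distribution must sum to 1")


@dataclass(frozen=True)
class PlantedOverlap:
    accession: str
    cds_a: str
    cds_b: str
    overlap_length: int
    frameshift: str


@dataclass
class GroundTruth:
    orf_to_cluster: Dict[str, int]
    junctions: List[PlantedOverlap]
    adjacency: Counter  # (cluster_u, cluster_v) -> genome count
    overlaps: Counter  # (cluster_u, cluster_v) -> genome count
    skipped: List[str] = field(default_factory=list)  # infeasible overlaps, resampled away


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate == 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alt = AA20.replace(chars[i], "")
        chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def _feasible_length(L: int, shift: int, lmax: int) -> Optional[int]:
    """Smallest adjustment of L to satisfy L' = (-shift) mod 3, 1 <= L' <= lmax."""
    L = max(1, L)
    Lp = L + ((-shift - L) % 3)
    while Lp > lmax:
        Lp -= 3
    return Lp if Lp >= 1 else None


def generate_family(spec: FamilySpec) -> Tuple[List[GenomeRecord], Dict[str, str], GroundTruth]:
    """Generate (genome records, protein FASTA map, ground truth).

    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.n_core_clusters + spec.n_accessory_clusters
    lengths = rng.integers(spec.gene_length_range[0], spec.gene_length_range[1] + 1, size=K)
    ancestors = ["".join(AA20[i] for i in rng.integers(20, size=m)) for m in lengths]
    labels = [f"protein c{k}" for k in range(K)]
    # accessory genes interleave with the core in one conserved global order
    order = list(range(K))

    genomes: List[GenomeRecord] = []
    proteins: Dict[str, str] = {}
    truth = GroundTruth(orf_to_cluster={}, junctions=[], adjacency=Counter(), overlaps=Counter())
    shift_labels = sorted(spec.frameshift_distribution)
    shift_probs = np.array([spec.frameshift_distribution[s] for s in shift_labels])

    for gi in range(spec.n_genomes):
        acc = f"SYN{gi:03d}"
        present = [
            k for k in order
            if k < spec.n_core_clusters or rng.random() < spec.accessory_presence_prob
        ]
        cds_list: List[CodingSequence] = []
        pos = int(rng.integers(20, 101))
        prev: Optional[CodingSequence] = None
        prev_forward_clean = False  # previous gene forward-strand, eligible as overlap host
        n_spliced_left = spec.n_spliced_per_genome
        for j, k in enumerate(present):
            cid = f"cds{j}"
            aa = _mutate(ancestors[k], spec.aa_mutation_rate, rng)
            nt_len = 3 * len(aa) + 3  # stop codon included
            strand = 1
            start = pos
            planted: Optional[Tuple[int, str]] = None
            if prev is not None and prev_forward_clean and rng.random() < spec.overlap_prob_per_junction:
                label = str(rng.choice(shift_labels, p=shift_probs))
                shift = int(label[1])
                L = spec.overlap_length_distribution(rng)
                lmax = min(prev.coding_length, nt_len) - 1
                Lp = _feasible_length(L, shift, lmax)
                if Lp is None:
                    truth.skipped.append(f"{acc}:{cid} overlap infeasible (lmax={lmax})")
                else:
                    start = prev.end - Lp
                    if label.startswith("-"):
                        strand = -1
                    planted = (Lp, label)
            if planted is None and prev is not None:
                start = prev.end + int(rng.integers(20, 101))
            spliced = False
            exons: Tuple[Tuple[int, int], ...] = ((start, start + nt_len),)
            if n_spliced_left > 0 and planted is None and nt_len > 120:
                # carve an intron inside the span; span unchanged, so the
                # overlap geometry of neighbours is unaffected
                mid = start + 3 * (nt_len // 6)
                exons = ((start, mid), (mid + 30, start + nt_len))
                spliced = True
                n_spliced_left -= 1
            cds = CodingSequence(
                id=cid, accession=acc, product=labels[k], strand=strand,
                exons=exons, frame_offset=0, spliced=spliced,
            )
            cds_list.append(cds)
            proteins[cds.key] = aa
            truth.orf_to_cluster[cds.key] = k
            if prev is not None:
                truth.adjacency[(truth.orf_to_cluster[prev.key], k)] += 1
                if planted is not None:
                    truth.junctions.append(
                        PlantedOverlap(acc, prev.id, cid, planted[0], planted[1])
                    )
                    truth.overlaps[(truth.orf_to_cluster[prev.key], k)] += 1
            prev = cds
            prev_forward_clean = strand == 1 and not spliced
            pos = cds.end
        length = pos + int(rng.integers(20, 101))
        genomes.append(
            GenomeRecord(
                accession=acc, length=length, topology="linear", molecule="DNA",
                strandedness="ds", cds=cds_list, family="Synthviridae",
            )
        )
    return genomes, proteins, truth


def evaluate_clustering(
    assignment: Mapping[str, int], truth: Mapping[str, int]
) -> float:
    """Adjusted Rand index between a cluster assignment and ground truth."""
    from sklearn.metrics import adjusted_rand_score

    if set(assignment) != set(truth):
        raise ValueError("assignment and truth cover different ORF sets")
    keys = sorted(assignment)
    return float(adjusted_rand_score([truth[k] for k in keys], [assignment[k] for k in keys]))


def write_genbank(genomes: List[GenomeRecord], stream, seed: int = 0) -> None:
    """Emit GenBank flat files with random nucleotide filler sequence.

    Feature annotations, not the filler sequence, carry the information
    the pipeline consumes; proteins travel in the companion FASTA.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqFeature import SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    records = []
    for g in genomes:
        seq = "".join("ACGT"[i] for i in rng.integers(4, size=g.length))
        rec = SeqRecord(Seq(seq), id=g.accession, name=g.accession.replace(".", "_"),
                        description="synthetic virus genome")
        rec.annotations["molecule_type"] = (
            f"{g.strandedness}-{g.molecule}" if g.strandedness else g.molecule
        )
        rec.annotations["topology"] = g.topology
        for c in g.cds:
            parts = [SimpleLocation(a, b, strand=c.strand) for a, b in c.exons]
            loc = parts[0]
            for part in parts[1:]:
                loc = loc + part
            feat = SeqFeature(loc, type="CDS")
            feat.qualifiers["protein_id"] = [c.id]
            feat.qualifiers["product"] = [c.product]
            feat.qualifiers["codon_start"] = [str(c.frame_offset + 1)]
            rec.features.append(feat)
        records.append(rec)
    SeqIO.write(records, stream, "genbank")
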