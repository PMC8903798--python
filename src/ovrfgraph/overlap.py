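"""Overlap detection and frameshift classification for annotated genomes.

Two CDSs overlap when their exon unions share at least one nucleotide.
Same-strand overlaps are labelled +0/+1/+2 by the phase shift of the
downstream reading frame relative to the upstream one; antisense overlaps
are labelled -0/-1/-2, where -0 is the perfectly codon-aligned antisense
frame and -1/-2 shift by one and two nucleotides relative to it.

The phase of a CDS is the top-strand coordinate (mod 3) at which its codon
triplets begin: ``(start + frame_offset) mod 3`` on the forward strand and
``(end - frame_offset) mod 3`` on the reverse strand, where start/end are
the 0-based half-open bounds of the exon union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple

import numpy as np
import pandas as pd

from .records import CodingSequence, GenomeRecord, intersect_length

RENDERINGS = ("+0", "+1", "+2", "-0", "-1", "-2")


@dataclass(frozen=True)
class FrameShiftLabel:
    strand_relation: Optional[str] = None  # same | opposite
    shift: Optional[int] = None  # 0, 1, 2
    undefined_reason: Optional[str] = None  # spliced | incomplete_frame

    def __post_init__(self) -> None:
        defined = self.strand_relation is not None and self.shift is not None
        if defined == (self.undefined_reason is not None):
            raise ValueError("label must be either defined or carry a reason, not both")

    @property
    def rendered(self) -> Optional[str]:
        if self.undefined_reason is not None:
            return None
        sign = "+" if self.strand_relation == "same" else "-"
        return f"{sign}{self.shift}"


@dataclass(frozen=True)
class OverlapRecord:
    accession: str
    cds_a: str  # id of the upstream (sort-order first) CDS
    cds_b: str
    overlap_length: int
    frameshift: FrameShiftLabel
    involves_spliced: bool

    @property
    def same_frame_plus0(self) -> bool:
        return self.frameshift.rendered == "+0"


@dataclass(frozen=True)
class GenomeSummary:
    accession: str
    n_orfs: int
    n_ovrfs: int
    mean_overlap_length: Optional[float]
    genome_length: int
    molecule: str
    baltimore: Optional[str]


def sort_orfs(genome: GenomeRecord) -> List[CodingSequence]:
    """ORFs sorted by ascending (start, end), strand ignored, ties by id."""
    return sorted(genome.cds, key=lambda c: (c.start, c.end, c.id))


def _phase(cds: CodingSequence) -> int:
    if cds.strand == 1:
        return (cds.start + cds.frame_offset) % 3
    return (cds.end - cds.frame_offset) % 3


def classify_frameshift(cds_a: CodingSequence, cds_b: CodingSequence) -> FrameShiftLabel:
    """Six-way frameshift label for an overlapping CDS pair.

    Raises ValueError if the pair does not overlap.  Pairs involving a
    spliced CDS (or an origin wraparound, whose phase is undefined in
    linear coordinates) get an undefined label instead of a rendering.
    """
    if intersect_length(cds_a.exons, cds_b.exons) == 0:
        raise ValueError(f"CDSs {cds_a.id} and {cds_b.id} do not overlap")
    if cds_a.spliced or cds_b.spliced:
        return FrameShiftLabel(undefined_reason="spliced")
    if cds_a.wraparound or cds_b.wraparound:
        return FrameShiftLabel(undefined_reason="incomplete_frame")
    pa, pb = _phase(cds_a), _phase(cds_b)
    if cds_a.strand == cds_b.strand:
        if cds_a.strand == 1:
            up, down = sorted((cds_a, cds_b), key=lambda c: (c.start, c.end, c.id))
            shift = (_phase(down) - _phase(up)) % 3
        else:
            # Mirror symmetry: for two reverse-strand CDSs the upstream gene
            # in reading direction is the higher-coordinate one, and the
            # mirrored phase difference flips sign.
            up, down = sorted((cds_a, cds_b), key=lambda c: (-c.end, -c.start, c.id))
            shift = (_phase(up) - _phase(down)) % 3
        return FrameShiftLabel(strand_relation="same", shift=shift)
    fwd, rev = (cds_a, cds_b) if cds_a.strand == 1 else (cds_b, cds_a)
    shift = (_phase(rev) - _phase(fwd)) % 3
    return FrameShiftLabel(strand_relation="opposite", shift=shift)


def detect_overlaps(
    genome: GenomeRecord,
    mode: str = "adjacent_pairs",
    circular_wrap: bool = False,
) -> List[OverlapRecord]:
    """Detect overlapping CDS pairs in one genome.

    ``adjacent_pairs`` (default) evaluates only consecutive pairs in
    sorted genome order, as in the screening procedure the census is
    built on; ``all_pairs`` reports every pair with a nonempty exon-union
    intersection (catches nested ORFs).  With ``circular_wrap`` the
    (last, first) pair of a circular genome is also evaluated.
    """
    if mode not in ("adjacent_pairs", "all_pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    ordered = sort_orfs(genome)
    if len(ordered) < 2:
        return []
    if mode == "adjacent_pairs":
        pairs = list(zip(ordered, ordered[1:]))
        if circular_wrap and genome.topology == "circular":
            pairs.append((ordered[-1], ordered[0]))
    else:
        pairs = [
            (ordered[i], ordered[j])
            for i in range(len(ordered))
            for j in range(i + 1, len(ordered))
        ]
    out: List[OverlapRecord] = []
    for a, b in pairs:
        n = intersect_length(a.exons, b.exons)
        if n <= 0:
            continue
        out.append(
            OverlapRecord(
                accession=genome.accession,
                cds_a=a.id,
                cds_b=b.id,
                overlap_length=n,
                frameshift=classify_frameshift(a, b),
                involves_spliced=a.spliced or b.spliced,
            )
        )
    return out


def genome_summary(
    genome: GenomeRecord,
    overlaps: Sequence[OverlapRecord],
    drop_plus0: bool = False,
    drop_spliced: bool = False,
) -> GenomeSummary:
    """Per-genome counts and mean overlap length.

    ``drop_plus0`` removes same-frame (+0) truncation artefacts, which do
    not encode distinct protein sequence; ``drop_spliced`` removes pairs
    involving a spliced CDS.
    """
    kept = [
        o for o in overlaps
        if not (drop_plus0 and o.same_frame_plus0)
        and not (drop_spliced and o.involves_spliced)
    ]
    mean_len = float(np.mean([o.overlap_length for o in kept])) if kept else None
    return GenomeSummary(
        accession=genome.accession,
        n_orfs=genome.n_cds,
        n_ovrfs=len(kept),
        mean_overlap_length=mean_len,
        genome_length=genome.length,
        molecule=genome.molecule,
        baltimore=genome.baltimore,
    )


def perturb_annotations(
    family: Sequence[GenomeRecord],
    genome_fraction: float,
    delta_range: Tuple[int, int] = (-10, 10),
    seed: int = 0,
) -> List[GenomeRecord]:
    """Misannotation experiment: jitter CDS bounds in a random genome subset.

    For ceil(fraction * N) genomes, every CDS start and end is shifted by
    independent uniform integer deviates from ``delta_range``, clamped to
    genome bounds and to end > start.  Deterministic given the seed.
    Multi-exon CDSs have their outermost bounds shifted.
    """
    if not 0.0 <= genome_fraction <= 1.0:
        raise ValueError(f"genome_fraction must be in [0,1], got {genome_fraction}")
    lo, hi = delta_range
    if lo > hi:
        raise ValueError("empty delta_range")
    rng = np.random.default_rng(seed)
    n_pick = math.ceil(genome_fraction * len(family))
    picked = set(rng.choice(len(family), size=n_pick, replace=False)) if n_pick else set()
    out: List[GenomeRecord] = []
    for gi, g in enumerate(family):
        if gi not in picked:
            out.append(g)
            continue
        new_cds = []
        for c in g.cds:
            ds, de = int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1))
            s = min(max(0, c.start + ds), g.length - 1)
            e = max(min(g.length, c.end + de), s + 1)
            if len(c.exons) == 1:
                new_cds.append(c.moved(s, e))
            else:
                exons = list(c.exons)
                exons[0] = (s, max(exons[0][1], s + 1))
                last_a = exons[-1][0]
                exons[-1] = (min(last_a, e - 1), e)
                new_cds.append(replace(c, exons=tuple(exons)))
        out.append(replace_genome(g, new_cds))
    return out


def replace_genome(g: GenomeRecord, cds: List[CodingSequence]) -> GenomeRecord:
    return GenomeRecord(
        accession=g.accession, length=g.length, topology=g.topology,
        molecule=g.molecule, strandedness=g.strandedness, cds=cds,
        family=g.family, baltimore=g.baltimore,
    )


def overlap_table(records: Iterable[OverlapRecord]) -> pd.DataFrame:
    rows = [
        dict(accession=o.accession, cds_a=o.cds_a, cds_b=o.cds_b,
             overlap_length=o.overlap_length,
             frameshift=o.frameshift.rendered or "",
             undefined_reason=o.frameshift.undefined_reason or "",
             involves_spliced=o.involves_spliced)
        for o in records
    ]
    return pd.DataFrame(
        rows, columns=["accession", "cds_a", "cds_b", "overlap_length",
                       "frameshift", "undefined_reason", "involves_spliced"],
    )


def summary_table(summaries: Iterable[GenomeSummary]) -> pd.DataFrame:
    rows = [
        dict(accession=s.accession, n_orfs=s.n_orfs, n_ovrfs=s.n_ovrfs,
             mean_overlap_length=s.mean_overlap_length,
             genome_length=s.genome_length, molecule=s.molecule,
             baltimore=s.baltimore or "")
        for s in summaries
    ]
    return pd.DataFrame(
        rows, columns=["accession", "n_orfs", "n_ovrfs", "mean_overlap_length",
                       "genome_length", "molecule", "baltimore"],
    )


def write_tsv(df: pd.DataFrame, stream: TextIO, header_lines: Sequence[str] = ()) -> None:
    for line in header_lines:
        stream.write(f"# {line}\n")
    df.to_csv(stream, sep="\t", index=False)
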