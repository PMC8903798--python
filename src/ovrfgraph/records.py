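"""Normalized in-memory representation of annotated genomes.

All coordinates are 0-based half-open on the top strand; the GenBank
1-based inclusive convention exists only at the I/O boundary.  Reverse
strand coding sequences keep their exon intervals in ascending genomic
order and carry ``strand == -1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Tuple

Interval = Tuple[int, int]


@dataclass(frozen=True)
class CodingSequence:
    """One annotated CDS.

    ``frame_offset`` is the GenBank ``codon_start`` qualifier minus one,
    i.e. the number of nucleotides (in reading direction) before the first
    complete codon.  ``spliced`` is True only for multi-exon features that
    are not origin wraparounds of a circular genome; ``wraparound`` marks
    those instead.
    """

    id: str
    accession: str
    product: str
    strand: int  # +1 or -1
    exons: Tuple[Interval, ...]
    frame_offset: int = 0
    spliced: bool = False
    wraparound: bool = False
    partial: bool = False
    pseudo: bool = False

    def __post_init__(self) -> None:
        if self.strand not in (1, -1):
            raise ValueError(f"CDS {self.id}: strand must be +1 or -1")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"CDS {self.id}: frame_offset must be in {{0,1,2}}")
        exons = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for a, b in exons:
            if b <= a:
                raise ValueError(f"CDS {self.id}: empty exon [{a},{b})")
        for (_, b1), (a2, _) in zip(exons, exons[1:]):
            if a2 < b1:
                raise ValueError(f"CDS {self.id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        """Lowest genomic coordinate covered."""
        return self.exons[0][0]

    @property
    def end(self) -> int:
        """Highest genomic coordinate covered, exclusive."""
        return self.exons[-1][1]

    @property
    def coding_length(self) -> int:
        return sum(b - a for a, b in self.exons)

    @property
    def key(self) -> str:
        """Family-unique ORF identifier: ``accession|id``."""
        return f"{self.accession}|{self.id}"

    def moved(self, new_start: int, new_end: int) -> "CodingSequence":
        """Return a copy whose overall span is [new_start, new_end).

        Only meaningful for single-exon features (used by the annotation
        perturbation experiment).
        """
        if len(self.exons) != 1:
            raise ValueError("moved() supports single-exon CDSs only")
        return replace(self, exons=((new_start, new_end),))


@dataclass
class GenomeRecord:
    """An annotated genome: metadata plus its ordered CDS features."""

    accession: str
    length: int
    topology: str = "linear"  # linear | circular
    molecule: str = "unknown"  # DNA | RNA | unknown
    strandedness: Optional[str] = None  # ss | ds | None
    cds: List[CodingSequence] = field(default_factory=list)
    family: Optional[str] = None
    baltimore: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"{self.accession}: bad topology {self.topology!r}")
        for c in self.cds:
            if c.end > self.length or c.start < 0:
                raise ValueError(
                    f"{self.accession}: CDS {c.id} exceeds genome bounds "
                    f"[{c.start},{c.end}) vs length {self.length}"
                )

    @property
    def n_cds(self) -> int:
        return len(self.cds)


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Union of half-open intervals as a sorted disjoint list."""
    out: List[Interval] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def intersect_length(xs: Iterable[Interval], ys: Iterable[Interval]) -> int:
    """Total length of the intersection of two interval unions."""
    xs, ys = merge_intervals(xs), merge_intervals(ys)
    total, i, j = 0, 0, 0
    while i < len(xs) and j < len(ys):
        lo = max(xs[i][0], ys[j][0])
        hi = min(xs[i][1], ys[j][1])
        if hi > lo:
            total += hi - lo
        if xs[i][1] < ys[j][1]:
            i += 1
        else:
            j += 1
    return total
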