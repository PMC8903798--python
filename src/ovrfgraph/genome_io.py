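"""Reading and writing annotated genomes and per-family protein sets.

Supported formats: GenBank flat files (read, via Biopython), a plain TSV
feature-table dialect (read/write, round-trip exact), protein FASTA
(read/write) and a per-CDS summary table.
"""

from __future__ import annotations

import csv
import io
import warnings
from typing import Dict, Iterable, List, TextIO, Tuple, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .records import CodingSequence, GenomeRecord


class GenomeParseError(ValueError):
    """Raised for malformed records; message names the accession."""


def _molecule_fields(mol_type: str) -> Tuple[str, str | None]:
    """Split a GenBank molecule_type like 'ss-RNA' into (molecule, strandedness)."""
    m = mol_type.upper()
    strand = None
    if m.startswith("SS-"):
        strand = "ss"
    elif m.startswith("DS-"):
        strand = "ds"
    if "RNA" in m:
        return "RNA", strand
    if "DNA" in m:
        return "DNA", strand
    return "unknown", strand


def _feature_to_cds(feat: SeqFeature, accession: str, idx: int, topology: str) -> CodingSequence:
    loc = feat.location
    if loc is None:
        raise GenomeParseError(f"{accession}: CDS #{idx} has no location")
    parts = loc.parts if isinstance(loc, CompoundLocation) else [loc]
    exons = [(int(p.start), int(p.end)) for p in parts]
    # An origin-spanning join on a circular genome lists a high-coordinate
    # part before a low-coordinate one; it is not alternative splicing.
    descending = any(a2 < a1 for (a1, _), (a2, _) in zip(exons, exons[1:]))
    wraparound = descending and topology == "circular"
    spliced = len(exons) > 1 and not wraparound
    quals = feat.qualifiers
    codon_start = int(quals.get("codon_start", ["1"])[0])
    raw = str(loc)
    partial = "<" in raw or ">" in raw
    ident = quals.get("protein_id", quals.get("locus_tag", [f"cds{idx}"]))[0]
    return CodingSequence(
        id=ident,
        accession=accession,
        product=quals.get("product", [""])[0],
        strand=-1 if loc.strand == -1 else 1,
        exons=tuple(sorted(exons)),
        frame_offset=codon_start - 1,
        spliced=spliced,
        wraparound=wraparound,
        partial=partial,
        pseudo="pseudo" in quals or "pseudogene" in quals,
    )


def parse_genbank(stream: Union[str, TextIO], family: str | None = None) -> List[GenomeRecord]:
    """Parse a GenBank flat file into GenomeRecords.

    CDS features only; all other feature types are ignored.  Coordinates
    are converted from 1-based inclusive to 0-based half-open.  An empty
    stream yields an empty list with a warning.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    genomes: List[GenomeRecord] = []
    try:
        records = list(SeqIO.parse(stream, "genbank"))
    except ValueError as exc:  # Biopython raises ValueError on bad locations
        raise GenomeParseError(f"malformed GenBank record: {exc}") from exc
    for rec in records:
        accession = rec.id or rec.name
        topology = rec.annotations.get("topology", "linear")
        molecule, strandedness = _molecule_fields(rec.annotations.get("molecule_type", ""))
        cds_list = []
        for i, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            try:
                cds_list.append(_feature_to_cds(feat, accession, i, topology))
            except ValueError as exc:
                raise GenomeParseError(
                    f"{accession}: malformed CDS location ({exc})"
                ) from exc
        genomes.append(
            GenomeRecord(
                accession=accession,
                length=len(rec.seq),
                topology=topology,
                molecule=molecule,
                strandedness=strandedness,
                cds=cds_list,
                family=family,
            )
        )
    if not genomes:
        warnings.warn("no GenBank records found in stream", stacklevel=2)
    return genomes


_FT_COLUMNS = ["accession", "id", "product", "strand", "exons", "codon_start"]
_FT_META = ["length", "topology", "molecule"]


def _encode_exons(cds: CodingSequence) -> str:
    return ";".join(f"{a}-{b}" for a, b in cds.exons)


def _decode_exons(text: str) -> Tuple[Tuple[int, int], ...]:
    out = []
    for chunk in text.split(";"):
        a, b = chunk.split("-")
        out.append((int(a), int(b)))
    return tuple(out)


def write_feature_table(genome: GenomeRecord, stream: TextIO) -> None:
    """Write the TSV feature-table dialect (one genome per file)."""
    stream.write(f"#length={genome.length}\ttopology={genome.topology}\tmolecule={genome.molecule}\n")
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_FT_COLUMNS)
    for cds in genome.cds:
        writer.writerow(
            [cds.accession, cds.id, cds.product, cds.strand,
             _encode_exons(cds), cds.frame_offset + 1]
        )


def parse_feature_table(stream: Union[str, TextIO]) -> GenomeRecord:
    """Read one genome from the TSV feature-table dialect.

    Round-trips exactly with :func:`write_feature_table`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    meta = {"length": None, "topology": "linear", "molecule": "unknown"}
    pos = stream.tell()
    first = stream.readline()
    if first.startswith("#"):
        for kv in first[1:].strip().split("\t"):
            k, _, v = kv.partition("=")
            if k in meta:
                meta[k] = v
    else:
        stream.seek(pos)
    reader = csv.reader(stream, delimiter="\t")
    header = next(reader, None)
    if header is None or header[: len(_FT_COLUMNS)] != _FT_COLUMNS:
        raise GenomeParseError(f"feature table header missing or wrong: {header}")
    cds_list: List[CodingSequence] = []
    accession = None
    for row in reader:
        if not row:
            continue
        acc, ident, product, strand, exons, codon_start = row[:6]
        if accession is None:
            accession = acc
        elif acc != accession:
            raise GenomeParseError(
                f"feature table mixes accessions {accession} and {acc}; one genome per table"
            )
        try:
            cds_list.append(
                CodingSequence(
                    id=ident, accession=acc, product=product, strand=int(strand),
                    exons=_decode_exons(exons), frame_offset=int(codon_start) - 1,
                    spliced=";" in exons,
                )
            )
        except ValueError as exc:
            raise GenomeParseError(f"CDS {ident}: {exc}") from exc
    if accession is None:
        raise GenomeParseError("feature table contains no rows")
    length = int(meta["length"]) if meta["length"] else max(c.end for c in cds_list)
    return GenomeRecord(
        accession=accession, length=length, topology=meta["topology"],
        molecule=meta["molecule"], cds=cds_list,
    )


def family_proteins(
    genomes: Iterable[GenomeRecord], translations: Union[str, TextIO]
) -> Dict[str, str]:
    """Map ORF keys (``accession|cds_id``) to amino-acid sequences.

    FASTA identifiers may be ``accession|cds_id`` or a bare CDS id; bare
    ids are resolved against all genomes and disambiguated by accession
    when unique.  CDSs lacking a translation trigger a warning.
    """
    if isinstance(translations, str):
        translations = io.StringIO(translations)
    by_key = {}
    by_bare: Dict[str, List[str]] = {}
    for g in genomes:
        for c in g.cds:
            by_key[c.key] = c
            by_bare.setdefault(c.id, []).append(c.key)
    seen_ids = set()
    mapping: Dict[str, str] = {}
    for rec in SeqIO.parse(translations, "fasta"):
        if rec.id in seen_ids:
            raise GenomeParseError(f"duplicate FASTA id {rec.id}")
        seen_ids.add(rec.id)
        if rec.id in by_key:
            mapping[rec.id] = str(rec.seq)
        elif rec.id in by_bare and len(by_bare[rec.id]) == 1:
            mapping[by_bare[rec.id][0]] = str(rec.seq)
        elif rec.id in by_bare:
            raise GenomeParseError(
                f"FASTA id {rec.id} is ambiguous across accessions; use accession|id"
            )
        else:
            warnings.warn(f"FASTA id {rec.id} matches no CDS", stacklevel=2)
    missing = sorted(set(by_key) - set(mapping))
    for key in missing:
        warnings.warn(f"CDS {key} has no translation", stacklevel=2)
    return mapping


def write_fasta(seqs: Dict[str, str], stream: TextIO) -> None:
    records = [SeqRecord(Seq(s), id=k, description="") for k, s in seqs.items()]
    SeqIO.write(records, stream, "fasta")


def cds_table(genomes: Iterable[GenomeRecord]) -> pd.DataFrame:
    """One row per CDS, sorted by (accession, start, end, id)."""
    rows = []
    for g in genomes:
        for c in g.cds:
            rows.append(
                dict(accession=c.accession, id=c.id, product=c.product,
                     strand=c.strand, start=c.start, end=c.end,
                     frame_offset=c.frame_offset, spliced=c.spliced)
            )
    df = pd.DataFrame(
        rows, columns=["accession", "id", "product", "strand", "start", "end",
                       "frame_offset", "spliced"],
    )
    if len(df):
        df = df.sort_values(["accession", "start", "end", "id"], kind="mergesort")
    return df.reset_index(drop=True)


def format_location(cds: CodingSequence) -> str:
    """Re-emit a GenBank 1-based inclusive location for simple locations."""
    if len(cds.exons) == 1:
        a, b = cds.exons[0]
        core = f"{a + 1}..{b}"
    else:
        core = "join(" + ",".join(f"{a + 1}..{b}" for a, b in cds.exons) + ")"
    return f"complement({core})" if cds.strand == -1 else core
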