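import numpy as np
import pytest

from ovrfgraph.records import CodingSequence, GenomeRecord
from ovrfgraph.synth import FamilySpec, generate_family


def make_cds(ident, start, end, strand=1, accession="ACC", product="p",
             frame_offset=0, exons=None, spliced=False):
    return CodingSequence(
        id=ident, accession=accession, product=product, strand=strand,
        exons=exons if exons is not None else ((start, end),),
        frame_offset=frame_offset, spliced=spliced,
    )


def make_genome(cds, length=None, accession="ACC", **kw):
    if length is None:
        length = max((c.end for c in cds), default=0) + 10
    return GenomeRecord(accession=accession, length=length, cds=list(cds), **kw)


def random_genome(rng, n_cds=8, accession="RND", length=2000):
    """Genome with random, possibly overlapping single-exon CDSs."""
    cds = []
    for i in range(n_cds):
        a = int(rng.integers(0, length - 30))
        b = a + 3 * int(rng.integers(2, 60)) + 3
        b = min(b, length)
        strand = int(rng.choice([1, -1]))
        cds.append(make_cds(f"c{i}", a, b, strand=strand, accession=accession))
    return make_genome(cds, length=length, accession=accession)


@pytest.fixture(scope="session")
def clean_family():
    """All-core family, no mutations: clustering should be exact."""
    spec = FamilySpec(
        n_genomes=10, n_core_clusters=7, n_accessory_clusters=0,
        aa_mutation_rate=0.0, overlap_prob_per_junction=0.35, seed=11,
    )
    return generate_family(spec)


@pytest.fixture(scope="session")
def noisy_family():
    """Family with accessory genes and point mutations, like real data."""
    spec = FamilySpec(
        n_genomes=14, n_core_clusters=6, n_accessory_clusters=3,
        accessory_presence_prob=0.6, aa_mutation_rate=0.05,
        overlap_prob_per_junction=0.4, seed=5,
    )
    return generate_family(spec)


GENBANK_TWO_RECORDS = """\
LOCUS       TEST1                    100 bp    ss-RNA  linear   VRL 01-JAN-2020
DEFINITION  toy virus 1.
ACCESSION   TEST1
VERSION     TEST1.1
FEATURES             Location/Qualifiers
     source          1..100
     gene            5..13
     CDS             5..13
                     /product="alpha"
                     /protein_id="A1"
     CDS             complement(10..18)
                     /product="beta"
                     /protein_id="B1"
                     /codon_start=1
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
LOCUS       TEST2                     60 bp    DNA     circular VRL 01-JAN-2020
DEFINITION  toy virus 2 with an origin-spanning CDS.
ACCESSION   TEST2
FEATURES             Location/Qualifiers
     CDS             join(52..60,1..9)
                     /product="wrap"
                     /protein_id="W1"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""
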