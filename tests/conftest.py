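import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from oscan import GenomeCDSSet, CodingSequence, SynthesisSpec, synth_genome

STOPS11 = {"TAA", "TAG", "TGA"}


def make_genome(seqs, table_id=11, organism="toy", genus="Toyus"):
    cds = [CodingSequence(id=f"g{i}", organism=organism, sequence=s,
                          genetic_code=table_id) for i, s in enumerate(seqs)]
    return GenomeCDSSet(organism=organism, genus=genus, division="test",
                        genetic_code=table_id, cds=cds)


@pytest.fixture(scope="session")
def small_genome():
    """50 genes x 150 codons at G+C 0.5, no planted excess."""
    return synth_genome(SynthesisSpec(n_genes=50, gc_target=0.5,
                                      length_sampler=150, seed=11))


@pytest.fixture(scope="session")
def medium_genome():
    """200 genes x 300 codons at G+C 0.45."""
    return synth_genome(SynthesisSpec(n_genes=200, gc_target=0.45, seed=17))


@pytest.fixture
def genbank_file(tmp_path):
    """Two-contig GenBank fixture: 3 CDS (one minus-strand, one pseudo)."""
    genome = ("ATGGCTGCTTTTGGGAAACCC" + "GCA" * 120 + "TAA"  # plus-strand CDS
              + "TTTTTT"
              + str(Seq("ATG" + "GAA" * 110 + "TGA").reverse_complement())
              + "ACGTAC")
    rec = SeqRecord(Seq(genome), id="SYN001", name="SYN001",
                    description="synthetic test contig",
                    annotations={"organism": "Synthia testii",
                                 "molecule_type": "DNA"})
    cds1_len = 21 + 360 + 3
    f1 = SeqFeature(FeatureLocation(0, cds1_len, strand=1), type="CDS",
                    qualifiers={"locus_tag": ["SYN_0001"]})
    rc_start = cds1_len + 6
    rc_len = 3 + 330 + 3
    f2 = SeqFeature(FeatureLocation(rc_start, rc_start + rc_len, strand=-1),
                    type="CDS", qualifiers={"locus_tag": ["SYN_0002"]})
    f3 = SeqFeature(FeatureLocation(0, 333, strand=1), type="CDS",
                    qualifiers={"locus_tag": ["SYN_0003"], "pseudo": [""]})
    fgene = SeqFeature(FeatureLocation(0, 30, strand=1), type="gene")
    rec.features = [fgene, f1, f2, f3]
    path = tmp_path / "toy.gb"
    SeqIO.write([rec], str(path), "genbank")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
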