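import numpy as np
import pytest

from rnadep.fixtures import FixtureConfig, make_fixture
from rnadep.reference import GeneModel, TranscriptModel, load_reference


def make_gene(seq: str, gene_id: str = "G", strand: str = "+",
              exons=None, contig: str = "chr1",
              extra_isoforms=()) -> GeneModel:
    """In-memory single-contig gene for unit tests.

    ``seq`` is the contig sequence; default exon structure is one exon
    covering it.  ``extra_isoforms`` is a list of exon lists.
    """
    from rnadep.reference import reverse_complement

    exons = exons or [(0, len(seq))]

    def _tx(tid, ex):
        spliced = "".join(seq[s:e] for s, e in sorted(ex))
        t = TranscriptModel(transcript_id=tid, gene_id=gene_id, contig=contig,
                            strand=strand, exons=ex)
        t.mrna_seq = spliced if strand == "+" else reverse_complement(spliced)
        return t

    txs = [_tx(f"{gene_id}.t1", exons)]
    for i, ex in enumerate(extra_isoforms, 2):
        txs.append(_tx(f"{gene_id}.t{i}", ex))
    return GeneModel(gene_id=gene_id, name=gene_id, transcripts=txs,
                     canonical_id=f"{gene_id}.t1")


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


SMALL_CONFIG = FixtureConfig(
    n_genes=14, n_targets=6,
    exon_length_range=(90, 180), intron_length_range=(60, 120),
    n_exons_range=(1, 3), target_n_exons_range=(3, 5))


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    return make_fixture(SMALL_CONFIG, 11, tmp_path_factory.mktemp("fix"))


@pytest.fixture(scope="session")
def fixture_genes(fixture_paths):
    return load_reference(fixture_paths.fasta, fixture_paths.gtf)
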