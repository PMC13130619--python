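import textwrap

import pytest

from fusiontriage.reference_io import Exon, GenomeSequence, TranscriptModel


@pytest.fixture
def write_fasta(tmp_path):
    def _write(records: dict, name="genome.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for header, seq in records.items():
                fh.write(f">{header}\n")
                fh.write("\n".join(textwrap.wrap(seq, 60)) + "\n")
        return path

    return _write


@pytest.fixture
def write_text(tmp_path):
    def _write(content: str, name: str):
        path = tmp_path / name
        path.write_text(content)
        return path

    return _write


def make_model(
    gene="GX",
    transcript="GX.t1",
    contig="chrT",
    strand="+",
    exons=((0, 10), (20, 30)),
    cds=None,
):
    """Build a TranscriptModel from genomic intervals given in transcript
    (rank) order."""
    exon_objs = tuple(Exon(start=s, end=e, rank=i + 1) for i, (s, e) in enumerate(exons))
    cds_start, cds_end = cds if cds else (None, None)
    return TranscriptModel(
        gene_id=f"G_{gene}",
        gene_name=gene,
        transcript_id=transcript,
        contig=contig,
        strand=strand,
        exons=exon_objs,
        cds_start=cds_start,
        cds_end=cds_end,
    )


@pytest.fixture
def simple_genome():
    #            0         1         2         3
    #            0123456789012345678901234567890123456789
    return GenomeSequence({"chrT": "ACGTACGTTAGCCATGGCATTACAGGTTCAAACCGGTTAA"})
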