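import textwrap

import pandas as pd
import pytest

from irsplit import CohortConfig, generate_cohort
from irsplit.annotation import GenomicInterval, TranscriptModel, filter_intronless

GTF_TEXT = textwrap.dedent("""\
    chr1\ttest\texon\t100\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; gene_name "G1";
    chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1"; gene_name "G1";
    chr1\ttest\texon\t100\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t2"; gene_name "G1";
    chr1\ttest\texon\t150\t250\t.\t+\t.\tgene_id "g1"; transcript_id "t2"; gene_name "G1";
    chr2\ttest\texon\t500\t600\t.\t-\t.\tgene_id "g2"; transcript_id "t3"; gene_name "G2";
    chr2\ttest\texon\t700\t800\t.\t-\t.\tgene_id "g2"; transcript_id "t3"; gene_name "G2";
    chr2\ttest\texon\t900\t950\t.\t-\t.\tgene_id "g2"; transcript_id "t3"; gene_name "G2";
""")


@pytest.fixture
def tiny_gtf(tmp_path):
    path = tmp_path / "tiny.gtf"
    path.write_text(GTF_TEXT)
    return path


def make_transcript(tid, exon_coords, chrom="chr1", strand="+", gene="g"):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    return TranscriptModel.from_exons(tid, gene, exons)


@pytest.fixture
def three_transcript_fs():
    """Three multi-exon transcripts on two chromosomes."""
    models = [
        make_transcript("tA", [(100, 200), (301, 400)]),
        make_transcript("tB", [(500, 550), (600, 650), (700, 750)], chrom="chr2"),
        make_transcript("tC", [(1000, 1100), (1301, 1400)], strand="-"),
    ]
    return filter_intronless(models)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest planted cohort shared by read-only tests."""
    cfg = CohortConfig(n_transcripts=400, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_groups(small_cohort) -> pd.Series:
    return small_cohort.groups
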