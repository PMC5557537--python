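import pytest

import tandemq as tq
from tandemq.core import write_fastq

# A hand-written SAM covering all four alignment categories plus an
# unaligned record, used for parsing/roundtrip/classification tests.
SAM_TEXT = """\
@HD\tVN:1.6\tSO:unknown
@SQ\tSN:chrT\tLN:10000
u1\t0\tchrT\t101\t40\t5M\t*\t0\t0\tACGTA\tIIIII\tMD:Z:5\tZT:Z:5,NA,200,0
u2\t16\tchrT\t201\t30\t3M2S\t*\t0\t0\tACGTA\tIIIII\tMD:Z:3\tZT:Z:3,1,120,80
c1\t99\tchrT\t301\t40\t5M\t=\t401\t105\tACGTA\tIIIII\tMD:Z:5\tZT:Z:5,NA,200,0
c1\t147\tchrT\t401\t40\t5M\t=\t301\t-105\tACGTA\tIIIII\tMD:Z:5\tZT:Z:5,NA,200,0
d1\t97\tchrT\t501\t20\t5M\t=\t2501\t2005\tACGTA\tIIIII\tMD:Z:2A2\tZT:Z:2,0,200,0
d1\t145\tchrT\t2501\t20\t5M\t=\t501\t-2005\tACGTA\tIIIII\tMD:Z:5\tZT:Z:2,0,200,0
b1\t73\tchrT\t601\t40\t5M\t=\t601\t0\tACGTA\tIIIII\tMD:Z:5\tZT:Z:5,NA,200,0
b1\t133\tchrT\t601\t0\t*\t=\t601\t0\tTTTTT\tIIIII
x1\t4\t*\t0\t0\t*\t*\t0\t0\tACGTA\tIIIII
"""


@pytest.fixture()
def sam_file(tmp_path):
    path = tmp_path / "fixture.sam"
    path.write_text(SAM_TEXT)
    return path


@pytest.fixture(scope="session")
def small_synthetic():
    """50 kb genome with 30% planted repeats (2% divergence)."""
    return tq.generate_genome(
        50_000, repeat_fraction=0.3, unit_len=500, divergence=0.02, seed=101
    )


@pytest.fixture(scope="session")
def small_genome(small_synthetic):
    return small_synthetic.genome


@pytest.fixture(scope="session")
def toy_aligner(small_genome):
    return tq.ToyAligner(small_genome)


@pytest.fixture(scope="session")
def input_reads(small_genome):
    """500 unpaired 100 nt truth-labeled reads from the small genome."""
    return tq.simulate_input_reads(small_genome, 500, 100, seed=102)


@pytest.fixture(scope="session")
def input_sam(tmp_path_factory, toy_aligner, input_reads):
    """The small input set aligned by the toy aligner."""
    d = tmp_path_factory.mktemp("aln")
    fq = d / "in.fastq"
    write_fastq(input_reads, fq)
    sam = d / "in.sam"
    toy_aligner.align_fastq(fq, sam)
    return sam
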