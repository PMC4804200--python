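import hypothesis
import pytest

from symbiorecruit import (
    CommunityConfig,
    FilterConfig,
    TabularAlignmentRecord,
    simulate_genome_pair,
)

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


def make_alignment(
    qseqid="r1",
    genome_id="A",
    sseqid=None,
    pident=99.0,
    qstart=1,
    qend=100,
    sstart=5001,
    send=None,
    evalue=1e-40,
    bitscore=180.0,
    length=None,
    mismatch=0,
    gapopen=0,
):
    """Terse factory for alignment records in tests."""
    if send is None:
        send = sstart + (qend - qstart)
    if length is None:
        length = abs(send - sstart) + 1
    return TabularAlignmentRecord(
        qseqid=qseqid,
        sseqid=sseqid or f"{genome_id}_ctg1",
        pident=pident,
        length=length,
        mismatch=mismatch,
        gapopen=gapopen,
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        evalue=evalue,
        bitscore=bitscore,
        genome_id=genome_id,
    )


@pytest.fixture(scope="session")
def small_pair():
    """A 20 kb two-lineage community used across tests."""
    cfg = CommunityConfig(
        genome_length=30_000,
        n_genes=40,
        gene_length=600,
        divergence=0.05,
        rrna_intervals=((28_000, 28_900),),
        its_intervals=((28_900, 29_000),),
        seed=12345,
    )
    return simulate_genome_pair(cfg)


@pytest.fixture
def toy_filter_inputs():
    """The six-record worked example: one record removed per rule, two kept.

    Reads are all 100 bp; genome A carries an rRNA mask at [1000, 1100).
    """
    records = [
        make_alignment("r1", pident=99.0, qstart=1, qend=95, sstart=5001),  # retained
        make_alignment("r2", pident=99.0, qstart=1, qend=85, sstart=6001),  # coverage 85%
        make_alignment("r3", pident=99.0, qstart=1, qend=100, sstart=1100),  # 1 bp in mask
        make_alignment("r4", pident=49.0, qstart=1, qend=100, sstart=7001),  # identity
        make_alignment("r5", pident=99.0, qstart=1, qend=100, sstart=8001, evalue=1e-3),
        make_alignment("r6", pident=96.0, qstart=1, qend=90, sstart=9001),  # coverage 90%
    ]
    read_lengths = {f"r{i}": 100 for i in range(1, 7)}
    masks = {"A": [(1000, 1100)]}
    return records, read_lengths, masks, FilterConfig()
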