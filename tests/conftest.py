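import numpy as np
import pandas as pd
import pytest

from riboload.annotation import ElementTable, TranscriptModel


@pytest.fixture
def single_exon_model():
    """1000-nt single-exon plus-strand transcript, CDS at [101, 700]."""
    return TranscriptModel(
        "T1", "G1", "chr1", "+", exons=((1001, 2000),), cds_span=(1101, 1700)
    )


@pytest.fixture
def two_exon_minus_model():
    """Minus-strand two-exon gene; 5'UTR on the genomically rightmost exon.

    Transcript length 600 (exons 400 + 200 in transcript order), with a
    500-nt genomic gap between the exons. CDS occupies transcript
    positions [101, 550].
    """
    exons = ((2100, 2499), (1400, 1599))  # 5'->3' on the minus strand
    m = TranscriptModel("T2", "G2", "chr1", "-", exons=exons)
    g_start = m.transcript_to_genomic(101)
    g_end = m.transcript_to_genomic(550)
    return TranscriptModel(
        "T2", "G2", "chr1", "-", exons=exons,
        cds_span=(min(g_start, g_end), max(g_start, g_end)),
    )


@pytest.fixture
def toy_reads(single_exon_model):
    """Three reads with 5' ends in each region of the single-exon gene."""
    return pd.DataFrame(
        {
            "sample": ["s1"] * 3,
            "assay": ["RPF"] * 3,
            "transcript": ["T1"] * 3,
            "start": [50, 150, 850],
            "length": [30, 30, 30],
        }
    )


@pytest.fixture
def elements_two_groups():
    flags = {}
    for i in range(10):
        flags[f"G{i:03d}"] = (i < 4, False, False)  # first 4 genes uORF+
    return ElementTable(flags)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
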