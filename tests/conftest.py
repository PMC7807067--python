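from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from histone3p import GenomeSequence, ScanWindow, TranscriptModel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def plus_tx() -> TranscriptModel:
    """Single-exon plus-strand toy gene: CDS [100, 400) on a 10-kb contig."""
    return TranscriptModel(
        gene_id="G1", transcript_id="T1", chrom="chrT", strand="+",
        exons=((100, 400),), cds_lo=100, cds_hi=400,
    )


@pytest.fixture
def minus_tx() -> TranscriptModel:
    """Single-exon minus-strand toy gene: CDS [200, 500); CDS end at 200."""
    return TranscriptModel(
        gene_id="G2", transcript_id="T2", chrom="chrT", strand="-",
        exons=((200, 500),), cds_lo=200, cds_hi=500,
    )


def make_window(seq_or_len, strand="+", start=0, end=None, anchor=0,
                kind="SL_WINDOW", chrom="chrT") -> ScanWindow:
    if end is None:
        end = seq_or_len if isinstance(seq_or_len, int) else len(seq_or_len)
    return ScanWindow(
        gene_id="G", transcript_id="T", chrom=chrom, strand=strand,
        start=start, end=end, anchor=anchor, kind=kind,
    )


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
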