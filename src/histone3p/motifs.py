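"""Stem-loop and polyadenylation-signal motif scanning.

The stem-loop of replication-dependent histone mRNAs is located by exact
matching of 12 literal variants of the 16-bp (one 17-bp) hairpin sequence;
candidate polyadenylation signals are the four hexamers AATAAA, ATTAAA,
ATGAAA and TATAAA ranked in that order of strength.  Scanning is
sense-strand only and strand-aware: for minus-strand transcripts the
reverse complement of the genomic window is searched and all positions are
reported in transcriptional coordinates relative to the CDS end.

Matching rules: exact string equality on uppercase sequence, ``N`` never
matches; a hit must *start* inside its window but may run up to
motif-length − 1 bp past the window edge, so boundary motifs are not lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .annotation import (
    Genome,
    GenomeSequence,
    PAS_FALLBACK_WINDOW,
    PAS_WINDOW,
    ScanWindow,
)

log = logging.getLogger(__name__)

#: The 12 literal stem-loop sequences (all 16 bp except one 17-bp variant).
STEM_LOOP_MOTIFS: tuple[str, ...] = (
    "GGCTCTTTTCAGAGCC",
    "GGCCCTTTTCAGGGCC",
    "GGTTCTTTTCAGAGCC",
    "GGTTCAAAAGAGAGCT",
    "GGCCCTTTTAAGGGCC",
    "CGGCTCTTTTCAGGGCC",
    "GGCCCTTTTTAGGGCC",
    "GGCTCTTTTAAGAGCC",
    "GGCTCTTTTTAGAGCC",
    "GGCCCTTCTCAGGGCC",
    "GGCTCTTCTAAGAGCC",
    "GGCTCTTCTCAGAGCC",
)

#: PAS hexamers in decreasing order of strength; rank 1 is strongest.
PAS_MOTIFS: tuple[str, ...] = ("AATAAA", "ATTAAA", "ATGAAA", "TATAAA")
PAS_RANK: dict[str, int] = {m: i + 1 for i, m in enumerate(PAS_MOTIFS)}

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class StemLoopHit:
    """An exact stem-loop occurrence on a transcript's sense strand.

    ``offset_from_cds_end`` counts bases in transcriptional direction from
    the CDS-end boundary to the motif's first (5'-most) base; 0 means the
    motif starts immediately after the last CDS base, negative values lie
    inside the CDS.
    """

    gene_id: str
    transcript_id: str
    motif_index: int
    motif: str
    genomic_start: int
    offset_from_cds_end: int
    strand: str


@dataclass(frozen=True)
class PASHit:
    """A PAS hexamer occurrence, with its strength rank and window of origin."""

    gene_id: str
    transcript_id: str
    motif: str
    rank: int
    genomic_start: int
    distance_from_cds_end: int
    strand: str
    window_kind: str


def _chrom_seq(genome, chrom: str) -> str:
    if isinstance(genome, GenomeSequence):
        return genome.residues
    return genome[chrom].residues


def _sense_occurrences(
    seq: str, window: ScanWindow, motif: str
) -> list[tuple[int, int]]:
    """All (genomic_start, transcriptional_offset) sense-strand occurrences
    of ``motif`` starting inside ``window``.  Overlapping hits all count."""
    L = len(motif)
    wlen = window.end - window.start
    if wlen <= 0:
        return []
    out: list[tuple[int, int]] = []
    if window.strand == "+":
        lo = window.start
        hi = min(len(seq), window.end + L - 1)
        region = seq[lo:hi]
        p = region.find(motif)
        while p != -1:
            if p < wlen:
                g = lo + p
                out.append((g, g - window.anchor))
            p = region.find(motif, p + 1)
    else:
        lo = max(0, window.start - (L - 1))
        hi = min(len(seq), window.end)
        region = reverse_complement(seq[lo:hi])
        # sense index q maps to the genomic coordinate of the motif's first
        # transcriptional base: m = hi - 1 - q; leftmost genomic base m-L+1.
        p = region.find(motif)
        while p != -1:
            if p < wlen:
                m = hi - 1 - p
                out.append((m - L + 1, window.anchor - 1 - m))
            p = region.find(motif, p + 1)
    return out


def scan_stem_loops(
    genome, window: ScanWindow, motifs: Sequence[str] = STEM_LOOP_MOTIFS
) -> list[StemLoopHit]:
    """Every exact stem-loop occurrence on the sense strand within ``window``.

    Returned in deterministic order by transcriptional position.
    """
    seq = _chrom_seq(genome, window.chrom)
    hits = [
        StemLoopHit(
            gene_id=window.gene_id,
            transcript_id=window.transcript_id,
            motif_index=i,
            motif=m,
            genomic_start=g,
            offset_from_cds_end=off,
            strand=window.strand,
        )
        for i, m in enumerate(motifs)
        for g, off in _sense_occurrences(seq, window, m)
    ]
    hits.sort(key=lambda h: (h.offset_from_cds_end, h.motif_index))
    return hits


def scan_pas(genome, window: ScanWindow) -> list[PASHit]:
    """All PAS hexamer occurrences in ``window``, sorted by (rank, distance)."""
    seq = _chrom_seq(genome, window.chrom)
    hits = [
        PASHit(
            gene_id=window.gene_id,
            transcript_id=window.transcript_id,
            motif=m,
            rank=PAS_RANK[m],
            genomic_start=g,
            distance_from_cds_end=dist,
            strand=window.strand,
            window_kind=window.kind,
        )
        for m in PAS_MOTIFS
        for g, dist in _sense_occurrences(seq, window, m)
    ]
    hits.sort(key=lambda h: (h.rank, h.distance_from_cds_end))
    return hits


def choose_pas(hits: Sequence[PASHit]) -> Optional[PASHit]:
    """Pick one PAS for a transcript: primary window beats fallback, then
    strongest rank, then closest to the CDS end.

    This deterministic rule stands in for manual curation of candidate
    sites; the full hit list is kept in outputs so a call can be overridden
    per gene.
    """
    if not hits:
        return None
    order = {PAS_WINDOW: 0, PAS_FALLBACK_WINDOW: 1}
    return min(
        hits,
        key=lambda h: (
            order.get(h.window_kind, 2),
            h.rank,
            h.distance_from_cds_end,
            h.genomic_start,
        ),
    )


def write_hits_tsv(
    sl_hits: Sequence[StemLoopHit], pas_hits: Sequence[PASHit], path: str
) -> None:
    cols = "gene_id transcript_id type motif rank genomic_start offset window_kind".split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for h in sl_hits:
            fh.write(
                "\t".join(
                    map(str, (h.gene_id, h.transcript_id, "SL", h.motif, "",
                              h.genomic_start, h.offset_from_cds_end, "SL_WINDOW"))
                )
                + "\n"
            )
        for h in pas_hits:
            fh.write(
                "\t".join(
                    map(str, (h.gene_id, h.transcript_id, "PAS", h.motif, h.rank,
                              h.genomic_start, h.distance_from_cds_end, h.window_kind))
                )
                + "\n"
            )
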