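"""Genome and annotation parsing, histone transcript selection, and scan windows.

Histone mRNA 3'-end processing is read off the genome around the coding
sequence: the stem-loop (SL) of replication-dependent transcripts sits a few
tens of bases past the CDS end, while polyadenylation signals (PAS) of
replication-independent isoforms can lie anywhere in the annotated 3'UTR or
up to a couple of kilobases further.  This module turns a FASTA + GTF pair
into :class:`TranscriptModel` objects and builds the three window kinds the
downstream motif scan operates on:

* ``SL_WINDOW``     — CDS start to CDS end + 600 bp,
* ``PAS_WINDOW``    — CDS end to (annotated 3'UTR end, if any) + 2 kb,
* ``PAS_FALLBACK_WINDOW`` — the next ``extension`` bp past the primary PAS
  window, consulted when poly(A)+ coverage runs past the primary window.

Internally all coordinates are 0-based half-open on the forward genomic
axis; GTF input/output converts at the boundary.  Window arithmetic is
performed on the genomic axis ignoring introns (histone genes are
overwhelmingly intronless); windows that cross an annotated intron carry a
``crosses_intron`` flag so spliced isoforms can be reviewed by eye.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from gffutils.feature import feature_from_line
from pyfaidx import Fasta

log = logging.getLogger(__name__)

# Window extents (bp, in transcriptional direction past the CDS end).
SL_WINDOW_DOWNSTREAM = 600
PAS_WINDOW_DOWNSTREAM = 2000
PAS_FALLBACK_EXTENSION = 8000

SL_WINDOW = "SL_WINDOW"
PAS_WINDOW = "PAS_WINDOW"
PAS_FALLBACK_WINDOW = "PAS_FALLBACK_WINDOW"

_VALID_RESIDUES = frozenset("ACGTN")

#: Human histone gene symbols that do not start with "HIST" (replication-
#: independent variants and the hybrid H2AFX, in the Gencode v27-era naming).
#: The default selector matches this list plus any gene whose name starts
#: with "HIST" (the HIST1/2/3/4 cluster genes and synthetic HISTSYNn
#: fixtures).  Edit or replace via the ``selector`` argument.
DEFAULT_HISTONE_GENES = frozenset(
    {
        "H2AFX", "H2AFZ", "H2AFY", "H2AFY2", "H2AFJ", "H2AFV",
        "H2AFB1", "H2AFB2", "H2AFB3",
        "H2BFS", "H2BFM", "H2BFWT",
        "H1F0", "H1FX", "H1FNT", "H1FOO",
        "H3F3A", "H3F3B", "H3F3C",
        "CENPA",
    }
)


class AnnotationError(ValueError):
    """Base class for annotation-layer errors."""


class GTFParseError(AnnotationError):
    """A GTF line could not be parsed; the message names the line number."""


class ReferenceMismatchError(AnnotationError):
    """Annotation references a chromosome absent from the genome FASTA."""


@dataclass(frozen=True)
class GenomeSequence:
    """A single chromosome/contig: an uppercase sequence over {A,C,G,T,N}."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise AnnotationError(
                f"sequence {self.name!r} contains invalid residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


Genome = Mapping[str, GenomeSequence]


def load_genome(fasta_path: str) -> dict[str, GenomeSequence]:
    """Load a FASTA into memory as ``{name: GenomeSequence}`` (via pyfaidx)."""
    fa = Fasta(fasta_path, as_raw=True, sequence_always_upper=True)
    return {name: GenomeSequence(name, str(fa[name][:])) for name in fa.keys()}


def write_fasta(genome: Genome, path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            seq = genome[name].residues
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class TranscriptModel:
    """One annotated transcript with the genomic anchors needed for scans.

    ``cds_lo``/``cds_hi`` bound the CDS on the forward genomic axis
    (0-based half-open); ``cds_start``/``cds_end`` expose the same bounds
    as boundary coordinates in transcriptional direction.  ``utr3_end`` is
    the farthest annotated 3'UTR end, again as a transcriptional-direction
    boundary coordinate, or ``None``.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_lo: int
    cds_hi: int
    utr3_end: Optional[int] = None
    gene_name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        if not 0 <= self.cds_lo < self.cds_hi:
            raise AnnotationError(f"{self.transcript_id}: empty or negative CDS")
        prev_end = -1
        for lo, hi in self.exons:
            if lo >= hi or lo < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons must be sorted and non-overlapping"
                )
            prev_end = hi
        if self.utr3_end is not None:
            ok = self.utr3_end >= self.cds_hi if self.strand == "+" else self.utr3_end <= self.cds_lo
            if not ok:
                raise AnnotationError(
                    f"{self.transcript_id}: utr3_end upstream of CDS end"
                )

    @property
    def cds_start(self) -> int:
        """CDS start boundary in transcriptional direction."""
        return self.cds_lo if self.strand == "+" else self.cds_hi

    @property
    def cds_end(self) -> int:
        """CDS end boundary in transcriptional direction (the window anchor)."""
        return self.cds_hi if self.strand == "+" else self.cds_lo

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def utr3_extent(self) -> int:
        """Length (bp) of the annotated 3'UTR past the CDS end, 0 if absent."""
        if self.utr3_end is None:
            return 0
        return abs(self.utr3_end - self.cds_end)


@dataclass(frozen=True)
class ScanWindow:
    """A genomic interval to scan, anchored at a transcript's CDS end.

    ``start``/``end`` are 0-based half-open on the forward axis; ``anchor``
    is the CDS-end boundary all motif offsets are measured from.  For
    fallback windows the anchor lies upstream of the window itself.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    anchor: int
    kind: str
    crosses_intron: bool = False

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(f"window start {self.start} > end {self.end}")
        if self.kind in (SL_WINDOW, PAS_WINDOW) and not (
            self.start <= self.anchor <= self.end
        ):
            raise AnnotationError(
                f"{self.kind} anchor {self.anchor} outside [{self.start},{self.end}]"
            )

    def __len__(self) -> int:
        return self.end - self.start


def _clip(lo: int, hi: int, chrom_length: Optional[int]) -> tuple[int, int]:
    lo = max(0, lo)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
        lo = min(lo, chrom_length)
    hi = max(lo, hi)
    return lo, hi


def _crosses_intron(t: TranscriptModel, lo: int, hi: int) -> bool:
    return any(a < hi and b > lo for a, b in t.introns)


def _make_window(
    t: TranscriptModel, lo: int, hi: int, kind: str, chrom_length: Optional[int]
) -> ScanWindow:
    lo, hi = _clip(lo, hi, chrom_length)
    if lo == hi:
        log.warning("%s for %s is empty after clipping", kind, t.transcript_id)
    anchor = t.cds_end
    if kind in (SL_WINDOW, PAS_WINDOW):
        anchor = min(max(anchor, lo), hi)
    return ScanWindow(
        gene_id=t.gene_id,
        transcript_id=t.transcript_id,
        chrom=t.chrom,
        strand=t.strand,
        start=lo,
        end=hi,
        anchor=anchor,
        kind=kind,
        crosses_intron=_crosses_intron(t, lo, hi),
    )


def sl_window(t: TranscriptModel, chrom_length: Optional[int] = None) -> ScanWindow:
    """Stem-loop scan window: CDS start to CDS end + 600 bp (transcriptional)."""
    if t.strand == "+":
        lo, hi = t.cds_lo, t.cds_hi + SL_WINDOW_DOWNSTREAM
    else:
        lo, hi = t.cds_lo - SL_WINDOW_DOWNSTREAM, t.cds_hi
    return _make_window(t, lo, hi, SL_WINDOW, chrom_length)


def pas_window(t: TranscriptModel, chrom_length: Optional[int] = None) -> ScanWindow:
    """PAS scan window: CDS end to (3'UTR end if annotated, else CDS end) + 2 kb."""
    ext = t.utr3_extent() + PAS_WINDOW_DOWNSTREAM
    if t.strand == "+":
        lo, hi = t.cds_hi, t.cds_hi + ext
    else:
        lo, hi = t.cds_lo - ext, t.cds_lo
    return _make_window(t, lo, hi, PAS_WINDOW, chrom_length)


def pas_fallback_window(
    t: TranscriptModel,
    extension: int = PAS_FALLBACK_EXTENSION,
    chrom_length: Optional[int] = None,
) -> ScanWindow:
    """Fallback PAS window: the ``extension`` bp past CDS end + 2 kb.

    Consulted when poly(A)+ signal loss lies beyond the primary 2-kb region.
    """
    if extension <= 0:
        raise AnnotationError("fallback extension must be positive")
    off = PAS_WINDOW_DOWNSTREAM
    if t.strand == "+":
        lo, hi = t.cds_hi + off, t.cds_hi + off + extension
    else:
        lo, hi = t.cds_lo - off - extension, t.cds_lo - off
    return _make_window(t, lo, hi, PAS_FALLBACK_WINDOW, chrom_length)


# --------------------------------------------------------------------------
# GTF parsing / writing
# --------------------------------------------------------------------------

_UTR_TYPES = {"utr", "three_prime_utr", "3utr", "five_prime_utr", "5utr"}


def parse_annotation(
    annotation_file: str, genome: Optional[Genome] = None
) -> list[TranscriptModel]:
    """Parse a Gencode-dialect GTF into TranscriptModels (one per CDS transcript).

    Transcripts without a CDS are skipped (the skip count is logged).
    stop_codon features, which Gencode keeps out of the CDS rows, are folded
    into the CDS extent so that "CDS end" means the ORF end including the
    stop.  Coordinates convert from 1-based inclusive GTF to the internal
    0-based half-open convention.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with open(annotation_file) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise GTFParseError(
                    f"{annotation_file}: malformed GTF at line {lineno}: {exc}"
                ) from exc
            ftype = f.featuretype.lower()
            if ftype == "gene":
                continue
            try:
                tx_id = f.attributes["transcript_id"][0]
            except KeyError as exc:
                raise GTFParseError(
                    f"{annotation_file}: line {lineno} lacks transcript_id"
                ) from exc
            if genome is not None and f.seqid not in genome:
                raise ReferenceMismatchError(
                    f"line {lineno}: chromosome {f.seqid!r} absent from genome"
                )
            rec = per_tx.get(tx_id)
            if rec is None:
                rec = per_tx[tx_id] = {
                    "gene_id": f.attributes.get("gene_id", [tx_id])[0],
                    "gene_name": f.attributes.get("gene_name", [""])[0],
                    "chrom": f.seqid,
                    "strand": f.strand,
                    "exons": [],
                    "cds": [],
                    "utr": [],
                }
                order.append(tx_id)
            lo, hi = f.start - 1, f.end
            if ftype == "exon":
                rec["exons"].append((lo, hi))
            elif ftype in ("cds", "stop_codon"):
                rec["cds"].append((lo, hi))
            elif ftype in _UTR_TYPES:
                rec["utr"].append((lo, hi))

    models: list[TranscriptModel] = []
    n_skipped = 0
    for tx_id in order:
        rec = per_tx[tx_id]
        if not rec["cds"]:
            n_skipped += 1
            continue
        cds_lo = min(lo for lo, _ in rec["cds"])
        cds_hi = max(hi for _, hi in rec["cds"])
        exons = sorted(rec["exons"]) or [(cds_lo, cds_hi)]
        strand = rec["strand"]
        # 3'UTR: UTR features at/downstream of the CDS end in transcriptional
        # direction; if several, the farthest end wins.
        if strand == "+":
            ends = [hi for lo, hi in rec["utr"] if lo >= cds_hi]
            utr3_end = max(ends) if ends else None
        else:
            ends = [lo for lo, hi in rec["utr"] if hi <= cds_lo]
            utr3_end = min(ends) if ends else None
        models.append(
            TranscriptModel(
                gene_id=rec["gene_id"],
                transcript_id=tx_id,
                chrom=rec["chrom"],
                strand=strand,
                exons=tuple(exons),
                cds_lo=cds_lo,
                cds_hi=cds_hi,
                utr3_end=utr3_end,
                gene_name=rec["gene_name"],
            )
        )
    if n_skipped:
        log.info("skipped %d transcript(s) without CDS", n_skipped)
    parse_annotation.last_skip_count = n_skipped  # type: ignore[attr-defined]
    return models


def transcripts_to_gtf(transcripts: Sequence[TranscriptModel], source: str = "histone3p") -> str:
    """Serialise TranscriptModels back to Gencode-dialect GTF text.

    Emits gene, transcript, exon, CDS and (where ``utr3_end`` is set and
    extends past the CDS end) UTR rows.  Re-parsing the output recovers the
    same internal coordinates.
    """
    lines: list[str] = []

    def row(t: TranscriptModel, ftype: str, lo: int, hi: int, attrs: str) -> None:
        lines.append(
            "\t".join(
                (t.chrom, source, ftype, str(lo + 1), str(hi), ".", t.strand, ".", attrs)
            )
        )

    seen_genes: set[str] = set()
    for t in transcripts:
        gattrs = f'gene_id "{t.gene_id}"; gene_name "{t.gene_name or t.gene_id}";'
        tattrs = f'{gattrs} transcript_id "{t.transcript_id}";'
        span_lo = min(t.exons[0][0], t.cds_lo)
        span_hi = max(t.exons[-1][1], t.cds_hi)
        if t.utr3_end is not None:
            span_lo = min(span_lo, t.utr3_end)
            span_hi = max(span_hi, t.utr3_end)
        if t.gene_id not in seen_genes:
            seen_genes.add(t.gene_id)
            row(t, "gene", span_lo, span_hi, gattrs)
        row(t, "transcript", span_lo, span_hi, tattrs)
        for lo, hi in t.exons:
            row(t, "exon", lo, hi, tattrs)
        for lo, hi in t.exons:
            clo, chi = max(lo, t.cds_lo), min(hi, t.cds_hi)
            if clo < chi:
                row(t, "CDS", clo, chi, tattrs)
        if t.utr3_end is not None and t.utr3_extent() > 0:
            if t.strand == "+":
                row(t, "UTR", t.cds_hi, t.utr3_end, tattrs)
            else:
                row(t, "UTR", t.utr3_end, t.cds_lo, tattrs)
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Histone transcript selection
# --------------------------------------------------------------------------

Selector = Union[None, str, Iterable[str]]


def select_histone_transcripts(
    transcripts: Sequence[TranscriptModel], selector: Selector = None
) -> list[TranscriptModel]:
    """Select histone transcripts; multiple isoforms per gene are kept.

    ``selector`` may be ``None`` (packaged default: DEFAULT_HISTONE_GENES
    plus any gene named ``HIST*``), a regular expression applied to gene
    name and gene id, or an explicit collection of gene names/ids
    (transcript version suffixes are ignored when matching ids).
    """
    if selector is None:
        def match(t: TranscriptModel) -> bool:
            name = t.gene_name or t.gene_id
            return name in DEFAULT_HISTONE_GENES or name.startswith("HIST")
    elif isinstance(selector, str):
        pat = re.compile(selector)
        def match(t: TranscriptModel) -> bool:
            return bool(pat.search(t.gene_name) or pat.search(t.gene_id))
    else:
        wanted = {s.split(".")[0] for s in selector}
        if not wanted:
            raise AnnotationError("selector must be non-empty")
        def match(t: TranscriptModel) -> bool:
            return (
                t.gene_name in wanted
                or t.gene_id in wanted
                or t.gene_id.split(".")[0] in wanted
            )
    out = [t for t in transcripts if match(t)]
    if not out:
        log.warning("histone selector matched no transcripts")
    return out


def build_windows(
    transcripts: Sequence[TranscriptModel],
    genome: Optional[Genome] = None,
    fallback_extension: int = PAS_FALLBACK_EXTENSION,
) -> list[ScanWindow]:
    """SL, PAS and fallback windows for every transcript, clipped to the genome."""
    windows: list[ScanWindow] = []
    for t in transcripts:
        clen = len(genome[t.chrom]) if genome is not None else None
        windows.append(sl_window(t, clen))
        windows.append(pas_window(t, clen))
        windows.append(pas_fallback_window(t, fallback_extension, clen))
    return windows


def write_windows_tsv(windows: Sequence[ScanWindow], path: str) -> None:
    cols = "gene_id transcript_id chrom strand window_kind start end anchor crosses_intron".split()
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for w in windows:
            fh.write(
                "\t".join(
                    map(
                        str,
                        (w.gene_id, w.transcript_id, w.chrom, w.strand, w.kind,
                         w.start, w.end, w.anchor, int(w.crosses_intron)),
                    )
                )
                + "\n"
            )
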