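"""Coverage-based scoring of stem-loop vs poly(A) isoform usage and gene calls.

The four fraction-specific RNA-seq libraries — poly(A)− and poly(A)+, each
in S and G1 phase — carry the diagnostic signal: a replication-dependent
(RD) histone gene shows S-phase-restricted poly(A)− coverage ending
abruptly just past the stem-loop; a replication-independent (RI) gene shows
poly(A)+ coverage throughout the cycle ending at a polyadenylation site; a
hybrid gene (the H2A.X pattern) shows both.  "Abrupt signal loss" is
formalised as a drop ratio: the mean library-scaled coverage over a flank
upstream of the candidate cleavage position divided by the mean over the
downstream flank (pseudocount-stabilised).  A site is *used* when the
upstream mean clears a minimum-signal floor and the drop ratio clears a
threshold.  The call table is then forced:

======== ==================== =====================
call     SL used (pA− S)      PAS used (pA+, S or G1)
======== ==================== =====================
RD       yes                  no
RI       no                   yes
hybrid   yes                  yes
======== ==================== =====================

anything else is ``unclassified``.  All thresholds live in
:class:`ClassifierConfig` and are echoed into every output.

The same scaled tracks yield an estimate of S-phase contamination of the
G1-sorted fraction: for genes called RD, residual G1 poly(A)− signal over
the stem-loop region can only come from contaminating S-phase cells, so the
median over genes of the G1/S coverage ratio estimates the contaminating
fraction.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from .annotation import Genome, ScanWindow, TranscriptModel
from .motifs import (
    PASHit,
    StemLoopHit,
    choose_pas,
    scan_pas,
    scan_stem_loops,
)

log = logging.getLogger(__name__)

PA_MINUS = "pA_minus"
PA_PLUS = "pA_plus"
PHASES = ("S", "G1")
LIBRARIES = ((PA_MINUS, "S"), (PA_MINUS, "G1"), (PA_PLUS, "S"), (PA_PLUS, "G1"))

RD = "RD"
RI = "RI"
HYBRID = "hybrid"
UNCLASSIFIED = "unclassified"


class CoverageError(ValueError):
    """Problem loading or combining coverage tracks."""


class ClassificationError(ValueError):
    """Problem producing a gene call or a contamination estimate."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the drop-ratio classifier.

    sl_cleavage_offset : bp past the stem-loop 3' end taken as the 3'
        terminus of the SL-processed mRNA (default 5).
    pas_cleavage_offset : bp past the PAS hexamer start taken as the
        poly(A) cleavage position (default 20).
    flank : bp on each side of a cleavage position over which mean
        coverage is taken (default 100).
    drop_ratio_min : minimum upstream/downstream mean ratio to call a
        site used (default 5).
    min_signal : minimum scaled upstream mean (per-million units) to
        attempt a call (default 1.0).
    min_readthrough_frac : minimum poly(A)+ signal past the stem-loop,
        as a fraction of the SL-region poly(A)− signal, required to
        credit a poly(A) isoform to a gene that has a stem-loop
        (default 0.1).
    pseudocount : added to both means before forming the ratio (0.01).
    """

    sl_cleavage_offset: int = 5
    pas_cleavage_offset: int = 20
    flank: int = 100
    drop_ratio_min: float = 5.0
    min_signal: float = 1.0
    min_readthrough_frac: float = 0.1
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "sl_cleavage_offset", "pas_cleavage_offset", "flank",
            "drop_ratio_min", "min_signal", "min_readthrough_frac", "pseudocount",
        ):
            if getattr(self, name) <= 0:
                raise ClassificationError(f"config field {name} must be > 0")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ClassifierConfig":
        """Load from JSON or YAML (by extension; YAML is a JSON superset here)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls(**data)


@dataclass
class FractionCoverage:
    """Per-base, strand-resolved coverage for one (fraction × phase) library.

    ``values`` maps chromosome name to a float array of per-base coverage.
    ``scale()`` converts to per-million-of-library units exactly once (the
    ``scaled`` flag records it, so scaling is idempotent).
    """

    fraction: str
    phase: str
    strand: str
    values: dict[str, np.ndarray]
    library_size: float
    scaled: bool = False

    def scale(self) -> "FractionCoverage":
        if not self.scaled:
            if self.library_size <= 0:
                raise CoverageError("library_size must be positive")
            factor = self.library_size / 1e6
            for arr in self.values.values():
                arr /= factor
            self.scaled = True
        return self

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Mean coverage over [start, end), clipped to the chromosome."""
        arr = self.values.get(chrom)
        if arr is None:
            return 0.0
        lo, hi = max(0, start), min(len(arr), end)
        if hi <= lo:
            if start != end:
                log.warning("flank [%d,%d) on %s empty after clipping", start, end, chrom)
            return 0.0
        return float(arr[lo:hi].mean())


class CoverageSet:
    """The collection of stranded tracks keyed by (fraction, phase, strand)."""

    def __init__(self, tracks: Iterable[FractionCoverage]):
        self._tracks: dict[tuple[str, str, str], FractionCoverage] = {}
        for t in tracks:
            key = (t.fraction, t.phase, t.strand)
            if key in self._tracks:
                raise CoverageError(f"duplicate track for {key}")
            self._tracks[key] = t

    def get(self, fraction: str, phase: str, strand: str) -> Optional[FractionCoverage]:
        return self._tracks.get((fraction, phase, strand))

    def require(self, fraction: str, phase: str, strand: str) -> FractionCoverage:
        t = self.get(fraction, phase, strand)
        if t is None:
            raise CoverageError(f"missing coverage track ({fraction}, {phase}, {strand})")
        return t

    def has_phase(self, phase: str) -> bool:
        return any(k[1] == phase for k in self._tracks)

    def __iter__(self):
        return iter(self._tracks.values())

    def __len__(self) -> int:
        return len(self._tracks)


def _read_bedgraph(path: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
        )
    except pd.errors.EmptyDataError:
        log.warning("bedGraph %s is empty; track will be all zero", path)
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    df = df[~df["chrom"].astype(str).str.startswith("track")]
    return df


def load_coverage(
    manifest: Union[str, Path, pd.DataFrame],
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> CoverageSet:
    """Load bedGraph tracks per a manifest and scale each to its library size.

    The manifest (TSV or DataFrame) needs columns
    ``file, fraction, phase, strand, library_size``; relative file paths
    resolve against the manifest's directory.  Overlapping intervals within
    a file are an error (the message names the interval), as is a
    chromosome absent from ``chrom_sizes`` when sizes are given; when they
    are not, array lengths default to the largest interval end seen per
    chromosome across all files.  Missing regions are zero.
    """
    if isinstance(manifest, (str, Path)):
        base = Path(manifest).parent
        mf = pd.read_csv(manifest, sep="\t")
        mf["file"] = [str(base / f) for f in mf["file"]]
    else:
        mf = manifest.copy()
    required = {"file", "fraction", "phase", "strand", "library_size"}
    if not required.issubset(mf.columns):
        raise CoverageError(f"manifest lacks columns {sorted(required - set(mf.columns))}")

    frames = [(row, _read_bedgraph(row["file"])) for _, row in mf.iterrows()]
    if chrom_sizes is None:
        sizes: dict[str, int] = {}
        for _, df in frames:
            for chrom, end in df.groupby("chrom")["end"].max().items():
                sizes[str(chrom)] = max(sizes.get(str(chrom), 0), int(end))
    else:
        sizes = dict(chrom_sizes)

    tracks = []
    for row, df in frames:
        values = {chrom: np.zeros(length, dtype=float) for chrom, length in sizes.items()}
        for chrom, sub in df.groupby("chrom", sort=False):
            chrom = str(chrom)
            if chrom not in values:
                raise CoverageError(f"{row['file']}: unknown chromosome {chrom!r}")
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts >= ends).any():
                i = int(np.argmax(starts >= ends))
                raise CoverageError(
                    f"{row['file']}: empty/inverted interval {chrom}:{starts[i]}-{ends[i]}"
                )
            bad = np.nonzero(starts[1:] < ends[:-1])[0]
            if bad.size:
                i = int(bad[0]) + 1
                raise CoverageError(
                    f"{row['file']}: overlapping interval {chrom}:{starts[i]}-{ends[i]}"
                )
            arr = values[chrom]
            for s, e, v in zip(starts, ends, sub["value"].to_numpy()):
                if e > len(arr):
                    raise CoverageError(
                        f"{row['file']}: interval {chrom}:{s}-{e} beyond chromosome end"
                    )
                arr[s:e] = v
        tracks.append(
            FractionCoverage(
                fraction=str(row["fraction"]),
                phase=str(row["phase"]),
                strand=str(row["strand"]),
                values=values,
                library_size=float(row["library_size"]),
            ).scale()
        )
    return CoverageSet(tracks)


# --------------------------------------------------------------------------
# Site scoring
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class UsageScore:
    """Drop-ratio evidence at one candidate cleavage position on one track."""

    site_kind: str                 # "SL" or "PAS"
    motif: str
    chrom: str
    strand: str
    cleavage_pos: int              # boundary coordinate on the forward axis
    fraction: str
    phase: str
    upstream_mean: float
    downstream_mean: float
    drop_ratio: float
    used: bool
    upstream_region: tuple[int, int]


def _flank_regions(pos: int, strand: str, flank: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """(upstream, downstream) genomic intervals around a cleavage boundary."""
    if strand == "+":
        return (pos - flank, pos), (pos, pos + flank)
    return (pos, pos + flank), (pos - flank, pos)


def score_site(
    cov: FractionCoverage,
    chrom: str,
    cleavage_pos: int,
    strand: str,
    cfg: ClassifierConfig,
    site_kind: str = "PAS",
    motif: str = "",
) -> UsageScore:
    """Score "abrupt signal loss" at a cleavage boundary on one track."""
    up_region, down_region = _flank_regions(cleavage_pos, strand, cfg.flank)
    up = cov.mean(chrom, *up_region)
    down = cov.mean(chrom, *down_region)
    ratio = (up + cfg.pseudocount) / (down + cfg.pseudocount)
    used = up >= cfg.min_signal and ratio >= cfg.drop_ratio_min
    return UsageScore(
        site_kind=site_kind,
        motif=motif,
        chrom=chrom,
        strand=strand,
        cleavage_pos=cleavage_pos,
        fraction=cov.fraction,
        phase=cov.phase,
        upstream_mean=up,
        downstream_mean=down,
        drop_ratio=ratio,
        used=used,
        upstream_region=up_region,
    )


def _tx_to_genomic(anchor: int, strand: str, t: int) -> int:
    """Boundary coordinate ``t`` bases past ``anchor`` in transcriptional direction."""
    return anchor + t if strand == "+" else anchor - t


def sl_cleavage_position(t: TranscriptModel, hit: StemLoopHit, cfg: ClassifierConfig) -> int:
    off = hit.offset_from_cds_end + len(hit.motif) + cfg.sl_cleavage_offset
    return _tx_to_genomic(t.cds_end, t.strand, off)


def pas_cleavage_position(t: TranscriptModel, hit: PASHit, cfg: ClassifierConfig) -> int:
    off = hit.distance_from_cds_end + cfg.pas_cleavage_offset
    return _tx_to_genomic(t.cds_end, t.strand, off)


# --------------------------------------------------------------------------
# Gene calls
# --------------------------------------------------------------------------

@dataclass
class GeneCall:
    """Per-gene classification with the evidence that produced it."""

    gene_id: str
    call: str
    transcript_id: str
    sl_used_S_pAminus: bool
    pas_used_pAplus: bool
    scores: list[UsageScore] = field(default_factory=list)
    sl_region: Optional[tuple[str, int, int, str]] = None  # chrom, start, end, strand
    notes: list[str] = field(default_factory=list)
    config: Optional[ClassifierConfig] = None


def _call_from_flags(sl_used: bool, pas_used: bool, sl_present: bool) -> str:
    if sl_used and pas_used:
        return HYBRID
    if sl_used:
        return RD
    if pas_used and not sl_used:
        # RI requires the stem-loop to be absent or unused; both reduce to
        # "not used" here, the distinction is kept in the notes.
        return RI
    return UNCLASSIFIED


def _pas_usage(
    t: TranscriptModel,
    hit: PASHit,
    coverage: CoverageSet,
    cfg: ClassifierConfig,
    best_sl: Optional[UsageScore],
    scores: list[UsageScore],
) -> bool:
    """Evaluate one candidate PAS on poly(A)+ S (and G1 when present)."""
    pos = pas_cleavage_position(t, hit, cfg)
    phase_scores = []
    for phase in PHASES:
        cov = coverage.get(PA_PLUS, phase, t.strand)
        if cov is None:
            continue
        s = score_site(cov, t.chrom, pos, t.strand, cfg, "PAS", hit.motif)
        scores.append(s)
        phase_scores.append(s)
    used = any(s.used for s in phase_scores)
    if used and best_sl is not None:
        # A gene with a stem-loop only earns a poly(A) isoform if poly(A)+
        # signal actually reads through past the SL cleavage point.
        sl_pos = best_sl.cleavage_pos
        _, down_region = _flank_regions(sl_pos, t.strand, cfg.flank)
        readthrough = max(
            (
                coverage.get(PA_PLUS, phase, t.strand).mean(t.chrom, *down_region)
                for phase in PHASES
                if coverage.get(PA_PLUS, phase, t.strand) is not None
            ),
            default=0.0,
        )
        frac = readthrough / (best_sl.upstream_mean + cfg.pseudocount)
        if frac < cfg.min_readthrough_frac:
            used = False
    return used


def classify_gene(
    transcripts: Sequence[TranscriptModel],
    sl_hits: Sequence[StemLoopHit],
    pas_hits: Sequence[PASHit],
    coverage: CoverageSet,
    cfg: Optional[ClassifierConfig] = None,
) -> GeneCall:
    """Combine motif hits and fraction coverage into one RD/RI/hybrid call.

    ``transcripts`` are the isoforms of a single gene; ``sl_hits`` and
    ``pas_hits`` are their motif hits (PAS hits may come from both the
    primary and the fallback window — the fallback is consulted only when
    the primary window yields no used PAS *and* poly(A)+ signal is still
    present at the primary window's end, i.e. the signal loss lies further
    downstream).  Stem-loop usage is evaluated on the poly(A)− S track;
    PAS usage on poly(A)+ in S and, when available, G1 (either suffices).
    The gene call follows the transcript with the strongest stem-loop
    usage.
    """
    if not transcripts:
        raise ClassificationError("classify_gene called with no transcripts")
    cfg = cfg or ClassifierConfig()
    gene_id = transcripts[0].gene_id
    notes: list[str] = []

    best: Optional[dict] = None
    sl_by_tx: dict[str, list[StemLoopHit]] = {}
    for h in sl_hits:
        sl_by_tx.setdefault(h.transcript_id, []).append(h)
    pas_by_tx: dict[str, list[PASHit]] = {}
    for h in pas_hits:
        pas_by_tx.setdefault(h.transcript_id, []).append(h)

    for t in transcripts:
        coverage.require(PA_MINUS, "S", t.strand)
        coverage.require(PA_PLUS, "S", t.strand)
        scores: list[UsageScore] = []
        pa_minus_S = coverage.get(PA_MINUS, "S", t.strand)

        # Stem-loop usage: poly(A)- S track at the SL cleavage position.
        best_sl: Optional[UsageScore] = None
        for h in sl_by_tx.get(t.transcript_id, []):
            pos = sl_cleavage_position(t, h, cfg)
            s = score_site(pa_minus_S, t.chrom, pos, t.strand, cfg, "SL", h.motif)
            scores.append(s)
            if best_sl is None or (s.used, s.drop_ratio) > (best_sl.used, best_sl.drop_ratio):
                best_sl = s
        sl_used = best_sl is not None and best_sl.used

        # PAS usage: primary window first, fallback only on downstream signal.
        tx_pas = pas_by_tx.get(t.transcript_id, [])
        primary = choose_pas([h for h in tx_pas if h.window_kind == ann.PAS_WINDOW])
        pas_used = False
        if primary is not None:
            pas_used = _pas_usage(t, primary, coverage, cfg, best_sl, scores)
        if not pas_used:
            fallback = choose_pas(
                [h for h in tx_pas if h.window_kind == ann.PAS_FALLBACK_WINDOW]
            )
            if fallback is not None and _readthrough_past_primary(t, coverage, cfg):
                notes.append(f"{t.transcript_id}: fallback PAS window consulted")
                pas_used = _pas_usage(t, fallback, coverage, cfg, best_sl, scores)

        if len(t.exons) > 1:
            notes.append(f"{t.transcript_id}: spliced isoform; windows are genomic")

        key = (
            sl_used,
            best_sl.drop_ratio if best_sl is not None else 0.0,
            pas_used,
        )
        if best is None or key > best["key"]:
            best = {
                "key": key,
                "transcript": t,
                "sl_used": sl_used,
                "pas_used": pas_used,
                "best_sl": best_sl,
                "scores": scores,
            }

    assert best is not None
    t = best["transcript"]
    sl_region = None
    if best["best_sl"] is not None:
        lo, hi = best["best_sl"].upstream_region
        sl_region = (t.chrom, lo, hi, t.strand)
    return GeneCall(
        gene_id=gene_id,
        call=_call_from_flags(best["sl_used"], best["pas_used"], best["best_sl"] is not None),
        transcript_id=t.transcript_id,
        sl_used_S_pAminus=best["sl_used"],
        pas_used_pAplus=best["pas_used"],
        scores=best["scores"],
        sl_region=sl_region,
        notes=notes,
        config=cfg,
    )


def _readthrough_past_primary(
    t: TranscriptModel, coverage: CoverageSet, cfg: ClassifierConfig
) -> bool:
    """True when poly(A)+ signal persists at the end of the primary PAS window."""
    end_t = t.utr3_extent() + ann.PAS_WINDOW_DOWNSTREAM
    pos = _tx_to_genomic(t.cds_end, t.strand, end_t)
    up_region, _ = _flank_regions(pos, t.strand, cfg.flank)
    for phase in PHASES:
        cov = coverage.get(PA_PLUS, phase, t.strand)
        if cov is not None and cov.mean(t.chrom, *up_region) >= cfg.min_signal:
            return True
    return False


def classify_genes(
    transcripts: Sequence[TranscriptModel],
    genome: Genome,
    coverage: CoverageSet,
    cfg: Optional[ClassifierConfig] = None,
    fallback_extension: int = ann.PAS_FALLBACK_EXTENSION,
) -> list[GeneCall]:
    """Full pipeline over many genes: windows → motif scans → gene calls."""
    cfg = cfg or ClassifierConfig()
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    calls = []
    for gene_id, txs in by_gene.items():
        sl_hits: list[StemLoopHit] = []
        pas_hits: list[PASHit] = []
        for t in txs:
            clen = len(genome[t.chrom])
            sl_hits.extend(scan_stem_loops(genome, ann.sl_window(t, clen)))
            pas_hits.extend(scan_pas(genome, ann.pas_window(t, clen)))
            pas_hits.extend(
                scan_pas(genome, ann.pas_fallback_window(t, fallback_extension, clen))
            )
        calls.append(classify_gene(txs, sl_hits, pas_hits, coverage, cfg))
    return calls


# --------------------------------------------------------------------------
# Contamination estimate
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContaminationEstimate:
    """Estimated S-phase cell fraction in the G1-sorted sample."""

    fraction_hat: float
    n_genes: int
    per_gene: dict[str, float]


def estimate_contamination(
    coverage: CoverageSet,
    calls: Sequence[GeneCall],
    cfg: Optional[ClassifierConfig] = None,
) -> ContaminationEstimate:
    """Median over RD genes of (G1 / S) poly(A)− coverage over the SL region.

    Residual stem-loop mRNA signal in a G1-sorted poly(A)− library can only
    come from contaminating S-phase cells, so for each gene called RD the
    ratio of scaled G1 to S coverage over its stem-loop region estimates
    the contaminating cell fraction; the median across genes is robust to
    single aberrant genes.  Requires at least 3 usable RD genes.
    """
    cfg = cfg or ClassifierConfig()
    per_gene: dict[str, float] = {}
    for call in calls:
        if call.call != RD or call.sl_region is None:
            continue
        chrom, lo, hi, strand = call.sl_region
        cov_s = coverage.require(PA_MINUS, "S", strand)
        cov_g1 = coverage.require(PA_MINUS, "G1", strand)
        s_mean = cov_s.mean(chrom, lo, hi)
        if s_mean < cfg.min_signal:
            continue
        per_gene[call.gene_id] = cov_g1.mean(chrom, lo, hi) / s_mean
    if len(per_gene) < 3:
        raise ClassificationError(
            f"only {len(per_gene)} RD gene(s) usable for the contamination "
            "estimate (need >= 3); consider relaxing min_signal or drop_ratio_min"
        )
    fraction_hat = float(np.clip(np.median(list(per_gene.values())), 0.0, 1.0))
    return ContaminationEstimate(
        fraction_hat=fraction_hat, n_genes=len(per_gene), per_gene=per_gene
    )


# --------------------------------------------------------------------------
# Output
# --------------------------------------------------------------------------

def gene_calls_frame(calls: Sequence[GeneCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        sl = next((s for s in c.scores if s.site_kind == "SL"), None)
        pas = next((s for s in c.scores if s.site_kind == "PAS" and s.used), None)
        if pas is None:
            pas = next((s for s in c.scores if s.site_kind == "PAS"), None)
        rows.append(
            {
                "gene_id": c.gene_id,
                "call": c.call,
                "transcript_id": c.transcript_id,
                "sl_used_S_pAminus": c.sl_used_S_pAminus,
                "pas_used_pAplus": c.pas_used_pAplus,
                "sl_drop_ratio": sl.drop_ratio if sl else np.nan,
                "sl_upstream_mean": sl.upstream_mean if sl else np.nan,
                "pas_drop_ratio": pas.drop_ratio if pas else np.nan,
                "pas_upstream_mean": pas.upstream_mean if pas else np.nan,
                "notes": "; ".join(c.notes),
            }
        )
    return pd.DataFrame(rows)


def write_gene_calls(calls: Sequence[GeneCall], path: str) -> None:
    """Gene-call TSV with the classifier configuration echoed in the header."""
    cfg = calls[0].config if calls and calls[0].config else ClassifierConfig()
    with open(path, "w") as fh:
        fh.write("# classifier_config: " + json.dumps(cfg.as_dict(), sort_keys=True) + "\n")
        gene_calls_frame(calls).to_csv(fh, sep="\t", index=False)


def write_contamination(est: ContaminationEstimate, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "fraction_hat": est.fraction_hat,
                "n_genes": est.n_genes,
                "per_gene": est.per_gene,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
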