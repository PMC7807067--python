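"""Self-contained synthetic fixture: toy genome, GTF, four-library coverage.

The generator lays out intronless histone-like genes on one contig,
alternating strands, and emulates the track structure the classifier
assumes:

* an RD gene carries one stem-loop motif past its CDS end and expresses
  poly(A)− coverage in S phase only, ending abruptly at the SL cleavage
  position; the G1 poly(A)− track carries a small multiple of that signal
  modelling S-phase contamination of the G1-sorted fraction (3% by
  default);
* an RI gene carries one PAS hexamer and expresses poly(A)+ coverage in
  both S and G1, ending at the poly(A) cleavage position;
* a hybrid gene carries both motifs and splits its expression between the
  two isoforms (``hybrid_pa_fraction`` on the poly(A)+ isoform).

Background sequence is rejection-sampled so that none of the 12 stem-loop
motifs nor the 4 PAS hexamers occurs, on either strand, outside the planted
positions — an exhaustive scan of an emitted genome finds exactly the
planted motifs.  Count noise is negative-binomial per 10-bp bin
(variance = mu + dispersion * mu^2); dispersion 0 is the noise-free limit in
which realised coverage equals its expectation exactly.  Cleavage is
rendered as a hard step to zero, matching the abrupt-signal-loss
idealisation; an optional 20-bp linear taper exercises classifier
robustness.  A fixed seed makes every output byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import Genome, GenomeSequence, TranscriptModel, transcripts_to_gtf, write_fasta
from .classify import (
    CoverageSet,
    FractionCoverage,
    LIBRARIES,
    PA_MINUS,
    PA_PLUS,
)
from .motifs import PAS_MOTIFS, STEM_LOOP_MOTIFS, reverse_complement

log = logging.getLogger(__name__)

CHROM = "chrSYN1"
RD, RI, HYBRID = "RD", "RI", "hybrid"

_DEFAULT_LIBRARY_SIZES = {
    (PA_MINUS, "S"): 1e6,
    (PA_MINUS, "G1"): 1e6,
    (PA_PLUS, "S"): 1e6,
    (PA_PLUS, "G1"): 1e6,
}


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic dataset.

    Defaults model a well-expressed histone locus: 400-bp CDS, stem-loop
    35 bp and PAS 150 bp past the CDS end (typical spacings for human
    histone genes), mean scaled coverage 200 over expressed regions,
    mild overdispersion, and 3% S-phase contamination of the G1 fraction.
    """

    n_rd: int = 10
    n_ri: int = 10
    n_hybrid: int = 10
    gene_length: int = 400          # CDS length, bp
    spacer_length: int = 3000       # intergenic spacer, bp
    tail_length: int = 400          # reserved region past the CDS end, bp
    sl_offset: int = 35             # SL motif start, bp past CDS end
    pas_distance: int = 150         # PAS hexamer start, bp past CDS end
    sl_cleavage_offset: int = 5     # SL mRNA 3' end, bp past SL 3' end
    pas_cleavage_offset: int = 20   # poly(A) cleavage, bp past PAS start
    expression_mean: float = 200.0  # expected per-base coverage, raw counts
    nb_dispersion: float = 0.05     # NB dispersion; 0 = deterministic
    contamination: float = 0.03     # S-phase fraction in the G1 sample
    hybrid_pa_fraction: float = 0.3  # share of hybrid signal on the pA+ isoform
    sl_variant_index: Optional[int] = None  # fixed SL variant, or cycle all 12
    pas_motif: str = "AATAAA"
    decoy_pas_motif: Optional[str] = None   # extra, weaker hexamer per RI/hybrid gene
    decoy_pas_extra: int = 500      # decoy distance past the real PAS
    taper: bool = False             # 20-bp linear taper after cleavage
    bin_size: int = 10
    library_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_LIBRARY_SIZES))
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rd, self.n_ri, self.n_hybrid) < 0:
            raise SimulationError("gene counts must be >= 0")
        if not 0.0 <= self.contamination <= 1.0:
            raise SimulationError("contamination must be in [0, 1]")
        if not 0.0 <= self.hybrid_pa_fraction <= 1.0:
            raise SimulationError("hybrid_pa_fraction must be in [0, 1]")
        if self.nb_dispersion < 0:
            raise SimulationError("nb_dispersion must be >= 0")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["library_sizes"] = {f"{fr}:{ph}": v for (fr, ph), v in self.library_sizes.items()}
        return d


# --------------------------------------------------------------------------
# Genome construction
# --------------------------------------------------------------------------

_FORBIDDEN = tuple(
    sorted(
        set(STEM_LOOP_MOTIFS)
        | set(PAS_MOTIFS)
        | {reverse_complement(m) for m in STEM_LOOP_MOTIFS}
        | {reverse_complement(m) for m in PAS_MOTIFS}
    )
)
_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")


def random_motif_free_sequence(length: int, rng: np.random.Generator) -> str:
    """Random sequence guaranteed free of SL/PAS motifs on both strands."""
    seq, _ = _purge_forbidden(list(rng.choice(_BASES, size=length)), set(), rng)
    return "".join(seq)


def _find_all(hay: str, needle: str) -> list[int]:
    out, p = [], hay.find(needle)
    while p != -1:
        out.append(p)
        p = hay.find(needle, p + 1)
    return out


def _purge_forbidden(
    seq: list[str], protected: set[int], rng: np.random.Generator, max_iter: int = 1000
) -> tuple[list[str], int]:
    """Resample bases until no forbidden motif occurs outside protected spans."""
    for it in range(max_iter):
        s = "".join(seq)
        dirty: set[int] = set()
        for motif in _FORBIDDEN:
            for p in _find_all(s, motif):
                span = range(p, p + len(motif))
                if all(i in protected for i in span):
                    continue
                dirty.update(i for i in span if i not in protected)
        if not dirty:
            return seq, it
        for i in dirty:
            seq[i] = str(rng.choice(_BASES))
    raise SimulationError(
        "rejection sampling failed 1000 consecutive times; motif set too dense "
        "for the requested spacer"
    )


def _gene_classes(cfg: SimulationConfig) -> list[str]:
    return [RD] * cfg.n_rd + [RI] * cfg.n_ri + [HYBRID] * cfg.n_hybrid


def build_genome(
    cfg: SimulationConfig,
) -> tuple[dict[str, GenomeSequence], list[TranscriptModel], pd.DataFrame]:
    """Emit the toy genome, transcript models and ground-truth table.

    Genes are laid out alternately on + and − strands, one per unit of
    ``gene_length + tail_length + spacer_length`` bp (a leading spacer pads
    the contig so upstream windows of the first gene stay on-sequence).
    RD and hybrid genes carry one stem-loop motif at ``sl_offset``; RI and
    hybrid genes one PAS hexamer at ``pas_distance``.  Genes at even index
    get an annotated 3'UTR ending at their cleavage position, exercising
    the UTR-aware PAS window branch; odd genes carry no UTR feature.
    """
    rng = np.random.default_rng(cfg.seed)
    classes = _gene_classes(cfg)
    unit = cfg.gene_length + cfg.tail_length + cfg.spacer_length
    total = cfg.spacer_length + unit * len(classes) + cfg.tail_length
    seq = list(rng.choice(_BASES, size=total))

    protected: set[int] = set()
    transcripts: list[TranscriptModel] = []
    rows: list[dict] = []

    def plant(motif: str, lo: int, strand: str) -> None:
        written = motif if strand == "+" else reverse_complement(motif)
        for k, base in enumerate(written):
            seq[lo + k] = base
            protected.add(lo + k)

    for i, klass in enumerate(classes):
        u = cfg.spacer_length + i * unit
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            cds_lo, cds_hi = u, u + cfg.gene_length
            anchor = cds_hi
        else:
            cds_lo, cds_hi = u + cfg.tail_length, u + cfg.tail_length + cfg.gene_length
            anchor = cds_lo

        def genomic_span(offset: int, length: int) -> int:
            """Leftmost genomic coordinate of a motif planted ``offset`` bp
            past the CDS end (transcriptional direction)."""
            if strand == "+":
                return anchor + offset
            return anchor - offset - length

        sl_motif = pas_motif = ""
        sl_cleav = pas_cleav = -1
        if klass in (RD, HYBRID):
            idx = cfg.sl_variant_index if cfg.sl_variant_index is not None else i % len(STEM_LOOP_MOTIFS)
            sl_motif = STEM_LOOP_MOTIFS[idx]
            plant(sl_motif, genomic_span(cfg.sl_offset, len(sl_motif)), strand)
            t_off = cfg.sl_offset + len(sl_motif) + cfg.sl_cleavage_offset
            sl_cleav = anchor + t_off if strand == "+" else anchor - t_off
        if klass in (RI, HYBRID):
            pas_motif = cfg.pas_motif
            plant(pas_motif, genomic_span(cfg.pas_distance, len(pas_motif)), strand)
            t_off = cfg.pas_distance + cfg.pas_cleavage_offset
            pas_cleav = anchor + t_off if strand == "+" else anchor - t_off
            if cfg.decoy_pas_motif:
                plant(
                    cfg.decoy_pas_motif,
                    genomic_span(cfg.pas_distance + cfg.decoy_pas_extra, len(cfg.decoy_pas_motif)),
                    strand,
                )

        # Annotated 3'UTR for even-indexed genes, ending at the isoform end.
        utr3_end: Optional[int] = None
        if i % 2 == 0:
            end = pas_cleav if klass == RI else sl_cleav
            if end >= 0 and end != anchor:
                utr3_end = end

        exon_lo = min(cds_lo, utr3_end if utr3_end is not None else cds_lo)
        exon_hi = max(cds_hi, utr3_end if utr3_end is not None else cds_hi)
        gene_id = f"SYNG{i:04d}"
        transcripts.append(
            TranscriptModel(
                gene_id=gene_id,
                transcript_id=f"SYNT{i:04d}.1",
                chrom=CHROM,
                strand=strand,
                exons=((exon_lo, exon_hi),),
                cds_lo=cds_lo,
                cds_hi=cds_hi,
                utr3_end=utr3_end,
                gene_name=f"HISTSYN{i}",
            )
        )
        rows.append(
            {
                "gene_id": gene_id,
                "transcript_id": f"SYNT{i:04d}.1",
                "klass": klass,
                "chrom": CHROM,
                "strand": strand,
                "cds_lo": cds_lo,
                "cds_hi": cds_hi,
                "sl_motif": sl_motif,
                "sl_offset": cfg.sl_offset if sl_motif else -1,
                "sl_cleavage": sl_cleav,
                "pas_motif": pas_motif,
                "pas_distance": cfg.pas_distance if pas_motif else -1,
                "pas_cleavage": pas_cleav,
                "expression": cfg.expression_mean,
                "utr3_end": -1 if utr3_end is None else utr3_end,
            }
        )

    seq, _ = _purge_forbidden(seq, protected, rng)
    genome = {CHROM: GenomeSequence(CHROM, "".join(seq))}
    truth = pd.DataFrame(rows)
    return genome, transcripts, truth


# --------------------------------------------------------------------------
# Coverage simulation
# --------------------------------------------------------------------------

def expected_coverage(
    genome_length: int, truth: pd.DataFrame, cfg: SimulationConfig
) -> dict[tuple[str, str, str], np.ndarray]:
    """Noise-free expected per-base coverage for every (library × strand)."""
    arrays = {
        (fr, ph, st): np.zeros(genome_length)
        for fr, ph in LIBRARIES
        for st in "+-"
    }

    def fill(key: tuple[str, str, str], row, cleavage: int, level: float) -> None:
        if level <= 0 or cleavage < 0:
            return
        if row.strand == "+":
            lo, hi = row.cds_lo, cleavage
        else:
            lo, hi = cleavage, row.cds_hi
        arr = arrays[key]
        arr[lo:hi] += level
        if cfg.taper:
            n = 20
            ramp = level * (1 - np.arange(1, n + 1) / n)
            if row.strand == "+":
                e = min(genome_length, hi + n)
                arr[hi:e] += ramp[: e - hi]
            else:
                s = max(0, lo - n)
                arr[s:lo] += ramp[: lo - s][::-1]

    for row in truth.itertuples():
        expr = row.expression
        st = row.strand
        if row.klass == RD:
            fill((PA_MINUS, "S", st), row, row.sl_cleavage, expr)
            fill((PA_MINUS, "G1", st), row, row.sl_cleavage, cfg.contamination * expr)
        elif row.klass == RI:
            fill((PA_PLUS, "S", st), row, row.pas_cleavage, expr)
            fill((PA_PLUS, "G1", st), row, row.pas_cleavage, expr)
        else:  # hybrid
            sl_level = (1 - cfg.hybrid_pa_fraction) * expr
            pa_level = cfg.hybrid_pa_fraction * expr
            fill((PA_MINUS, "S", st), row, row.sl_cleavage, sl_level)
            fill((PA_MINUS, "G1", st), row, row.sl_cleavage, cfg.contamination * sl_level)
            fill((PA_PLUS, "S", st), row, row.pas_cleavage, pa_level)
            fill((PA_PLUS, "G1", st), row, row.pas_cleavage, pa_level)
    return arrays


def _nb_bins(expected: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial realisation at bin granularity around the expectation."""
    if cfg.nb_dispersion == 0:
        return expected.copy()
    out = np.zeros_like(expected)
    b = cfg.bin_size
    r = 1.0 / cfg.nb_dispersion
    n_bins = (len(expected) + b - 1) // b
    for k in range(n_bins):
        mu = expected[k * b : (k + 1) * b].mean()
        if mu <= 0:
            continue
        p = r / (r + mu)
        out[k * b : (k + 1) * b] = rng.negative_binomial(r, p)
    return out


def simulate_coverage(
    genome: Genome, truth: pd.DataFrame, cfg: SimulationConfig
) -> dict[tuple[str, str, str], np.ndarray]:
    """Realised (noisy) per-base coverage for the eight stranded tracks.

    Tracks are drawn in a fixed canonical order from a generator seeded by
    ``cfg.seed``, so identical configs give bit-identical output.
    """
    glen = len(genome[CHROM])
    expected = expected_coverage(glen, truth, cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    return {
        (fr, ph, st): _nb_bins(expected[(fr, ph, st)], cfg, rng)
        for fr, ph in LIBRARIES
        for st in "+-"
    }


def coverage_set_from_arrays(
    arrays: dict[tuple[str, str, str], np.ndarray],
    library_sizes: Optional[dict] = None,
    chrom: str = CHROM,
) -> CoverageSet:
    """Wrap raw arrays as a scaled CoverageSet (the in-memory pipeline path)."""
    sizes = library_sizes or dict(_DEFAULT_LIBRARY_SIZES)
    return CoverageSet(
        FractionCoverage(
            fraction=fr,
            phase=ph,
            strand=st,
            values={chrom: arr.astype(float).copy()},
            library_size=float(sizes[(fr, ph)]),
        ).scale()
        for (fr, ph, st), arr in arrays.items()
    )


def simulate_inputs(
    cfg: SimulationConfig,
) -> tuple[dict[str, GenomeSequence], list[TranscriptModel], pd.DataFrame, CoverageSet]:
    """Genome, transcripts, ground truth and scaled coverage, all in memory."""
    genome, transcripts, truth = build_genome(cfg)
    arrays = simulate_coverage(genome, truth, cfg)
    return genome, transcripts, truth, coverage_set_from_arrays(arrays, cfg.library_sizes)


# --------------------------------------------------------------------------
# File output
# --------------------------------------------------------------------------

def _format_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else f"{v:.6g}"

def write_bedgraph(arr: np.ndarray, chrom: str, path: str) -> None:
    """Run-length-encoded bedGraph; zero runs are omitted."""
    with open(path, "w") as fh:
        if len(arr) == 0:
            return
        change = np.nonzero(np.diff(arr))[0] + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(arr)]))
        for s, e in zip(starts, ends):
            v = arr[s]
            if v != 0:
                fh.write(f"{chrom}\t{s}\t{e}\t{_format_value(v)}\n")


def simulate_dataset(cfg: SimulationConfig, out_dir: str) -> dict[str, str]:
    """Write the complete fixture to ``out_dir``; returns the file paths.

    Emits FASTA, GTF, eight bedGraphs (4 libraries × 2 strands), a library
    manifest TSV, the ground-truth TSV and a config-echo JSON.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, transcripts, truth, _ = simulate_inputs(cfg)
    arrays = simulate_coverage(genome, truth, cfg)

    paths = {"fasta": str(out / "genome.fa"), "gtf": str(out / "annotation.gtf")}
    write_fasta(genome, paths["fasta"])
    (out / "annotation.gtf").write_text(transcripts_to_gtf(transcripts))

    manifest_rows = []
    strand_tag = {"+": "plus", "-": "minus"}
    for (fr, ph, st), arr in arrays.items():
        name = f"{fr}_{ph}_{strand_tag[st]}.bedgraph"
        write_bedgraph(arr, CHROM, str(out / name))
        manifest_rows.append(
            {
                "file": name,
                "fraction": fr,
                "phase": ph,
                "strand": st,
                "library_size": cfg.library_sizes[(fr, ph)],
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    paths["manifest"] = str(out / "manifest.tsv")
    manifest.to_csv(paths["manifest"], sep="\t", index=False)

    paths["truth"] = str(out / "ground_truth.tsv")
    truth.to_csv(paths["truth"], sep="\t", index=False)

    paths["config"] = str(out / "sim_config.json")
    (out / "sim_config.json").write_text(json.dumps(cfg.as_dict(), indent=2, sort_keys=True) + "\n")
    return paths
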