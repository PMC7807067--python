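# Methods

## Coordinate and annotation model

All internal coordinates are 0-based half-open on the forward genomic
axis; GTF input/output converts at the boundary (GTF is 1-based
inclusive). "Transcriptional direction" quantities (CDS end, motif
offsets, cleavage positions) are boundary coordinates: on the minus strand
the CDS end of a GTF CDS spanning 201..500 is the genomic position-200
boundary.

Gencode keeps the stop codon out of its CDS rows; since the biologically
meaningful anchor here is the ORF end, `stop_codon` features are folded
into the CDS extent during parsing. The 3'UTR end is taken from UTR
features downstream of the CDS end on the same transcript; when several
are annotated, the farthest end wins.

Window arithmetic is genomic and ignores introns: human histone genes are
overwhelmingly intronless, and scanning genomic windows matches how the
regions are defined. Windows that cross an annotated intron are flagged
(`crosses_intron`), surfacing the spliced isoforms that warrant manual
review rather than silently mis-measuring them. Windows are clipped to
[0, chromosome length]; a window that clips to empty produces a warning
and no hits.

Histone transcript selection defaults to an explicit packaged symbol list
(the non-`HIST`-prefixed histone variant genes) plus a `^HIST` prefix
rule; histone naming in annotation releases is inconsistent enough that an
editable explicit list is safer than a single regex. Whether pseudogene
transcripts belong in the set is a user decision — the selector accepts
any explicit list or regex.

## Motif scanning

Stem-loops are found by exact, uppercase, sense-strand matching of the 12
literal variants (eleven 16-mers and one 17-mer); PAS candidates by exact
matching of AATAAA, ATTAAA, ATGAAA and TATAAA, ranked in that order of
strength (rank 1 strongest). `N` never matches. A hit must start inside
its window but may overhang the end by up to motif length − 1 bases, so
boundary motifs are not lost. Scanning the antisense strand as well is
biologically meaningless for this assay and is off by default.

Where several PAS candidates exist, `choose_pas` picks deterministically:
primary window before fallback window, then strongest rank, then smallest
distance to the CDS end. This replaces what is otherwise a manual
curation step; the full candidate list is written to outputs so any gene
can be overridden.

## Drop-ratio classifier

"Abrupt signal loss" at a 3' end is quantified at a model cleavage
position — `sl_cleavage_offset` (default 5 bp) past the stem-loop 3' end,
`pas_cleavage_offset` (default 20 bp) past the PAS hexamer start; both are
literature-typical spacings for U7-dependent cleavage and poly(A)
cleavage respectively and are config-exposed. The statistic is

    drop_ratio = (upstream_mean + eps) / (downstream_mean + eps)

with means over `flank` = 100 bp on each side (clipped at chromosome ends
with a warning) and `eps` = 0.01 guarding division by zero on empty
tracks. A site is *used* when `upstream_mean >= min_signal` (1.0, in
per-million-of-library units) and `drop_ratio >= drop_ratio_min` (5).
The min-signal floor prevents high ratios on near-zero tracks from
producing calls; the pseudocount makes the ratio scale-dependent only
below ~0.01, far under the floor. Raising `drop_ratio_min` can only turn
usage off, never on (monotonicity), and multiplying raw coverage and
library size by the same constant changes nothing (scaling invariance).

Gene calls: SL usage is evaluated on the poly(A)− S track; PAS usage on
poly(A)+ in S and, when present, G1, either sufficing — the hybrid
H2A.X-type poly(A) mRNA is present throughout the cell cycle, so
requiring both phases would add nothing and drop power. Two guards make
the call robust:

* a gene with a stem-loop is only credited a poly(A) isoform if poly(A)+
  signal actually reads through past the SL cleavage point
  (`min_readthrough_frac` = 0.1 of the SL-region poly(A)− signal);
* the fallback PAS window (8 kb past the primary window, configurable) is
  consulted only when the primary window yields no used PAS *and*
  poly(A)+ signal is still present at the primary window's end — i.e. the
  signal loss genuinely lies further downstream. Without this gate a
  fallback scan can reach a neighbouring gene's PAS and mis-assign its
  coverage.

Multi-isoform genes are scored per transcript; the gene call follows the
transcript with the strongest SL usage. Library scaling divides by
(library size / 10^6) exactly once; the `scaled` flag makes rescaling a
no-op. Cross-library ratios beyond the usage booleans are deliberately
not interpreted: fractionation steps make the levels qualitative.

## Contamination estimator

For genes called RD with SL-region S-phase signal ≥ `min_signal`, the
per-gene ratio of scaled G1 to S poly(A)− coverage over the SL upstream
flank estimates the S-phase cell fraction of the G1-sorted sample. The
estimate is the median across genes, clipped to [0, 1] — the median is
preferred over the mean because a single aberrant gene (mis-sorted reads,
overlapping transcription) should not move the estimate. At least 3
usable RD genes are required; with fewer, the error message suggests
relaxing the thresholds rather than returning a fragile number.

## Synthetic data

The generator is the package's study-condition definition, not a tuning
knob. One contig carries `n_rd + n_ri + n_hybrid` intronless genes,
alternating strands, each in a unit of
`gene_length + tail_length + spacer_length` (defaults 400 + 400 + 3000 bp,
with a leading 3-kb spacer so upstream windows of the first gene stay on
the contig). RD and hybrid genes carry one stem-loop (cycling through the
12 variants unless fixed) 35 bp past the CDS end; RI and hybrid genes one
PAS hexamer (AATAAA by default) at 150 bp. Even-indexed genes get an
annotated 3'UTR ending at the isoform 3' end, so both branches of the PAS
window rule are exercised; odd genes get none.

Background sequence is rejection-sampled: after planting, every
occurrence of any SL motif or PAS hexamer on either strand whose span is
not a planted span has its non-planted bases resampled, iterating to a
fixed point (error after 1,000 iterations). This keeps base composition
uniform, unlike post-hoc masking, and guarantees the no-spurious-motif
invariant that several tests rely on.

Expected coverage is piecewise constant: each gene's track runs from its
CDS start (the modelled TSS) to the relevant cleavage position at level
`expression_mean` (default 200, chosen so scaled signal sits two orders
of magnitude above `min_signal`), split for hybrid genes as
(1 − `hybrid_pa_fraction`) on the SL isoform and `hybrid_pa_fraction`
(default 0.3) on the poly(A) isoform; the G1 poly(A)− track of an SL
isoform is `contamination` (default 0.03) times its S-phase expectation.
Realised coverage draws one negative-binomial value per 10-bp bin
(variance μ + dispersion·μ², dispersion 0.05 by default) — binning gives
the short-range autocorrelation of real coverage at negligible cost.
Dispersion 0 is defined as the exactly deterministic limit. Cleavage is a
hard step to zero; the optional `taper` flag replaces it with a 20-bp
linear ramp to probe classifier robustness. Default library sizes are
10^6, making scaled and raw values coincide.

What the simulation does *not* emulate: mappability artefacts, antisense
or overlapping transcription, internal priming, gradual 3'-end
heterogeneity beyond the taper, and replicate-to-replicate library
effects. Passing tests therefore demonstrate correctness of the
windowing, scanning, scoring and estimation machinery under the model's
own assumptions, not performance on real libraries.

Statistical test calibration: the law-of-large-numbers check on the
generator compares per-bin means over 50 seeds against the configured
expectation at 3 standard errors; since ~0.27% of bins fall outside 3 SE
by chance, up to 1% of bins may exceed 3 SE and none may exceed 6 SE.
Problem sizes throughout the suite (genes per simulation, seeds per
estimate, 1,000 3-kb sequences for the scanner cross-check) were chosen
as the smallest sizes at which the checked quantities are statistically
stable.

## In-silico genotyping

The ΔHDE edit is expressed in the gene's own convention — 1-based
positions counted from the first nucleotide of the 5'UTR — so published
coordinates can be typed verbatim; `apply_edit` converts internally. PCR
is exact-match only (the screen is a length assay, so mismatch tolerance
and melting thermodynamics would add nothing); multiple binding sites for
either primer raise an ambiguity error, since a diagnostic screen needs
unique priming. EcoRI digestion cuts G^AATTC; fragments always sum to
the amplicon length.

The packaged locus is synthetic. The true genomic primer positions are
not published, but the printed numbers over-determine the geometry: with
the deletion starting at gene position 574 and the upstream digest
fragment being the 557-bp one, the forward primer's 5' end must sit at
gene position 18 (574 − 557 + 1); the alternative solution (position 359)
would swap the fragment order and is rejected in favour of the
upstream-fragment-major reading. The locus generator stamps the primers
at the solved positions in random sequence and verifies, by construction,
that each primer binds once, the wild-type locus has no EcoRI site, and
the default edit introduces exactly one. A fixed internal seed makes the
fixture a constant of the package.

## Known limitations

* Exact-match motif scanning cannot find diverged stem-loops or
  non-canonical PAS hexamers; the motif set is extensible via config but
  no PWM model is provided.
* The drop-ratio statistic assumes reasonably uniform coverage upstream
  of the cleavage point; strongly 3'-biased protocols would need a
  different flank scheme.
* Windows on spliced isoforms are genomic; the `crosses_intron` flag
  marks them but no spliced-coordinate scan is attempted.
* GFF3 input is not supported; the parser expects the Gencode GTF
  attribute dialect.
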