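"""In-silico CRISPR ΔHDE genotyping: edit, exact-match PCR, EcoRI digest.

The screening logic being reproduced: a homology-directed repair template
deletes the histone downstream element (gene nucleotides 574–598, counted
1-based from the first nucleotide of the 5'UTR) and inserts a 6-nt EcoRI
site (GAATTC) at the junction.  Screening PCR with a fixed primer pair
gives a 792-bp product on the wild-type allele and a 773-bp product
(792 − 25 + 6) on the edited allele; EcoRI cuts only the edited amplicon,
into 557-bp and 216-bp fragments.  PCR here is a pure length assay:
exact-match primer binding, no mismatches or melting model.

The packaged locus is *synthetic*: the true genomic positions of the
screening primers are not published, so the fixture solves the printed
arithmetic instead.  With the deletion starting at gene position 574 and
EcoRI cutting G^AATTC, the upstream digest fragment is 574 − p + 1 bp where
p is the forward primer's 5' gene position; the upstream-fragment-major
solution of 557 bp forces p = 18 (the alternative, p = 359, would swap the
fragments).  The fixture commits to p = 18.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .motifs import reverse_complement

log = logging.getLogger(__name__)

ECORI_SITE = "GAATTC"
ECORI_CUT_OFFSET = 1  # G^AATTC

WT = "WT"
HOMOZYGOUS_EDIT = "homozygous_edit"
AMBIGUOUS = "ambiguous"


class GenotypingError(ValueError):
    pass


class AmbiguousPcrError(GenotypingError):
    """A primer has multiple exact binding sites; the message lists them."""


@dataclass(frozen=True)
class EditPlan:
    """ΔHDE knock-in description, in the gene's own coordinate convention.

    ``deletion_start``/``deletion_end`` are 1-based inclusive gene
    positions counted from the first nucleotide of the 5'UTR, so the
    published numbers can be typed verbatim.  ``left_arm``/``right_arm``
    record the ssODN homology-arm lengths (bookkeeping only; the edit
    itself is exact).
    """

    deletion_start: int = 574
    deletion_end: int = 598
    insertion: str = ECORI_SITE
    left_arm: int = 26
    right_arm: int = 29

    def __post_init__(self) -> None:
        if self.deletion_start < 1 or self.deletion_start > self.deletion_end:
            raise GenotypingError("deletion_start must be >= 1 and <= deletion_end")
        if set(self.insertion) - set("ACGT"):
            raise GenotypingError("insertion must be over {A,C,G,T}")

    @property
    def deletion_length(self) -> int:
        return self.deletion_end - self.deletion_start + 1

    @property
    def length_change(self) -> int:
        return len(self.insertion) - self.deletion_length


@dataclass(frozen=True)
class PrimerPair:
    """Screening primers, written 5'→3'; exact-match semantics."""

    forward: str = "CGGGCGTCTGTTCTAGTGTT"
    reverse: str = "ACGGAGGTCCCCGAAGAG"

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise GenotypingError("primers must be non-empty")


@dataclass(frozen=True)
class DigestResult:
    amplicon_length: int
    cut_positions: tuple[int, ...]
    fragment_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        assert sum(self.fragment_lengths) == self.amplicon_length
        assert len(self.fragment_lengths) == len(self.cut_positions) + 1

    @property
    def is_cut(self) -> bool:
        return len(self.cut_positions) > 0


def apply_edit(locus: str, plan: EditPlan, utr5_offset: int = 0) -> str:
    """Apply the knock-in to ``locus``.

    ``utr5_offset`` is the 0-based index in ``locus`` of the first
    nucleotide of the 5'UTR, the origin of the plan's 1-based coordinates.
    The deleted interval is replaced by the insertion; the length change is
    ``len(insertion) - deletion_length``.
    """
    start = utr5_offset + plan.deletion_start - 1
    end = utr5_offset + plan.deletion_end  # exclusive
    if start < 0 or end > len(locus):
        raise GenotypingError(
            f"deletion {plan.deletion_start}-{plan.deletion_end} falls outside the locus"
        )
    return locus[:start] + plan.insertion + locus[end:]


def _find_all(hay: str, needle: str) -> list[int]:
    out, p = [], hay.find(needle)
    while p != -1:
        out.append(p)
        p = hay.find(needle, p + 1)
    return out


def in_silico_pcr(template: str, primers: Optional[PrimerPair] = None) -> Optional[str]:
    """Exact-match PCR: the amplicon from the forward primer's match through
    the match of the reverse primer's reverse complement, inclusive.

    Returns ``None`` when either site is absent or the orientation is
    wrong; multiple binding sites for either primer raise
    :class:`AmbiguousPcrError` (a specific screen needs unique priming).
    """
    primers = primers or PrimerPair()
    template = template.upper()
    fwd_sites = _find_all(template, primers.forward.upper())
    rc_rev = reverse_complement(primers.reverse.upper())
    rev_sites = _find_all(template, rc_rev)
    if len(fwd_sites) > 1 or len(rev_sites) > 1:
        raise AmbiguousPcrError(
            f"multiple primer binding sites: forward at {fwd_sites}, "
            f"reverse-complement at {rev_sites}"
        )
    if not fwd_sites or not rev_sites:
        return None
    start = fwd_sites[0]
    end = rev_sites[0] + len(rc_rev)
    if end <= start:
        return None
    return template[start:end]


def digest(
    amplicon: str, site: str = ECORI_SITE, cut_offset: int = ECORI_CUT_OFFSET
) -> DigestResult:
    """Restriction digest with a literal recognition site (default G^AATTC).

    Fragments always conserve the amplicon length; zero sites give a single
    uncut fragment.
    """
    amplicon = amplicon.upper()
    cuts = tuple(p + cut_offset for p in _find_all(amplicon, site.upper()))
    bounds = (0,) + cuts + (len(amplicon),)
    fragments = tuple(
        sorted(bounds[i + 1] - bounds[i] for i in range(len(bounds) - 1))
    )
    return DigestResult(
        amplicon_length=len(amplicon), cut_positions=cuts, fragment_lengths=fragments
    )


def screen_report(wt_result: DigestResult, edited_result: DigestResult) -> str:
    """Classify the diagnostic digest pattern of a clone.

    ``homozygous_edit``: the edited amplicon is cut exactly once (two
    fragments) while the wild-type amplicon is uncut.  ``WT``: the edited
    amplicon is also uncut.  Anything else — extra cut sites, or a cut
    wild-type product — is ``ambiguous``.
    """
    if wt_result.is_cut:
        return AMBIGUOUS
    if not edited_result.is_cut:
        return WT
    if len(edited_result.fragment_lengths) == 2:
        return HOMOZYGOUS_EDIT
    return AMBIGUOUS


# --------------------------------------------------------------------------
# Packaged synthetic locus
# --------------------------------------------------------------------------

_GENE_PRIMER_POS = 18     # forward primer 5' end, 1-based gene position
_WT_AMPLICON_LEN = 792
_LOCUS_UPSTREAM = 60      # genomic context before the 5'UTR start
_LOCUS_DOWNSTREAM = 80    # genomic context after the amplicon end
_FIXTURE_SEED = 574598    # fixed: the fixture is a constant of the package


@lru_cache(maxsize=1)
def h2afx_like_locus() -> tuple[str, int]:
    """The packaged synthetic H2AFX-like screening locus.

    Returns ``(locus, utr5_offset)``.  The locus is random sequence with
    the screening primers stamped at the solved positions: forward primer
    5' end at gene position 18 and the reverse primer placed so the
    wild-type amplicon is exactly 792 bp.  Constraints enforced during
    construction: each primer binds exactly once, the wild-type locus
    contains no EcoRI site, and the default edit introduces exactly one.
    Deterministic — the same sequence is produced on every call.
    """
    primers = PrimerPair()
    plan = EditPlan()
    rc_rev = reverse_complement(primers.reverse)
    fwd_lo = _GENE_PRIMER_POS - 1                      # 0-based gene coord
    rev_lo = fwd_lo + _WT_AMPLICON_LEN - len(rc_rev)   # 0-based gene coord
    gene_len = fwd_lo + _WT_AMPLICON_LEN + _LOCUS_DOWNSTREAM
    rng = np.random.default_rng(_FIXTURE_SEED)
    bases = np.frombuffer(b"ACGT", dtype="S1").astype("U1")
    for _ in range(1000):
        gene = list(rng.choice(bases, size=gene_len))
        gene[fwd_lo : fwd_lo + len(primers.forward)] = primers.forward
        gene[rev_lo : rev_lo + len(rc_rev)] = rc_rev
        locus = "".join(str(b) for b in rng.choice(bases, size=_LOCUS_UPSTREAM)) + "".join(gene)
        edited = apply_edit(locus, plan, utr5_offset=_LOCUS_UPSTREAM)
        ok = (
            len(_find_all(locus, primers.forward)) == 1
            and len(_find_all(locus, rc_rev)) == 1
            and not _find_all(locus, ECORI_SITE)
            and len(_find_all(edited, ECORI_SITE)) == 1
            and len(_find_all(locus, reverse_complement(primers.forward))) == 0
            and len(_find_all(locus, primers.reverse)) == 0
        )
        if ok:
            return locus, _LOCUS_UPSTREAM
    raise GenotypingError("failed to construct the synthetic locus")  # pragma: no cover


def run_screen(
    locus: Optional[str] = None,
    utr5_offset: Optional[int] = None,
    plan: Optional[EditPlan] = None,
    primers: Optional[PrimerPair] = None,
    extra_plans: Sequence[EditPlan] = (),
) -> dict:
    """End-to-end screen: edit, PCR both alleles, digest, classify.

    ``extra_plans`` lets additional user-supplied edits (e.g. a secondary
    deletion observed in a clone) be applied after the primary plan.
    Returns a dict with the per-allele amplicon lengths, fragment lengths
    and the classification.
    """
    if locus is None:
        locus, utr5_offset = h2afx_like_locus()
    if utr5_offset is None:
        utr5_offset = 0
    plan = plan or EditPlan()
    primers = primers or PrimerPair()

    edited = apply_edit(locus, plan, utr5_offset)
    for extra in extra_plans:
        edited = apply_edit(edited, extra, utr5_offset)

    results = {}
    for allele, seq in (("WT", locus), ("edited", edited)):
        amplicon = in_silico_pcr(seq, primers)
        if amplicon is None:
            raise GenotypingError(f"no amplicon from the {allele} allele")
        results[allele] = digest(amplicon)
    return {
        "wt_amplicon_length": results["WT"].amplicon_length,
        "edited_amplicon_length": results["edited"].amplicon_length,
        "wt_fragments": results["WT"].fragment_lengths,
        "edited_fragments": results["edited"].fragment_lengths,
        "classification": screen_report(results["WT"], results["edited"]),
    }


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("allele\tamplicon_length\tfragment_lengths\tclassification\n")
        fh.write(
            f"WT\t{report['wt_amplicon_length']}\t"
            f"{','.join(map(str, report['wt_fragments']))}\t{report['classification']}\n"
        )
        fh.write(
            f"edited\t{report['edited_amplicon_length']}\t"
            f"{','.join(map(str, report['edited_fragments']))}\t{report['classification']}\n"
        )
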