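"""Independent reference implementations used only to cross-check the package.

Everything here is deliberately naive — per-position membership tests,
character-by-character reverse complement, mean-of-ratios instead of
median — and shares no scanning or estimation code with histone3p.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_scan(seq: str, motifs: list[str], start: int, end: int, strand: str,
               anchor: int) -> list[tuple[str, int, int]]:
    """Per-position oracle scan of a window.

    Returns (motif, genomic_start, tx_offset) for every occurrence whose
    first transcriptional base lies in [start, end); motifs may overhang
    the window end by up to len-1 bases.  ``tx_offset`` counts bases from
    the CDS-end boundary to the motif's first base in transcriptional
    direction.
    """
    lengths = sorted({len(m) for m in motifs})
    by_len = {L: {m for m in motifs if len(m) == L} for L in lengths}
    hits = []
    if strand == "+":
        for g in range(max(0, start), min(end, len(seq))):
            for L, mset in by_len.items():
                sub = seq[g : g + L]
                if len(sub) == L and sub in mset:
                    hits.append((sub, g, g - anchor))
    else:
        sense = naive_revcomp(seq)  # sense index ps <-> genomic m = len-1-ps
        n = len(seq)
        for ps in range(n):
            m = n - 1 - ps
            if not (start <= m < end):
                continue
            for L, mset in by_len.items():
                sub = sense[ps : ps + L]
                if len(sub) == L and sub in mset:
                    hits.append((sub, m - L + 1, anchor - 1 - m))
    return hits


def mean_of_ratios(s_means: list[float], g1_means: list[float]) -> float:
    """Independent contamination estimator: arithmetic mean of per-gene ratios."""
    ratios = [g / s for s, g in zip(s_means, g1_means)]
    return sum(ratios) / len(ratios)
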