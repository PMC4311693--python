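"""Scans for the stability and promoter sequence elements of the screen.

Transcript-stability side: AWTAAA polyadenylation signals near the 5' end
(early PAS mark unstable promoter-upstream transcripts) and U1-snRNP-binding
5'-splice-site-like hexamers (their presence stabilizes).  Promoter side:
TATA box, CCAAT box, ISRE, and Gardiner-Garden/Frommer CpG islands on a
bidirectional promoter region with two divergent TSSs.

All scans are literal/IUPAC matching; overlapping occurrences are reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "MotifHit",
    "PromoterRegion",
    "scan_pas",
    "scan_u1_sites",
    "detect_core_elements",
    "detect_isre",
    "detect_cpg_islands",
    "iupac_to_regex",
    "revcomp",
]

ELEMENTS = ("PAS", "U1", "TATA", "CCAAT", "ISRE", "CpG_island")

PAS_MOTIF = "AWTAAA"
#: canonical 5'-splice-site hexamers recognized by U1 snRNP
U1_MOTIFS = ("GGTAAG", "GTAAGT", "GTGAGT")
TATA_MOTIF = "TATAWAWR"
ISRE_CONSENSUS = "RNGAAANTGAAACT"

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMP = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


def iupac_to_regex(motif: str) -> str:
    motif = motif.upper()
    bad = [c for c in motif if c not in _IUPAC]
    if bad:
        raise ValueError(f"invalid IUPAC characters in motif: {bad}")
    return "".join(_IUPAC[c] for c in motif)


@dataclass(frozen=True)
class MotifHit:
    """A located sequence element, 0-based half-open in the scanned sequence."""

    element: str
    start: int
    end: int
    strand: str
    matched_text: str
    label: str = ""  # e.g. which TSS a promoter element serves

    def __post_init__(self) -> None:
        if self.element not in ELEMENTS:
            raise ValueError(f"unknown element {self.element!r}")
        if self.end - self.start != len(self.matched_text):
            raise ValueError("matched_text length disagrees with coordinates")


@dataclass(frozen=True)
class PromoterRegion:
    """A bidirectional promoter: one sequence, two divergent TSS positions.

    By convention ``tss_a`` serves the minus-strand gene (transcribing
    leftward) and ``tss_b`` the plus-strand gene; strands are configurable.
    """

    sequence: str
    tss_a: int
    tss_b: int
    strand_a: str = "-"
    strand_b: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        L = len(self.sequence)
        for name, p in (("tss_a", self.tss_a), ("tss_b", self.tss_b)):
            if not (0 <= p < L):
                raise ValueError(f"{name}={p} outside sequence of length {L}")


def _scan_motif(
    seq: str, motif: str, element: str, *, strand: str = "+", offset: int = 0
) -> list[MotifHit]:
    """All (overlapping) occurrences of an IUPAC motif on the given text."""
    pat = re.compile(f"(?=({iupac_to_regex(motif)}))")
    hits = []
    for m in pat.finditer(seq.upper()):
        s = m.start()
        hits.append(
            MotifHit(
                element=element,
                start=offset + s,
                end=offset + s + len(m.group(1)),
                strand=strand,
                matched_text=m.group(1),
            )
        )
    return hits


def scan_pas(seq: str, window: int = 1000) -> list[MotifHit]:
    """Polyadenylation-signal (AWTAAA) hits in the first ``window`` nt.

    Early PAS occurrence marks promoter-upstream transcripts committed to
    decay; a stable transcript tends to lack them near its 5' end.
    """
    window = min(window, len(seq))
    return _scan_motif(seq[:window].upper().replace("U", "T"), PAS_MOTIF, "PAS")


def scan_u1_sites(
    seq: str, window: int = 500, motifs: Sequence[str] = U1_MOTIFS
) -> list[MotifHit]:
    """U1-binding (5'-splice-site-like) hexamer hits in the first ``window`` nt."""
    window = min(window, len(seq))
    text = seq[:window].upper().replace("U", "T")
    hits = []
    for motif in motifs:
        hits.extend(_scan_motif(text, motif, "U1"))
    hits.sort(key=lambda h: (h.start, h.matched_text))
    return hits


def _tata_for_tss(
    seq: str, tss: int, strand: str, label: str
) -> list[MotifHit]:
    """TATA-box scan in the [-40, -20] window upstream of one TSS,
    on the strand that gene is transcribed from."""
    L = len(seq)
    mlen = len(TATA_MOTIF)
    if strand == "+":
        lo, hi = tss - 40, tss - 20  # candidate start positions, genome coords
        if lo < 0:
            raise ValueError("promoter sequence too short upstream of TSS")
        text = seq[lo : hi + mlen]
        hits = _scan_motif(text, TATA_MOTIF, "TATA", strand="+", offset=lo)
        hits = [h for h in hits if lo <= h.start <= hi]
    else:
        rc = revcomp(seq)
        tss_rc = L - 1 - tss
        lo, hi = tss_rc - 40, tss_rc - 20
        if lo < 0:
            raise ValueError("promoter sequence too short upstream of TSS")
        text = rc[lo : hi + mlen]
        raw = _scan_motif(text, TATA_MOTIF, "TATA", strand="-", offset=lo)
        hits = []
        for h in raw:
            if not (lo <= h.start <= hi):
                continue
            hits.append(
                MotifHit(
                    element="TATA",
                    start=L - h.end,
                    end=L - h.start,
                    strand="-",
                    matched_text=h.matched_text,
                )
            )
    return [
        MotifHit(h.element, h.start, h.end, h.strand,
                 seq[h.start:h.end] if h.strand == "+" else seq[h.start:h.end],
                 label=label)
        for h in hits
    ]


def detect_core_elements(p: PromoterRegion) -> list[MotifHit]:
    """TATA and CCAAT boxes on a bidirectional promoter.

    TATA is searched in the [-40, -20] window upstream of each TSS on that
    gene's template-appropriate strand; CCAAT (or its reverse complement
    ATTGG) anywhere in the inter-TSS region plus 200-nt flanks.  Hits are
    labelled with the TSS they serve (CCAAT hits serve both).
    """
    seq = p.sequence
    hits = []
    hits += _tata_for_tss(seq, p.tss_a, p.strand_a, "tss_a")
    hits += _tata_for_tss(seq, p.tss_b, p.strand_b, "tss_b")
    lo = max(0, min(p.tss_a, p.tss_b) - 200)
    hi = min(len(seq), max(p.tss_a, p.tss_b) + 200)
    text = seq[lo:hi]
    for motif, strand in (("CCAAT", "+"), ("ATTGG", "-")):
        for h in _scan_motif(text, motif, "CCAAT", strand=strand, offset=lo):
            hits.append(
                MotifHit("CCAAT", h.start, h.end, strand, seq[h.start:h.end],
                         label="shared")
            )
    hits.sort(key=lambda h: (h.start, h.element, h.strand))
    return hits


def detect_isre(p: PromoterRegion, motif: str = ISRE_CONSENSUS) -> list[MotifHit]:
    """Interferon-stimulated response element hits on both strands."""
    iupac_to_regex(motif)  # validate up front (configuration error)
    seq = p.sequence
    hits = list(_scan_motif(seq, motif, "ISRE", strand="+"))
    for h in _scan_motif(seq, revcomp(motif), "ISRE", strand="-"):
        hits.append(
            MotifHit("ISRE", h.start, h.end, "-", seq[h.start:h.end])
        )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _island_ok(gc_count: int, c: int, g: int, cg: int, length: int) -> bool:
    if length < 200:
        return False
    if gc_count / length < 0.5:
        return False
    if c == 0 or g == 0:
        return False
    return (cg * length) / (c * g) >= 0.6


def detect_cpg_islands(seq: str, window: int = 200) -> list[MotifHit]:
    """CpG islands by the Gardiner-Garden/Frommer criteria.

    A qualifying window has length >= 200, GC fraction >= 0.5 and
    observed/expected CpG >= 0.6 (obs/exp = N_CG * L / (N_C * N_G)).
    Overlapping/adjacent qualifying 200-nt windows are merged greedily while
    the merged span still qualifies; every reported island re-qualifies in
    isolation and islands are disjoint.
    """
    seq = seq.upper().replace("U", "T")
    L = len(seq)
    if L < window:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(L, dtype=np.int64)
    if L > 1:
        is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    def stats(s: int, e: int) -> tuple[int, int, int, int]:
        c = int(cum_c[e] - cum_c[s])
        g = int(cum_g[e] - cum_g[s])
        cg = int(cum_cg[min(e - 1, L - 1)] - cum_cg[s])  # CG dimer fully inside
        return c + g, c, g, cg

    def ok(s: int, e: int) -> bool:
        gc, c, g, cg = stats(s, e)
        return _island_ok(gc, c, g, cg, e - s)

    qualifying = [s for s in range(L - window + 1) if ok(s, s + window)]
    islands: list[tuple[int, int]] = []
    cur: Optional[list[int]] = None
    for s in qualifying:
        e = s + window
        if cur is None:
            cur = [s, e]
            continue
        if s <= cur[1]:  # overlaps or abuts the current island
            if e > cur[1] and ok(cur[0], e):
                cur[1] = e
            # else: absorbed or refused extension — skip
        else:
            islands.append((cur[0], cur[1]))
            cur = [s, e]
    if cur is not None:
        islands.append((cur[0], cur[1]))
    return [
        MotifHit("CpG_island", s, e, "+", seq[s:e]) for s, e in islands
    ]


def hits_bed6(hits: Sequence[MotifHit], chrom: str) -> str:
    """Motif hits as BED6 (name = element, score = 0)."""
    lines = [
        f"{chrom}\t{h.start}\t{h.end}\t{h.element}\t0\t{h.strand}" for h in hits
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def hits_summary(hits: Sequence[MotifHit]) -> dict:
    """Counts per element."""
    out: dict[str, int] = {}
    for h in hits:
        out[h.element] = out.get(h.element, 0) + 1
    return out
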