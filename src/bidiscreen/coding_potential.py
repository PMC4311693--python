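"""Protein-coding capacity assessment for a candidate lncRNA.

An annotated transcript is judged on the evidence a coding gene would be
expected to show: open reading frames of useful length, an initiation
context (Kozak), ORF positions compatible with translation rather than
nonsense-mediated decay, and cross-species conservation of the putative
peptide (frameshift-indel frequency, non-synonymous:synonymous substitution
ratio, regional identity).  Each criterion is reported as its own boolean;
the verdict is an aggregation, never a bare label.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional, Sequence

from Bio.Seq import Seq

__all__ = [
    "MatureTranscript",
    "OrfCall",
    "OrfConservation",
    "Alignment",
    "find_orfs",
    "nmd_uorf_flags",
    "kozak_class",
    "frameshift_indel_rate",
    "ns_s_counts",
    "regional_identity",
    "coding_verdict",
]

_STOPS = {"TAA", "TAG", "TGA"}
_VALID = set("ACGTN")


@lru_cache(maxsize=None)
def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass(frozen=True)
class MatureTranscript:
    """A spliced transcript sequence with exon–exon junction positions.

    ``junctions`` are 0-based positions in transcript coordinates: junction j
    means exon boundary between bases j-1 and j.
    """

    id: str
    sequence: str
    junctions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        if not seq:
            raise ValueError("sequence must be non-empty")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)
        js = tuple(sorted(self.junctions))
        if js != tuple(self.junctions):
            raise ValueError("junctions must be strictly increasing")
        for j in js:
            if not (0 < j < len(seq)):
                raise ValueError(f"junction {j} outside (0, {len(seq)})")
        if len(set(js)) != len(js):
            raise ValueError("junctions must be unique")


@dataclass(frozen=True)
class OrfCall:
    """An AUG-initiated open reading frame in transcript coordinates."""

    frame: int
    start: int  # position of the A of AUG
    end: int  # position just past the stop codon
    aa_length: int  # codons between start and stop, stop excluded
    ends_before_last_junction: bool = False
    has_uorf: bool = False
    kozak_class: str = "weak"

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a codon multiple")
        if self.aa_length != (self.end - self.start) // 3 - 1:
            raise ValueError("aa_length inconsistent with span")


@dataclass(frozen=True)
class OrfConservation:
    """Alignment-derived conservation metrics for one ORF."""

    orf_id: str
    frameshift_indel_rate: float
    background_indel_rate: float
    ns_count: float
    s_count: float
    ns_s_ratio: Optional[float]  # None when s_count == 0
    identity_orf: float
    identity_flank: float
    identity_intron: Optional[float] = None


def find_orfs(t: MatureTranscript, min_aa: int = 30) -> list[OrfCall]:
    """Enumerate AUG…stop ORFs of at least ``min_aa`` codons.

    All three forward frames are scanned; each (frame, stop) yields at most
    one call, anchored at the 5'-most AUG since the previous in-frame stop.
    Calls are sorted by start position.
    """
    seq = t.sequence
    calls = []
    for frame in range(3):
        open_start = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if codon in _STOPS:
                if open_start is not None:
                    aa = (i - open_start) // 3
                    if aa >= min_aa:
                        calls.append(
                            OrfCall(frame=frame, start=open_start, end=i + 3, aa_length=aa)
                        )
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = i
    calls.sort(key=lambda c: (c.start, c.frame))
    return calls


def nmd_uorf_flags(
    orfs: Sequence[OrfCall], t: MatureTranscript, *, ptc_rule_50nt: bool = False
) -> list[OrfCall]:
    """Annotate ORFs with NMD-position and upstream-ORF flags.

    ``ends_before_last_junction`` marks a stop codon upstream of the last
    exon–exon junction (with ``ptc_rule_50nt`` the canonical refinement:
    more than 50 nt upstream).  ``has_uorf`` marks an ORF preceded by any
    other ORF start.
    """
    out = []
    last_j = max(t.junctions) if t.junctions else None
    starts = sorted(o.start for o in orfs)
    for o in orfs:
        if last_j is None:
            nmd = False
        else:
            stop_pos = o.end - 3
            cutoff = last_j - 50 if ptc_rule_50nt else last_j
            nmd = stop_pos < cutoff
        uorf = any(s < o.start for s in starts)
        out.append(replace(o, ends_before_last_junction=nmd, has_uorf=uorf))
    return out


def kozak_class(t: MatureTranscript, orf: OrfCall) -> str:
    """Initiation-context class from the two highest-information Kozak
    positions: -3 in {A, G} and +4 == G (A of AUG is +1).

    ``strong`` needs both, ``adequate`` exactly one, ``weak`` neither.
    Positions falling outside the transcript count as non-matching.
    """
    seq = t.sequence
    if not (0 <= orf.start and orf.end <= len(seq)):
        raise ValueError("ORF outside transcript")
    minus3 = seq[orf.start - 3] if orf.start >= 3 else None
    plus4 = seq[orf.start + 3] if orf.start + 3 < len(seq) else None
    hits = int(minus3 in ("A", "G")) + int(plus4 == "G")
    return {2: "strong", 1: "adequate", 0: "weak"}[hits]


# ---------------------------------------------------------------------------
# Alignment-based conservation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """A multiple alignment; the first row is the reference."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows must have equal length")
        object.__setattr__(self, "rows", tuple(r.upper() for r in self.rows))

    @property
    def reference(self) -> str:
        return self.rows[0]

    def ref_columns(self) -> list[int]:
        """Alignment column of each ungapped reference position."""
        return [i for i, c in enumerate(self.reference) if c != "-"]

    def region_columns(self, start: int, end: int) -> list[int]:
        """Columns covering reference coordinates [start, end)."""
        cols = self.ref_columns()
        if not (0 <= start < end <= len(cols)):
            raise ValueError(
                f"region [{start},{end}) outside reference length {len(cols)}"
            )
        return cols[start:end]

    @classmethod
    def from_fasta(cls, text: str) -> "Alignment":
        ids, rows, cur = [], [], []
        for line in text.splitlines():
            if line.startswith(">"):
                if cur:
                    rows.append("".join(cur))
                    cur = []
                ids.append(line[1:].split()[0])
            elif line.strip():
                cur.append(line.strip())
        if cur:
            rows.append("".join(cur))
        return cls(ids=tuple(ids), rows=tuple(rows))

    def to_fasta(self) -> str:
        return "".join(f">{i}\n{r}\n" for i, r in zip(self.ids, self.rows))


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """Maximal gap runs as (start_col, end_col) half-open intervals."""
    runs, start = [], None
    for i, c in enumerate(row):
        if c == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(row)))
    return runs


def frameshift_indel_rate(
    aln: Alignment, region: tuple[int, int]
) -> float:
    """Frameshift-inducing indel events per aligned reference position.

    Counts, per non-reference row, the maximal gap runs overlapping the
    region whose full length is not a multiple of 3, and divides by
    (rows - 1) x region length.  Region is in reference coordinates and must
    map to ungapped reference columns.
    """
    start, end = region
    cols = aln.region_columns(start, end)
    if cols != list(range(cols[0], cols[0] + len(cols))):
        raise ValueError("reference must be ungapped within the region")
    lo, hi = cols[0], cols[-1] + 1
    events = 0
    for row in aln.rows[1:]:
        for rs, re_ in _gap_runs(row):
            if rs < hi and re_ > lo and (re_ - rs) % 3 != 0:
                events += 1
    return events / ((len(aln.rows) - 1) * (end - start))


def _path_counts(ref_codon: str, alt_codon: str) -> tuple[float, float]:
    """Synonymous / non-synonymous step counts between two codons,
    averaged over all orderings of the single-base steps (equal weights)."""
    diff = [i for i in range(3) if ref_codon[i] != alt_codon[i]]
    s_tot, ns_tot, n_paths = 0.0, 0.0, 0
    for order in itertools.permutations(diff):
        cur = list(ref_codon)
        s, ns = 0, 0
        for pos in order:
            nxt = cur.copy()
            nxt[pos] = alt_codon[pos]
            if _translate("".join(cur)) == _translate("".join(nxt)):
                s += 1
            else:
                ns += 1
            cur = nxt
        s_tot += s
        ns_tot += ns
        n_paths += 1
    return s_tot / n_paths, ns_tot / n_paths


def ns_s_counts(
    aln: Alignment, region: tuple[int, int]
) -> tuple[float, float, Optional[float]]:
    """Non-synonymous and synonymous substitution counts in an ORF region.

    Each non-reference row is compared codon-by-codon to the reference
    (standard genetic code); multi-hit codons are resolved by averaging over
    the orderings of single-base steps, all orderings weighted equally.
    Codons containing gaps or N in either row are skipped.  Returns
    (ns_count, s_count, ns/s or None when s_count is 0).
    """
    start, end = region
    if (end - start) % 3 != 0:
        raise ValueError("region length must be a multiple of 3")
    cols = aln.region_columns(start, end)
    ns_total, s_total = 0.0, 0.0
    for row in aln.rows[1:]:
        for k in range(0, len(cols), 3):
            c3 = cols[k : k + 3]
            ref_codon = "".join(aln.reference[c] for c in c3)
            alt_codon = "".join(row[c] for c in c3)
            if "-" in ref_codon + alt_codon or "N" in ref_codon + alt_codon:
                continue
            if ref_codon == alt_codon:
                continue
            s, ns = _path_counts(ref_codon, alt_codon)
            s_total += s
            ns_total += ns
    ratio = (ns_total / s_total) if s_total > 0 else None
    return ns_total, s_total, ratio


def regional_identity(
    aln: Alignment, regions: dict[str, tuple[int, int]]
) -> dict[str, float]:
    """Mean pairwise percent identity per labelled region.

    Identity for a row pair is matches / columns where both rows are
    ungapped, x100; the regional value averages over all row pairs.
    Regions are reference-coordinate intervals.
    """
    out = {}
    n = len(aln.rows)
    for label, (start, end) in regions.items():
        if end <= start:
            raise ValueError(f"region {label!r} is empty")
        cols = aln.region_columns(start, end)
        idents = []
        for i in range(n):
            for j in range(i + 1, n):
                a, b = aln.rows[i], aln.rows[j]
                both = [(a[c], b[c]) for c in cols if a[c] != "-" and b[c] != "-"]
                if not both:
                    continue
                matches = sum(x == y for x, y in both)
                idents.append(100.0 * matches / len(both))
        if not idents:
            raise ValueError(f"region {label!r}: no alignable columns")
        out[label] = float(sum(idents) / len(idents))
    return out


def coding_verdict(
    orfs: Sequence[OrfCall],
    conservation: Sequence[OrfConservation] = (),
    polysome_heavy_fraction_pct: Optional[float] = None,
    *,
    min_coding_aa: int = 100,
    ns_s_neutral: float = 3.0,
    identity_margin: float = 2.0,
) -> dict:
    """Aggregate the non-coding evidence into per-criterion booleans.

    A criterion is True when it supports a NON-coding interpretation:
    no ORF reaches ``min_coding_aa``; every ORF is NMD- or uORF-flagged;
    no ORF has a strong Kozak context; NS:S is at or above the neutral
    expectation; ORF identity shows no enrichment over flanks; and (when
    polysome data is supplied) <50% of the signal sits in heavy fractions.
    The summary leans non-coding when a majority of evaluable criteria do.
    """
    reasons: dict[str, Optional[bool]] = {}
    if not orfs:
        reasons["no_orf_min_aa"] = True
        reasons["all_orfs_nmd_or_uorf_flagged"] = True
        reasons["no_strong_kozak"] = True
    else:
        reasons["no_orf_min_aa"] = max(o.aa_length for o in orfs) < min_coding_aa
        reasons["all_orfs_nmd_or_uorf_flagged"] = all(
            o.ends_before_last_junction or o.has_uorf for o in orfs
        )
        reasons["no_strong_kozak"] = all(o.kozak_class != "strong" for o in orfs)
    if conservation:
        ratios = [c.ns_s_ratio for c in conservation if c.ns_s_ratio is not None]
        reasons["ns_s_elevated"] = (
            all(r >= ns_s_neutral for r in ratios) if ratios else None
        )
        reasons["no_orf_conservation_enrichment"] = all(
            c.identity_orf <= c.identity_flank + identity_margin for c in conservation
        )
        reasons["frameshift_rate_like_background"] = all(
            c.frameshift_indel_rate >= 0.5 * c.background_indel_rate
            or c.background_indel_rate == 0
            for c in conservation
        )
    if polysome_heavy_fraction_pct is not None:
        reasons["not_polysome_enriched"] = polysome_heavy_fraction_pct < 50.0
    evaluable = {k: v for k, v in reasons.items() if v is not None}
    n_support = sum(evaluable.values())
    verdict = (
        "non_coding_leaning"
        if n_support > len(evaluable) / 2
        else "coding_leaning"
    )
    return {"verdict": verdict, "reasons": reasons, "n_supporting": n_support}


def orf_table(orfs: Sequence[OrfCall]) -> str:
    """ORF calls as a tab-separated table."""
    lines = [
        "frame\tstart\tend\taa_length\tends_before_last_junction\thas_uorf\tkozak_class"
    ]
    for o in orfs:
        lines.append(
            f"{o.frame}\t{o.start}\t{o.end}\t{o.aa_length}\t"
            f"{o.ends_before_last_junction}\t{o.has_uorf}\t{o.kozak_class}"
        )
    return "\n".join(lines) + "\n"


def orf_bed(orfs: Sequence[OrfCall], transcript_id: str) -> str:
    """ORF coordinates as BED6 in transcript space."""
    lines = []
    for i, o in enumerate(orfs, 1):
        lines.append(
            f"{transcript_id}\t{o.start}\t{o.end}\tORF{i}\t0\t+"
        )
    return "\n".join(lines) + ("\n" if lines else "")
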