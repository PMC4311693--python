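"""Stranded transcript models and lncRNA–mRNA pair geometry.

Parses GENCODE-dialect GTF into exon-resolved transcript models, classifies
the relative orientation of two transcription units (divergent / tandem /
intronic / antisense-overlapping / convergent) and screens an annotation for
candidate lncRNA/protein-coding pairs whose transcription units lie within a
configurable distance of each other — the geometric half of a bidirectional
promoter screen.

Coordinates are 0-based half-open throughout; GTF I/O converts at the
boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import gffutils

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GenePair",
    "GtfParseError",
    "parse_gtf",
    "write_gtf",
    "tss",
    "three_prime_end",
    "classify_orientation",
    "pair_distance",
    "find_candidate_pairs",
    "gene_level_models",
]

BIOTYPES = ("protein_coding", "lncRNA", "other")
ORIENTATIONS = ("divergent", "tandem", "intronic", "antisense_overlap", "convergent")

#: annotation biotype strings folded into the lncRNA class
_LNC_SYNONYMS = {"lncRNA", "lincRNA", "antisense", "antisense_RNA", "lnc_RNA"}


class GtfParseError(ValueError):
    """Raised for malformed GTF input; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """A stranded, exon-resolved transcript (or gene-level union model).

    Invariants enforced at construction: every exon lies within ``interval``,
    shares its chromosome and strand, exons are sorted by start and pairwise
    non-overlapping, and there is at least one exon.  Introns are the maximal
    gaps between consecutive exons.
    """

    transcript_id: str
    gene_id: str
    biotype: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript must have >= 1 exon")
        object.__setattr__(self, "exons", tuple(self.exons))
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom or ex.strand != self.interval.strand:
                raise ValueError(
                    f"{self.transcript_id}: exon {ex} disagrees with transcript "
                    f"chrom/strand"
                )
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(
                    f"{self.transcript_id}: exon [{ex.start},{ex.end}) outside "
                    f"transcript span [{self.interval.start},{self.interval.end})"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons unsorted or overlapping at "
                    f"[{ex.start},{ex.end})"
                )
            prev_end = ex.end

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(a.chrom, a.end, b.start, a.strand)
                )
        return tuple(out)

    @property
    def tss(self) -> int:
        return tss(self)

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class GenePair:
    """A candidate lncRNA / protein-coding pair with geometry annotations."""

    lnc: TranscriptModel
    pc: TranscriptModel
    orientation: str
    tss_distance: int
    gap_distance: int

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.tss_distance < 0 or self.gap_distance < 0:
            raise ValueError("distances must be non-negative")


def tss(t: TranscriptModel) -> int:
    """Transcription start site: 5' end of the transcript, strand-aware."""
    iv = t.interval
    return iv.start if iv.strand == "+" else iv.end - 1


def three_prime_end(t: TranscriptModel) -> int:
    """3' terminal position (0-based, inclusive)."""
    iv = t.interval
    return iv.end - 1 if iv.strand == "+" else iv.start


def _require_same_chrom(a: TranscriptModel, b: TranscriptModel) -> None:
    if a.chrom != b.chrom:
        raise ValueError(
            f"transcripts on different chromosomes: {a.chrom} vs {b.chrom}"
        )


def _is_intronic(inner: TranscriptModel, outer: TranscriptModel) -> bool:
    return any(intr.contains(inner.interval) for intr in outer.introns)


def classify_orientation(a: TranscriptModel, b: TranscriptModel) -> str:
    """Classify the relative orientation of two same-chromosome transcripts.

    Classes (mutually exclusive, checked in priority order):

    - ``intronic``  — one unit lies fully inside an intron of the other
      (any strand combination);
    - ``antisense_overlap`` — opposite strands with overlapping units, not
      intronic (overlap wins over divergent under boundary jitter);
    - ``divergent`` — opposite strands, non-overlapping, head-to-head: each
      TSS is nearer to the other gene than to its own 3' end;
    - ``convergent`` — opposite strands, non-overlapping, tail-to-tail;
    - ``tandem`` — same strand (non-overlapping, or overlapping without the
      intronic containment).
    """
    _require_same_chrom(a, b)
    if _is_intronic(a, b) or _is_intronic(b, a):
        return "intronic"
    if a.strand == b.strand:
        return "tandem"
    if a.interval.overlaps(b.interval):
        return "antisense_overlap"

    def _head_to_head(x: TranscriptModel, other: TranscriptModel) -> bool:
        t = tss(x)
        d_other = max(other.interval.start - t, t - (other.interval.end - 1), 0)
        d_own_3p = abs(t - three_prime_end(x))
        return d_other < d_own_3p

    if _head_to_head(a, b) and _head_to_head(b, a):
        return "divergent"
    return "convergent"


def pair_distance(a: TranscriptModel, b: TranscriptModel) -> tuple[int, int]:
    """(TSS-to-TSS distance, gap between nearest unit boundaries).

    The gap clamps to 0 when the units overlap.
    """
    _require_same_chrom(a, b)
    tss_distance = abs(tss(a) - tss(b))
    lo, hi = sorted([a.interval, b.interval], key=lambda iv: iv.start)
    gap_distance = max(0, hi.start - lo.end)
    return tss_distance, gap_distance


def gene_level_models(
    transcripts: Iterable[TranscriptModel],
) -> list[TranscriptModel]:
    """Collapse transcripts into one union-span model per gene.

    Exons of the gene model are the merged exon union of all transcripts;
    introns are the remaining gaps.  Biotype is protein_coding if any
    transcript is, else lncRNA if any is, else other.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    out = []
    for gene_id, ts in by_gene.items():
        chroms = {t.chrom for t in ts}
        strands = {t.strand for t in ts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"gene {gene_id}: transcripts disagree on chrom/strand")
        start = min(t.interval.start for t in ts)
        end = max(t.interval.end for t in ts)
        chrom, strand = ts[0].chrom, ts[0].strand
        # merge exon union
        exs = sorted(
            (ex for t in ts for ex in t.exons), key=lambda e: (e.start, e.end)
        )
        merged: list[list[int]] = []
        for ex in exs:
            if merged and ex.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], ex.end)
            else:
                merged.append([ex.start, ex.end])
        biotypes = {t.biotype for t in ts}
        if "protein_coding" in biotypes:
            biotype = "protein_coding"
        elif "lncRNA" in biotypes:
            biotype = "lncRNA"
        else:
            biotype = "other"
        out.append(
            TranscriptModel(
                transcript_id=gene_id,
                gene_id=gene_id,
                biotype=biotype,
                interval=GenomicInterval(chrom, start, end, strand),
                exons=tuple(
                    GenomicInterval(chrom, s, e, strand) for s, e in merged
                ),
            )
        )
    return out


def find_candidate_pairs(
    transcripts: Sequence[TranscriptModel],
    max_gap: int = 2000,
    *,
    gene_level: bool = True,
    use_tss_distance: bool = False,
) -> list[GenePair]:
    """All (lncRNA, protein-coding) pairs whose units lie within ``max_gap``.

    The distance criterion is strict (< max_gap) on the gene-body gap by
    default; ``use_tss_distance=True`` applies it to the TSS spacing instead.
    Intronic pairs qualify regardless of distance.  Output is deterministic:
    sorted by chromosome, then lncRNA TSS, then gene ids.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    models = gene_level_models(transcripts) if gene_level else list(transcripts)
    lncs = [t for t in models if t.biotype == "lncRNA"]
    pcs = [t for t in models if t.biotype == "protein_coding"]
    pairs = []
    for ln in lncs:
        for pc in pcs:
            if ln.chrom != pc.chrom:
                continue
            tss_d, gap_d = pair_distance(ln, pc)
            orient = classify_orientation(ln, pc)
            dist = tss_d if use_tss_distance else gap_d
            if dist < max_gap or orient == "intronic":
                pairs.append(
                    GenePair(
                        lnc=ln,
                        pc=pc,
                        orientation=orient,
                        tss_distance=tss_d,
                        gap_distance=gap_d,
                    )
                )
    pairs.sort(key=lambda p: (p.lnc.chrom, tss(p.lnc), p.lnc.gene_id, p.pc.gene_id))
    return pairs


# ---------------------------------------------------------------------------
# GTF I/O (GENCODE attribute dialect)
# ---------------------------------------------------------------------------

def _prevalidate_gtf(text: str) -> None:
    for i, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise GtfParseError(
                f"line {i}: expected 9 tab-separated fields, got {len(fields)}"
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise GtfParseError(f"line {i}: non-integer coordinates") from exc
        if start < 1 or end < start:
            raise GtfParseError(f"line {i}: bad coordinate range {start}..{end}")
        if fields[6] not in ("+", "-", "."):
            raise GtfParseError(f"line {i}: bad strand {fields[6]!r}")


def _biotype_of(attrs: dict) -> str:
    for key in ("gene_type", "gene_biotype", "transcript_type"):
        if key in attrs:
            val = attrs[key][0]
            if val == "protein_coding":
                return "protein_coding"
            if val in _LNC_SYNONYMS:
                return "lncRNA"
            return "other"
    return "other"


def parse_gtf(stream) -> list[TranscriptModel]:
    """Parse GTF text (string or file-like) into transcript models.

    GTF's 1-based inclusive coordinates are converted to 0-based half-open.
    A declared ``transcript`` feature, when present, must contain all of its
    exons; otherwise the transcript span is the exon union.
    """
    text = stream.read() if hasattr(stream, "read") else stream
    _prevalidate_gtf(text)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    spans: dict[str, tuple] = {}
    for f in db.features_of_type("transcript"):
        tid = f.attributes["transcript_id"][0]
        spans[tid] = (f.seqid, f.start - 1, f.end, f.strand, dict(f.attributes))
    exons: dict[str, list] = {}
    attrs_by_tid: dict[str, dict] = {}
    for f in db.features_of_type("exon"):
        tid = f.attributes["transcript_id"][0]
        exons.setdefault(tid, []).append(
            GenomicInterval(f.seqid, f.start - 1, f.end, f.strand)
        )
        attrs_by_tid.setdefault(tid, dict(f.attributes))
    out = []
    for tid, exs in exons.items():
        exs = sorted(exs, key=lambda e: e.start)
        attrs = attrs_by_tid[tid]
        gene_id = attrs["gene_id"][0]
        if tid in spans:
            chrom, start, end, strand, t_attrs = spans[tid]
            attrs = {**attrs, **t_attrs}
            for ex in exs:
                if ex.start < start or ex.end > end:
                    raise ValueError(
                        f"transcript {tid}: exon [{ex.start},{ex.end}) outside "
                        f"declared span [{start},{end})"
                    )
        else:
            chrom = exs[0].chrom
            start = min(e.start for e in exs)
            end = max(e.end for e in exs)
            strand = exs[0].strand
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=gene_id,
                biotype=_biotype_of(attrs),
                interval=GenomicInterval(chrom, start, end, strand),
                exons=tuple(exs),
            )
        )
    out.sort(key=lambda t: (t.chrom, t.interval.start, t.transcript_id))
    return out


_BIOTYPE_OUT = {"protein_coding": "protein_coding", "lncRNA": "lncRNA", "other": "misc_RNA"}


def write_gtf(models: Iterable[TranscriptModel]) -> str:
    """Serialize transcript models back to GENCODE-dialect GTF text."""
    buf = io.StringIO()
    for t in sorted(models, key=lambda m: (m.chrom, m.interval.start, m.transcript_id)):
        attrs = (
            f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
            f'gene_type "{_BIOTYPE_OUT[t.biotype]}";'
        )
        iv = t.interval
        buf.write(
            f"{iv.chrom}\tbidiscreen\ttranscript\t{iv.start + 1}\t{iv.end}\t.\t"
            f"{iv.strand}\t.\t{attrs}\n"
        )
        for ex in t.exons:
            buf.write(
                f"{ex.chrom}\tbidiscreen\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                f"{ex.strand}\t.\t{attrs}\n"
            )
    return buf.getvalue()


def pairs_table(pairs: Sequence[GenePair]) -> str:
    """Candidate pairs as a tab-separated table."""
    lines = ["chrom\tlnc_gene\tpc_gene\torientation\ttss_distance\tgap_distance"]
    for p in pairs:
        lines.append(
            f"{p.lnc.chrom}\t{p.lnc.gene_id}\t{p.pc.gene_id}\t{p.orientation}\t"
            f"{p.tss_distance}\t{p.gap_distance}"
        )
    return "\n".join(lines) + "\n"


def pairs_bed12(pairs: Sequence[GenePair]) -> str:
    """Pair spans as BED12 (one record per pair, two blocks = the two units)."""
    lines = []
    for p in pairs:
        lo = min(p.lnc.interval.start, p.pc.interval.start)
        hi = max(p.lnc.interval.end, p.pc.interval.end)
        blocks = sorted(
            [p.lnc.interval, p.pc.interval], key=lambda iv: iv.start
        )
        # BED12 blocks may not overlap; fall back to one spanning block then
        if blocks[0].end > blocks[1].start:
            sizes, starts = [hi - lo], [0]
        else:
            sizes = [len(b) for b in blocks]
            starts = [b.start - lo for b in blocks]
        name = f"{p.lnc.gene_id}|{p.pc.gene_id}|{p.orientation}"
        lines.append(
            "\t".join(
                [
                    p.lnc.chrom,
                    str(lo),
                    str(hi),
                    name,
                    "0",
                    p.lnc.strand,
                    str(lo),
                    str(hi),
                    "0,0,0",
                    str(len(sizes)),
                    ",".join(map(str, sizes)) + ",",
                    ",".join(map(str, starts)) + ",",
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
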