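import numpy as np
import pytest

from bidiscreen.genome_model import GenomicInterval, TranscriptModel
from bidiscreen.synthetic import make_focal_locus


@pytest.fixture(scope="session")
def focal():
    """The constructed divergent lncRNA/mRNA locus with its planted evidence."""
    return make_focal_locus(seed=0)


def make_transcript(
    tid="t1",
    gene=None,
    chrom="chr1",
    start=0,
    end=1000,
    strand="+",
    biotype="lncRNA",
    exons=None,
):
    """Small helper to build a valid transcript model in one line."""
    exons = exons or [(start, end)]
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene or tid,
        biotype=biotype,
        interval=GenomicInterval(chrom, start, end, strand),
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


def random_transcripts(rng: np.random.Generator, n: int, chrom="chr1"):
    """Random non-degenerate single-exon transcripts for geometry fuzzing."""
    out = []
    for i in range(n):
        s = int(rng.integers(0, 50_000))
        L = int(rng.integers(200, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "lncRNA" if i % 2 == 0 else "protein_coding"
        out.append(
            make_transcript(
                f"t{i}", chrom=chrom, start=s, end=s + L, strand=strand,
                biotype=biotype,
            )
        )
    return out


def random_dna_str(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
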