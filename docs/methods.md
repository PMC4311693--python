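# Methods

This note records the models, conventions, and parameter choices behind
`bidiscreen`, and what the synthetic generator does and does not emulate.

## Coordinate and model conventions

All internal coordinates are 0-based half-open; GTF input/output converts at
the boundary (GTF is 1-based inclusive). A transcript's TSS is `start` on the
plus strand and `end − 1` on the minus strand. Orientation between two
transcripts on one chromosome is classified exhaustively with this priority:

1. **intronic** — one gene's span lies entirely within an intron of the other;
2. **tandem** — same strand;
3. **antisense_overlap** — opposite strands with overlapping spans;
4. **divergent** — head-to-head: each TSS is nearer the other gene than its
   own 3′ end;
5. **convergent** — everything else (tail-to-tail). The convergent class
   exists so classification is total: every geometry gets exactly one label.

Pair distance is reported two ways: TSS-to-TSS distance and gene-body gap
(0 when spans overlap). The screen's distance cutoff applies to the gap by
default (strictly less than 2000 bp) and can be switched to TSS spacing.

## Pair screen

A candidate pair passes when all of the following hold:

- **robust expression** (both genes): at least `min_level` (1 expression
  unit) in at least `min_samples` (2) samples;
- **differential response** (either gene): some time point's fold change
  versus baseline is strictly above `fc_threshold` (2) or strictly below its
  reciprocal, and, whenever every time point has ≥ 2 replicates, the
  replicate-level two-sample t-test at the strongest time point gives
  p < `alpha` (0.05);
- **concordance**: Spearman rho of the two genes' per-sample profiles is
  positive and both genes move in the same direction.

Fold changes use a pseudocount (0.5) to guard against zero baselines. The
t-test is the pooled-variance Student test (`scipy.stats.ttest_ind`); a
Welch variant is available. Degenerate zero-variance inputs return p = 1
when the means are equal.

## Coding potential

`find_orfs` reports one ORF per (frame, stop codon): the 5′-most AUG reading
to the first in-frame stop; `aa_length` counts the initiator methionine but
not the stop (so `aa = (end − start)/3 − 1`). Default reporting threshold is
30 aa. NMD flagging uses the literal last-junction rule (stop strictly
upstream of the final exon–exon junction), with the conventional 50-nt
offset available as an option. Kozak context is classified from the −3 and
+4 positions: both matching (−3 ∈ {A,G}, +4 = G) is *strong*, one is
*adequate*, neither is *weak*.

Conservation statistics operate on a multiple alignment whose first row is
the reference. NS:S counting follows the Nei–Gojobori spirit: for each
codon pair the single-base substitution steps are averaged over all orders
with equal weights; codons touched by gaps or ambiguity are skipped. The
frameshift-indel rate counts maximal gap runs whose length is not a multiple
of 3, normalized by (rows − 1) × region length. The combined
`coding_verdict` leans non-coding when no ORF reaches 100 aa, every ORF is
NMD-flagged or behind a uORF, no ORF has strong Kozak context, NS:S is near
the neutral site-count expectation (~3), ORF identity does not exceed flank
identity by a margin, and (when provided) heavy-polysome association is low.

## Sequence elements

Motifs are IUPAC strings compiled to regular expressions; overlapping
occurrences are all reported, and every hit quotes the scanned sequence so
`sequence[start:end] == matched_text` always holds. Conventions:

- **PAS**: AWTAAA, scanned in the transcript's first 1000 nt (early PAS mark
  unstable transcripts; the stability question is about the 5′ region);
- **U1 sites**: the 5′-splice-site-like hexamers GGTAAG, GTAAGT, GTGAGT in
  the first 500 nt;
- **TATA**: TATAWAWR in the [−40, −20] window upstream of each TSS, on that
  gene's template-appropriate strand (for a minus-strand TSS "upstream" is
  rightward and the motif is sought on the reverse complement);
- **CCAAT**: CCAAT or its reverse complement ATTGG in the inter-TSS region
  plus 200-nt flanks (shared between the two genes);
- **ISRE**: RNGAAANTGAAACT on both strands;
- **CpG islands**: Gardiner-Garden/Frommer — windows of length ≥ 200 with
  GC ≥ 0.5 and observed/expected CpG ≥ 0.6 (obs/exp = N_CG · L / (N_C ·
  N_G)), merged greedily while the merged span still qualifies. Reported
  islands are disjoint and each re-qualifies in isolation.

## Expression kinetics

Onset detection walks the time grid and calls the earliest time whose
replicate values differ from baseline (t-test, p < 0.05) with mean fold
≥ 1.5; `compare_onsets` reduces two series on a shared grid to
a-first/b-first/tie/undetermined. Decay fitting regresses ln(mean) on time
(ordinary least squares) and reports rate, half-life = ln 2 / rate, and R².
A non-positive fitted rate is flagged `no_measurable_decay` (half-life ∞)
rather than reported as a spurious number. Ratio profiles divide the means
at each shared time point (optionally as log2, i.e. delta-Ct units);
zero denominators yield NaN, never an exception.

## Synthetic generator

The generator's defaults *are* the study conditions; analyses are scored
against its recorded ground truth.

- **Genome**: one chromosome, 9 planted divergent pairs (TSS spacing
  250 bp), 10 decoy divergent pairs (random spacing, no response), 30 decoy
  singletons, inter-unit spacing 3–6 kb. Background DNA is GC 0.42 with 85%
  of CpG dimers rewritten CG→TG. The depletion matters: uniform random DNA
  has observed/expected CpG ≈ 1 and would qualify as a CpG island about
  half the time, flooding the scans with false positives. Responsive
  divergent promoters get one exact ISRE instance and a CCAAT box planted.
- **Expression**: value = baseline × (1 + (peak_fold − 1) · H(t)) ×
  lognormal noise, with H a smooth-step induction shape that is exactly 0
  at t ≤ 0, exactly 0.5 at the onset time, and clamped to exactly 1 from
  twice the onset onward — so noiseless plateau folds are exact, which the
  tests exploit. Defaults: peak fold 4, onset 2 h, noise σ 0.2, 3
  replicates, grid (0, 2, 4, 8, 24) h.
- **Kinetics**: a minute-scale pair with onsets 40 and 90 min for the
  onset-ordering analyses; shutoff decay v(t) = v₀ · 2^(−t/half-life) ×
  noise on a (0–8) h grid, half-lives 4 h (target) and 20 h (control).
- **Alignment evolution**: species rows are derived from the reference by
  uniform substitutions (rate 0.08) and deletions only (rate 0.01,
  geometric lengths, mean 1.5) — insertions are omitted so reference
  coordinates equal alignment columns, which keeps ground truth exact
  without a coordinate-lifting layer. Under *constrained* selection,
  non-synonymous changes inside annotated ORFs are accepted with probability
  0.1 and ORF-overlapping deletions are rounded up to multiples of 3; under
  *neutral* the ORF is ordinary sequence.
- **Focal locus**: a constructed 1100-nt lncRNA whose ORF census is exactly
  the planted five (36, 40, 43, 46, 49 aa — ORF bodies use A-free codons so
  no stray AUG or stop can arise in any frame, and residual matches are
  scrubbed iteratively, with a hard verification failure if the census ever
  disagrees). It has three junctions (four exons), weak Kozak context
  everywhere, three U1 sites in the first 500 nt, no AWTAAA before 1000 nt,
  one 3′ PAS, and a shared promoter (TSSs 250 bp apart) carrying an ISRE
  and CCAAT but no TATA in either [−40, −20] window and no CpG island. Two
  25-nt knockdown-duplex target intervals are recorded for downstream use.

### What the generator does not emulate

Read-level RNA-seq (alignment, counting), mapping ambiguity, batch effects,
insertions, substitution-rate heterogeneity along the sequence, and real
phylogeny (species are i.i.d. draws from the reference, not a tree). These
are deliberate simplifications: the analyses under test operate downstream
of all of them.

## Numerical choices

- Statistics come from scipy (`ttest_ind`, `spearmanr`, `linregress`);
  GTF parsing is backed by gffutils, translation by biopython. The package's
  own code is the screen logic, interval arithmetic, motif conventions,
  evolution simulator, and orchestration.
- Zero-variance and degenerate inputs return defined sentinel values (p = 1,
  rho = NaN, half-life ∞) instead of raising, so batch runs never die on a
  flat gene; genuinely invalid input (mismatched lengths, malformed GTF,
  regions outside an alignment) raises with a precise message.
- All randomness flows through `numpy.random.default_rng` seeded from
  configuration; every generator output is byte-reproducible for a given
  seed, and derived seeds stay below 2³¹.
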