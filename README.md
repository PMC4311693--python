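# bidiscreen

A toolkit for finding and characterizing **divergent lncRNA / protein-coding
gene pairs transcribed from shared bidirectional promoters**, with a focus on
interferon-stimulated loci.

## Scientific problem

Many long non-coding RNAs are transcribed head-to-head with a protein-coding
neighbor from one bidirectional promoter. Such pairs are often co-regulated:
when the coding gene is induced (for example by interferon), the lncRNA rises
too, frequently *earlier* and with a *shorter half-life*. Deciding whether a
candidate lncRNA is genuinely non-coding — and whether the pair really shares
a promoter rather than sitting nearby by accident — requires a battery of
small, well-defined analyses:

- **Pair screen** — find lncRNA/coding gene pairs whose gene bodies lie
  within 2 kb of each other, classify their orientation (divergent, tandem,
  intronic, antisense-overlapping, convergent), and keep pairs where both
  genes are robustly expressed, at least one responds more than twofold to
  stimulation (with a replicate t-test), and the two expression profiles are
  concordant (positive Spearman correlation, same direction of change).
- **Coding potential** — enumerate AUG-initiated ORFs, flag those that end
  upstream of the last exon–exon junction (nonsense-mediated-decay targets)
  or sit downstream of an upstream ORF, classify Kozak context, and measure
  cross-species constraint: non-synonymous:synonymous substitution counts
  (Nei–Gojobori-style step counting) and frameshift-indel rates.
- **Sequence elements** — scan for early polyadenylation signals (AWTAAA)
  and U1-snRNP binding sites that govern transcript stability, and for
  promoter features: TATA and CCAAT boxes, interferon-stimulated response
  elements (ISRE), and Gardiner-Garden/Frommer CpG islands.
- **Expression kinetics** — detect induction onsets on a minute-scale grid,
  compare which gene of a pair responds first, and fit exponential decay to
  transcription-shutoff series to estimate half-lives.
- **Synthetic data** — a seeded generator that plants all of the above into
  an annotated genome with recorded ground truth, so every analysis can be
  scored on instances where the right answer is known.

## Worked example

Generate a synthetic cohort (nine planted divergent pairs, ten decoy pairs,
thirty decoy singleton genes) and screen it:

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_screen_pairs.py
```

prints

```
seed=1: 9 planted pairs, 10 decoy pairs, 30 decoy singletons -> results/simulated
candidates=19 passing=9 recovered 9/9 planted pairs, 0 false positives
```

The remaining drivers characterize the focal locus — a constructed divergent
pair whose lncRNA carries five short ORFs (36–49 aa) in weak Kozak context,
four exons, U1 sites but no early polyadenylation signal, and a shared
promoter with an ISRE and a CCAAT box but no TATA box or CpG island:

```sh
python analysis/03_element_scans.py      # -> results/elements.tsv
python analysis/04_coding_potential.py   # -> results/orfs.tsv, conservation.tsv
python analysis/05_kinetics.py           # -> results/onsets.tsv, decay_fits.tsv
```

```
transcript: 0 early PAS, 3 U1 sites in first 500 nt; promoter: 5 element hits
5 ORFs (36-49 aa), verdict: non_coding_leaning (3 supporting observations)
onsets: lnc_early=40.0 min, mrna_late=60.0 min (a_first); decay fits written for 2 genes
```

The same functionality is available through the `bidiscreen` command-line
tool (`bidiscreen simulate`, `screen`, `elements`, `orf`, `kinetics`,
`run-all`); see `bidiscreen --help`.

Or from Python:

```python
from bidiscreen.genome_model import parse_gtf
from bidiscreen.pair_screen import ExpressionMatrix, run_screen

transcripts = parse_gtf(open("results/simulated/annotation.gtf").read())
expr = ExpressionMatrix.from_tsv(
    open("results/simulated/expression.tsv").read(),
    open("results/simulated/samples.tsv").read(),
)
for r in run_screen(transcripts, expr):
    if r.passed:
        print(r.pair.lnc.gene_id, r.pair.pc.gene_id, round(r.concordance_rho, 2))
```

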