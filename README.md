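# rbpscan

Prediction and mapping of RNA-binding-protein (RBP) binding sites on query
RNA sequences, for researchers who have an experimentally defined binding
motif (IUPAC consensus or MEME-format PSSM) and want candidate sites with
calibrated significance rather than bare pattern matches.

RBP motifs are short and degenerate, so naive scanning drowns in false
positives. `rbpscan` layers three context-aware devices on top of the scan:

1. **Region-specific empirical calibration.** Every window of width *k*
   gets a min–max-normalized log-odds match score
   `S = Σ_i log2(p_i(b_i)/0.25)`; scores are converted to p-values against
   a per-motif background built separately for six genomic region classes
   (splice-site flanks, internal exons, 5′/3′ UTR exons, ncRNA,
   mid-intron/intergenic). Stringency presets high/medium/low set the
   anchor and suboptimal p-value thresholds to (0.001, 0.01),
   (0.005, 0.01) and (0.01, 0.02).
2. **Weighted-Rank (WR) clustering score.** Each significant anchor is
   boosted by suboptimal matches within a 50-nt window:
   `WR = s_anchor · (1 + Σ_{q∈cluster} s_q / N)` with `N = 50 − k + 1`.
   The WR score is Z-tested against the mean/sd of WR scores on the
   region-matched background, and a site is reported only when the
   one-tailed normal p-value is below 0.05. For genomes without a
   background corpus ("other-genome" mode) anchors come instead from the
   exact analytic score distribution of a random k-mer, which accounts for
   motif length and complexity.
3. **Conservation filter.** Sites in mid-intron/intergenic sequence are
   dropped when the mean conservation of their 50-nt environment falls
   below the average conservation of intronic splice-flank regions
   (optional; all other region classes are exempt).

A seeded synthetic-data module generates background corpora, motif-spiked
strong/weak binding sets, a toy gene model and a toy conservation track,
so the whole pipeline — including the Fisher-exact enrichment validation —
runs without any external downloads. See `docs/methods.md` for the model
details and assumptions.

## Worked example

```sh
rbpscan fixtures --out fx --seed 3
rbpscan build-background --meme fx/motif.meme \
    --background-fasta mid_intron_intergenic fx/background_mid_intron_intergenic.fasta \
    --out bg
rbpscan scan --fasta fx/strong.fasta --meme fx/motif.meme \
    --backgrounds bg --out run1
head -4 run1.summary.tsv
```

prints

```
# seed=0
seq_id      position  genomic_coordinate  protein    motif         occurrence  match_score  wr_score  z_score  p_value
strong_0000 52        NA                  FOX1_like  UGCAUGU_pssm  UGUAUGU     0.8622       0.8988    1.7091   4.372e-02
strong_0000 61        NA                  FOX1_like  UGCAUGU_pssm  CGCAUGU     0.8677       0.9044    1.8098   3.517e-02
```

Each row is one surviving binding site: its 1-based position in the query,
the matched k-mer, the normalized match score, the clustering-boosted WR
score, and the Z-score/p-value of the WR score against the
mid-intron/intergenic background (p < 0.05 for every reported site).
Queries given as genomic coordinates (`--bed` + `--reference`) additionally
carry genomic positions, and the companion `run1.bedgraph` places each site
at its first genomic position, one track block per protein.

Validation against a ranked binding experiment:

```sh
rbpscan enrich --strong fx/strong.fasta --weak fx/weak.fasta \
    --meme fx/motif.meme --backgrounds bg
```

```
config              a    b    c    d    fisher_p   sensitivity  specificity
match-only          420  80   214  286  2.394e-43  0.840        0.572
wr-no-conservation  388  112  39   461  4.424e-123 0.776        0.922
```

`a/b` (`c/d`) count strong-set (weak-set) sequences with/without at least
one predicted site. On this spiked fixture (80% planting in strong, 5% in
weak) the WR stage trims weak-set false positives from 214 to 39 sequences,
raising specificity from 0.57 to 0.92 and sharpening the one-tailed Fisher
enrichment p-value by eighty orders of magnitude at a modest sensitivity
cost — the motivation for clustering-aware calling.

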