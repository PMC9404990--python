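# slrkit

Analysis toolkit for the **sex-linked region (SLR)** of XY dioecious plant
genomes — built around the kind of question asked for spinach and its wild
relatives: which variants cosegregate perfectly with sex, how do X- and
Y-specific transposable-element insertions distribute along the sex
chromosomes, where is the male-specific Y-duplication region (YDR), and how
differentiated is the Y chromosome between populations inside vs outside the
recombination-suppressed region?

It is a library first (import `slrkit`, see `examples/`), with a thin
`slrkit` command-line interface over the same functions, and it ships a
fully ground-truthed synthetic data generator so that every stage is testable
without any external download.

## What it computes

On a Y-chromosome reference in an XY system, males are X/Y heterogametes and
females X/X homogametes, so within the SLR:

- **Fully sex-linked SNP** — genotype 0/1 in *all* males and 1/1 in *all*
  females (the reference allele is Y-specific). `variants` classifies these,
  measures cross-population sharing, filters sites (MAF > 0.05, MAC ≥ 4,
  QUAL ≥ 30, call rate ≥ 0.9), and annotates coding effects
  (synonymous / nonsynonymous / stopgain / stoploss, strand-aware).
- **TIP (TE insertion polymorphism)** — an insertion present on exactly one
  of X/Y. `tips` calls them from one-to-one whole-chromosome alignment
  blocks: indels ≥ 50 bp between adjacent collinear blocks, exclusion of
  BRK discontinuities and assembly N-gap overlaps, then classification
  against a TE consensus library at ≥ 80% identity and ≥ 80% coverage
  (X-TIP / Y-TIP by host). `tipgeno` genotypes TIPs across samples from
  junction-read support (presence/absence alleles from the insertion ± 1 kb
  flanks), filters on MAF ≤ 0.05 / missing ≥ 0.08, and classifies fully
  sex-linked TIPs.
- **log2(F/M)** — per 20-kb bin,
  `log2((mean normalized female depth + ε) / (mean normalized male depth + ε))`.
  Sustained strongly negative runs (default ≤ −2 over ≥ 5 bins) mark
  male-specific sequence; `coverage.detect_male_specific_region` turns them
  into YDR intervals.
- **Windowed Weir–Cockerham F_ST** — per-site 1984 variance components
  a, b, c combined as `Σa / Σ(a+b+c)` in 1000-kb windows stepping 200 kb
  (any window/step works), plus per-region means and a PAR-vs-SLR Wilcoxon
  contrast. `popgen` also provides pairwise p-distance
  (mean |Δdosage|/2 over shared called sites), neighbor-joining trees, and
  PCA of standardized dosages.
- **Synthetic study system** — `simdata` builds an X/Y pair with
  PAR1–IV–YDR–PAR2 architecture (IV reverse-complemented on Y, YDR absent
  from X), plants TE insertions on one haplotype each, simulates three
  populations of XX females / XY males (two sharing the SLR haplotype
  structure, one diverged), coverage tracks with female YDR depletion, and
  per-TIP junction support — all with a `TruthSet` for recovery tests.

## Worked example

```bash
python examples/sex_linked_snps.py
```

```
simulated 10024 SNPs x 60 samples (3 groups)
fully sex-linked SNPs in the focal group: 258 (planted: 258)
sharing with turkestanica_like: 100.00%
sharing with tetrandra_like: 0.00%
```

The classifier recovers exactly the 258 planted fully sex-linked SNPs; the
population that shares the SLR haplotype structure keeps 100% of them, while
in the diverged population (whose X/Y never fixed that haplotype) none
survive the all-males-het / all-females-hom rule — the signature that two
taxa share one sex-linked region.

```bash
python examples/coverage_ydr_scan.py
```

```
100 bins of 20 kb; log2(F/M) range -3.64 .. 0.22
male-specific interval: 1,300,000 - 1,800,000 bp
planted YDR:             1,300,000 - 1,800,000 bp
```

The other examples run the TIP detection + genotyping chain
(`tip_detection_and_genotyping.py`), the windowed F_ST / NJ / PCA analyses
(`popgen_fst_tree.py`), and write a complete dataset with ground truth to
disk (`simulate_dataset.py`). The same operations are exposed as CLI
subcommands: `slrkit simulate`, `sexlink-snps`, `tip-detect`,
`tip-genotype`, `coverage-ratio`, `detect-msr`, `fst`, `njtree`, `pca`.

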