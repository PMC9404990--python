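# Methods

This note documents the models, decision rules, parameters and numerical
choices behind slrkit, and what the synthetic-data generator does and does
not emulate.

## The study system

An XY dioecious plant genome with a Y-chromosome reference. The Y carries a
pseudoautosomal backbone (PAR1/PAR2) that still recombines with the X, an
inversion segment (IV) present in reverse-complement orientation relative to
the X, and a Y-duplication region (YDR) with no X counterpart. IV + YDR form
the sex-linked region (SLR): recombination suppression there makes variants
cosegregate with sex. Males are X/Y, females X/X.

## Fully sex-linked variants

A site is fully sex-linked iff every male is heterozygous (0/1) and every
female homozygous-alternate (1/1) on the Y reference; the reference allele
is then carried only by Y haplotypes. The rule is strict about missing data
by default (`allowed_missing = 0`): the quantifier is "all", and any
uncalled sample leaves the condition unverifiable. Because real
resequencing panels always have missing calls, `allowed_missing` is exposed
as a per-sex tolerance rather than hard-coded.

The same logic applies to TIPs: an X-TIP is fully sex-linked iff females
are presence/presence and males presence/absence; a Y-TIP iff females are
absence/absence and males presence/absence. ("Homologous" presence in the
female X-TIP condition is read as homozygous presence.)

Cross-group sharing of a fully sex-linked SNP set is the fraction of sites
that also satisfy the rule in the second group's samples; positions absent
from the second matrix count as unshared.

## Site filtering

`filter_sites` retains biallelic SNPs with minor-allele frequency strictly
above `maf_min` (0.05), minor-allele count ≥ `mac_min` (4), site quality ≥
`qual_min` (30), and call rate ≥ `min_call_rate` (0.9, inclusive).
Frequencies are computed over called genotypes only. The filter is
idempotent (frequencies do not change when only whole sites are removed) and
logs per-criterion removal counts. Removing every site returns an empty
matrix with a warning, not an error, so pipelines can report rather than
crash.

## TIP detection chain

1. **Alignment blocks.** The production input is a PAF-like TSV of
   one-to-one alignment blocks from any whole-genome aligner. For synthetic
   data and tests the built-in `align_pair` anchors on 21-mers that occur
   exactly once in each sequence, chains anchors that share a diagonal with
   inter-anchor gaps ≤ 1000 bp, and keeps chains spanning ≥ 90 bp with
   ≥ 40 anchor bp — deliberately a toy: exact matches only, no extension
   across diagonal changes, both orientations searched. Block identity is
   the percent base match over the (equal-length) spans.
2. **One-to-one filtering.** Blocks under 90% identity are dropped;
   remaining blocks are admitted greedily by weight (aligned length ×
   identity, deterministic coordinate tie-break) under a zero-overlap
   constraint on both axes. Exact maximum-weight selection under the
   two-axis constraint is combinatorial; the greedy rule is deterministic,
   preserves every dominance case we rely on, and guarantees the
   no-overlap invariant. Candidates conflicting by ≤ 50 bp in total are
   trimmed at their ends instead of dropped, because anchors legitimately
   cross an indel junction by a few bases when the first base of an
   insertion coincides with the backbone base.
3. **Indel calling.** Along the maximum-weight collinear backbone per
   strand (weighted longest-increasing-subsequence on block order), an
   adjacent pair whose query gap exceeds the reference gap by ≥ 50 bp with
   the reference gap ~0 (≤ 20 bp slack) is an insertion on the query;
   symmetrically for the reference. Blocks off the backbone, orientation
   flips, overlapping gaps, and two-sided gaps become BRK features. "In
   syntenic regions" is operationalized as "between adjacent collinear
   one-to-one blocks"; BRK candidates are excluded downstream. This also
   disposes of spurious TE-copy-to-TE-copy blocks (two insertions of one
   family on opposite haplotypes), which land off the backbone.
4. **Filtering.** Candidates overlapping an assembly N-gap on their host
   chromosome are removed with any-overlap (≥ 1 bp) semantics — a
   conservative exclusion, since gap-adjacent coordinates are unreliable.
5. **TE classification.** Each candidate is locally aligned (match +1,
   mismatch −1, gap open −2, extend −1) against every library consensus in
   both orientations; the best hit by score (ties: higher identity, then
   library order) yields a TIP iff identity ≥ 0.80 and candidate coverage
   ≥ 0.80. "Greater than 80%" is implemented inclusively (≥ 0.80); the
   boundary is ambiguous in prose and equality is measure-zero in practice.
   Consensi shorter than `min_coverage × candidate length` cannot pass and
   are skipped without alignment, which keeps megabase-scale candidates
   (e.g. the YDR itself appearing as a giant Y-side gap) cheap to reject.

An insertion is attributed to the chromosome that carries the extra
sequence: X-TIP on the query (X) side, Y-TIP on the reference (Y) side.

## TIP genotyping

The TE reference for a TIP is the insertion ± 1 kb flanks (presence allele)
vs the joined flanks (absence allele); flanks truncated at chromosome ends
are recorded. Junction support `(presence_reads, absence_reads)` is turned
into a genotype by a min-support rule (default 2): both alleles supported →
heterozygote; exactly one supported and the other at zero → that homozygote;
anything else (total below threshold, or conflicting sub-threshold reads) →
missing. The rule is monotone: adding presence reads never moves a call away
from presence.

Filtering removes samples with > 50% missing calls first (the cutoff is a
package parameter; panels typically drop one or two such samples without
stating a threshold), then TIPs with minor presence/absence allele frequency
≤ 0.05 **or** missing rate ≥ 0.08. Removal on either condition (rather than
requiring both) is deliberate: requiring both would retain uninformative
monomorphic TIPs. The 0.08 missing cap is taken literally (8%, not 0.8).

## Coverage ratio and YDR detection

Per-sample depth is averaged in 20-kb bins and divided by the sample's
genome-wide mean (`norm="genome_mean"`), making samples of different
sequencing depth comparable. The statistic is the ratio of sex means,
`log2((mean_F + ε)/(mean_M + ε))` with ε = 0.05 normalized-depth units:
a ratio of means rather than a mean of per-pair ratios, which is robust to
individual dropout; the pseudocount keeps female-absent bins finite and a
zero ε is rejected. Fully male-specific sequence sits near
log2(ε/(0.5 + ε)) ≈ −3.5 at haploid male dose.

Detection reports maximal runs of bins ≤ −2.0 (≥ 4-fold female depletion),
merged across single-bin interruptions, of at least 5 below-threshold bins
(≥ 100 kb at the default grid). Threshold and run length are exposed flags;
lowering the threshold never enlarges the detected set. No GC or
mappability correction is applied and no CNV segmentation is attempted
beyond the threshold-run rule.

## Population genetics

- **p-distance**: mean over shared called sites of |dosage_i − dosage_j|/2,
  dosage ∈ {0, 1, 2}. This matches the diploid behavior of common
  VCF-distance tools; it is stated here explicitly because distance tools
  rarely document it. Pairs with zero shared called sites raise an error
  naming the pair.
- **Neighbor joining**: standard Q-criterion agglomeration with
  deterministic tie-breaking by the smallest index pair; negative branch
  lengths are clamped to zero with the deficit moved to the sibling branch
  (a common convention that preserves path lengths through the joined
  node); the last three clusters join at an unrooted trifurcation. On
  additive matrices the tree reproduces the generating path-length matrix
  to machine precision.
- **PCA**: dosages centered at 2p and scaled by √(2p(1−p)) with p from
  called alleles; fixed sites dropped; missing values mean-imputed after
  centering; eigendecomposition of the sample covariance; component signs
  fixed by making the largest-magnitude coordinate positive.
- **F_ST**: Weir & Cockerham (1984) two-population variance components per
  site, combined per window as Σa / Σ(a+b+c) (the weighted, ratio-of-sums
  form used by the standard windowed-F_ST tools). Sites where either
  population has fewer than two called samples are skipped. Windows advance
  by `step` over half-open coordinates; empty or zero-denominator windows
  are omitted; negative per-window estimates are reported, not clamped.
  Region means are means over windows (not sites) — the statement "mean
  F_ST of a region" is window-weighted here, and the PAR-vs-SLR contrast
  is a two-sided Wilcoxon rank-sum (normal approximation with tie
  correction) over the two window sets.
- **Region contrasts** elsewhere use the pooled-variance two-sample
  Student's t (densities, lengths) or the same Wilcoxon, both two-sided.

Percentages in summary tables are **truncated** toward zero at two decimals
rather than rounded; reported shares of published count tables reproduce
their printed values under truncation (e.g. 1571/3616 → 43.44).

## The synthetic-data generator

`simdata` emulates, at desk scale, the features the pipeline is sensitive
to; defaults are chosen once and shared by tests and the acceptance script.

- **Architecture**: 2-Mb chromosome, PAR1 800 kb, IV 500 kb, YDR 500 kb
  (25 bins of 20 kb), PAR2 200 kb — the published system is ~115 Mb with a
  14.1-Mb inversion and 10-Mb YDR; the desk scale keeps every test in
  seconds while preserving the PAR/IV/YDR proportions that matter
  (a YDR much larger than the detection run-length, inversions long enough
  to host TIPs away from boundaries).
- **Sequence**: uniform i.i.d. nucleotides; each TE family has one
  consensus, and every inserted copy is that consensus with 10% per-base
  substitutions (old enough to diverge between copies — which keeps copies
  of one family from anchoring to each other — yet ≥ 80% identical to the
  consensus, so the 80/80 rule accepts them). X and Y backbones differ by
  0.1% background substitutions outside insertions. X and Y insertion
  points are drawn jointly in shared backbone coordinates with a 5-kb
  minimum spacing: two insertions at nearly the same syntenic spot on
  opposite haplotypes would cancel in the alignment diagonal and look like
  a substitution, which is a genuinely different event class.
- **Populations**: three groups of 10 females + 10 males. Each group's
  consensus allele differs from the ancestral reference with probability
  `divergence` (defaults 0 / 0.02 / 0.20), scaled by 0.3 inside the SLR to
  reflect its conservation; a site is polymorphic within a group with
  probability 0.3 at minor-allele frequency U(0.1, 0.5). A
  `fully_linked_fraction` (5%) of SLR sites is forced fully sex-linked in
  the two SLR-sharing groups. These within-species diversity parameters are
  free choices documented here; no published values exist for them.
- **Coverage**: per-bin Poisson read counts at 10–20× mean; female YDR dose
  0 (no mapping), male YDR dose 0.5 (haploid).
- **Junction support**: deterministic mean counts (default 10 per diploid
  locus, split across alleles) with per-cell dropout as the noise source,
  and optional Poisson counts. Deterministic support makes zero-dropout
  recovery exactly 100% and isolates the genotype decision rule from count
  noise.
- **Determinism**: one top-level seed; each stage derives its own child
  seed via `SeedSequence(seed, spawn_key=(stage,))`, so identical configs
  give byte-identical FASTA/VCF/TSV/bedGraph outputs and stages can be
  rerun independently.

What it does **not** emulate: read-level sequencing (no FASTQ, no mapper —
depth and junction support are summary-level), recombination and
forward-in-time population genetics (genotypes are drawn from frequencies,
not pedigrees), nested or fragmented TE structure, GC/mappability bias, and
linkage disequilibrium outside the planted SLR haplotype. Passing tests
therefore demonstrate the correctness of the decision rules and estimators
on data satisfying their assumptions, not robustness to mapping artifacts
or complex repeat structure in real resequencing data.

## Degenerate inputs and errors

Classification with a single sex, sharing from an empty site list, PCA
without polymorphic sites, NJ with < 3 samples or an asymmetric matrix,
p-distance pairs with no shared calls, F_ST with an absent population,
region contrasts with < 2 values, and coverage ratios with eps ≤ 0 or
mismatched grids all raise `ValueError` with a message naming the offending
object. CDS models whose spliced length is not divisible by 3 raise an
error naming the transcript; a site whose stated reference base disagrees
with the genome raises rather than silently annotating.

## Known limitations

- The built-in aligner is exact-match and unique-anchor only; it is not a
  substitute for a whole-genome aligner on real assemblies (precomputed
  block files are the production path).
- TIP boundary coordinates can be off by up to ~20 bp when a background
  X/Y substitution falls within an anchor length of the junction; side and
  family calls are unaffected.
- The greedy one-to-one selection is a heuristic; adversarial block sets
  could force a sub-optimal (but still non-overlapping) subset.
- Multi-allelic SNPs and indel annotation are out of scope; gene models
  use one transcript per gene (the first, when several share a parent).
- F_ST supports exactly two populations; no bootstrap support on NJ trees;
  no admixture-style model fitting.
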