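# Methods

This note documents the models behind `pairdel`, the defaults and why
they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions. Coordinates are 0-based
half-open (BED) throughout; sequence comparisons are case-insensitive.

## Library design

**Protospacer scan.** Every 20-nt window immediately 5' of a PAM match
(default `NGG`, IUPAC degeneracy supported) is reported on both strands.
The cut site is the blunt-cut boundary between protospacer positions 17
and 18, i.e. 3 bp 5' of the PAM. Windows containing `N` are skipped; a
fully degenerate PAM position accepts any base.

**Filters.** Efficacy and off-target scores are *inputs* (they come from
an external scorer); the filter keeps guides with efficacy > 0.15,
top-5 off-target total < 47 and top-10 < 50 — all strict inequalities —
whose protospacer overlaps no exclusion interval (exons, repeats) and
whose cut site is ≥ 10 bp from every annotated splice site. Protospacers
containing a BsmBI (`CGTCTC`/`GAGACG`) or BbsI (`GAAGAC`/`GTCTTC`)
recognition sequence are additionally removed in `build_library` and
rejected by the oligo assembler: the two-step cloning opens the vector
with these enzymes, so an internal site would destroy the construct.

**Pairing.** The flanking strategy takes up to 5 guides per 200-bp flank
(ranked by efficacy, ties by distance to the region boundary, then
guide id) and emits their Cartesian product — at most 25 pairs, whose
expected deletion always contains the whole region. Regions without
usable flanks fall back to internal pairing: in-region guides are split
at the region midpoint, pairs spanning the midpoint are taken
widest-deletion-first (ties by pair id) up to 14. The caps (5/flank, 14
internal) reflect the library scale these screens use; both are
parameters.

**Oligo and cassette grammar.** The synthesized oligo is fixed flanks +
guide1 + version-specific linker(s) (+ 10-nt barcode in v2) + reverse
complement of guide2 + fixed 3' flank; v1 is 123 nt, v2 is 167 nt, and
`parse_oligo_sequence` inverts the grammar exactly (property-tested on
random pairs). The post-cloning expression cassette places the two full
sgRNA scaffolds convergently with a neutral spacer between them:
50 bp (v1) or 200 bp (v2), the v2 widening improving sequencing
cluster diversity. The spacer is a fixed, deterministically generated
sequence constrained to 40–60% GC, sharing no 6-mer with the promoter
anchors or scaffold on either strand, and free of the cloning enzymes'
sites. Barcodes are random 10-mers with no homopolymer run ≥ 4 and
pairwise Hamming distance ≥ 2 (plumbing constraints, parameterized).

## Amplicon read processing

Each read pair covers one integrated cassette from its two promoter
sides. The extractor anchors on the printed promoter sequences
(`ATATATCTTGTGGAAAGGACGAAA` for U6, `ATAAGTTCTGTATGAGACCACTCTT` for H1)
allowing ≤ 1 mismatch (parameter), skips the fixed junction bases
(`CACCG` / `TCCCG` per the cloning grammar; the junction itself is not
re-verified — the anchor and scaffold checks bracket it), and takes the
next 20 nt as the protospacer. The following 20 bp must match the
scaffold prefix with ≤ 1 mismatch; when they do not, the tracrRNA
identifier (`AAGTTAAAAT`, scaffold positions 21–30) is accepted as a
fallback — the two checks are redundant descriptions of the same
construct region and the prefix takes precedence. Variable stagger
prefixes (0–7 nt by default) are transparent to the anchored search.

Matching replaces a read aligner with a **unique-best-match contract**:
a protospacer is assigned to a side's reference guide only when exactly
one guide sits at minimal Hamming distance ≤ 1 (parameter); ties are
`ambiguous`. Because the flanking design reuses guides across its
Cartesian product, a guide maps to a *set* of pairs; the read pair is
`matched` when the two sides' pair sets intersect, `recombinant` when
both sides resolve but to disjoint pair sets (template-switching
artifact; excluded from counts), `unmatched` otherwise. The fates
partition all read pairs, so tallies always sum to the input size.

Low-coverage filtering drops pairs whose day-0 (reference) count falls
below `min_count` (default 5; the analysis convention, not a printed
value) and reports per-region retention.

## Screen statistics

**Normalization** uses median-ratio size factors over pairs positive in
every sample — the standard convention of the screen-analysis tool
family this follows. Fold changes use pseudocount 1.

**α-RRA.** Pairs are ranked by log2 fold change (most depleted first,
ties by pair id); a region with k pairs at sorted global percentiles
u(1) ≤ … ≤ u(k) gets

    ρ = min over j with u(j) < α of  P( Beta(j, k−j+1) ≤ u(j) ),

the smallest tail probability of a uniform order statistic; ρ = 1 when
no percentile is below α. By default α is **adaptive**: the fraction of
guides whose score falls below median − 1.645 × 1.4826 MAD, i.e. the
fraction that looks genuinely depleted. A fixed α (e.g. 0.25) is
accepted, but it admits regions whose guides are only coincidentally and
mildly jointly depleted: the null probability of ρ < 0.01 under a fixed
α = 0.25 is ≈ 0.4–0.6% for any k, which at a 5% hit prevalence caps
precision near 90%. Tying α to the depleted fraction restricts
aggregation to the tail that carries signal and keeps the region-level
false-call rate near zero; this matches how the cited tool family
determines its α from the significantly selected guides. Permutation
p-values draw `n_perm` random k-subsets of all percentiles without
replacement (vectorized; shared across regions of equal k; add-one
smoothing); BH adjusts across regions. The hit call is ρ < 0.01.

**Beta scores.** The per-condition selection coefficient of a region is
the median over its pairs of the mean log2 fold change versus day 0 — a
robust median-LFC estimator standing in for the cited
maximum-likelihood beta: this package deliberately substitutes the
simpler estimator because the interaction rules operate identically on
any consistent selection coefficient, and the median is robust to
single-pair outliers. Drug-interaction calls: *resistant* regions have
β_treated above the population mean by > 2 s.d., untreated β within
1 s.d. of its mean, and differential β (treated − untreated) above its
mean by > 1 s.d.; *sensitizing* is the mirror image. The treated
threshold follows the stricter 2-s.d. convention; the differential uses
1 s.d. All three multipliers are parameters. Calls are invariant to
adding a constant to all betas of one condition.

## Enhancer clusters

Regions are assigned to the cluster interval containing their midpoint
(half-open; overlapping cluster annotations are rejected as ambiguous;
unassigned regions are excluded and reported). Two statistics are
computed per cluster: a weighted Kolmogorov–Smirnov running-sum
enrichment score (weight 1 on |score|, one-sided toward depletion,
label-permutation p, null distribution shared across clusters of equal
size) and α-RRA over the pooled guide pairs of the cluster's members.
Each method's p-values are BH-corrected; the shared top-20 clusters of
the two rankings (ordered by joint rank sum) are the reporting set, with
FDR < 0.25 as the enrichment-reporting convention. Pooling is what
buys power: members whose individual effects sit below the single-region
threshold still produce a coherent depleted tail when combined.

## Single-cell perturbations

**Assignment.** Pair-level capture UMIs are the sum of the pair's two
guides. A cell is assigned to its top pair when that pair has ≥ 3 UMIs
(`min_umi`) and ≥ 80% of all pair UMIs (`dominance`); two or more pairs
above `min_umi` without dominance is a `multiplet`; otherwise
`unassigned`. The thresholds are this package's defaults for a
MOI ≈ 0.2 experiment; assignment by pair (not individual guide) reflects
that both guides ride one construct.

**Normalization** is LogNormalize: ln(1 + 10,000 · count / cell total);
zero-total cells are dropped with a warning.

**Hurdle test.** Genes with mean normalized expression < 0.01 across the
tested cells, or detected in < 5% of cells in both groups, are skipped
(detection-limit filters; the 5% is parameterized). For each remaining
gene two nested model pairs are fit with group plus per-cell covariates
(natural-log total expressed genes, natural-log total guides detected;
centered): a logistic model of detection and a Gaussian model of
log-normalized expression among detected cells. The LRT statistic is the
sum of the two deviance drops from removing the group term, referred to
χ²(2 df). On logistic separation/non-convergence, or when the continuous
part has fewer than 2 detected cells per group (or fewer than 6 total),
a closed-form binomial LRT on detection counts (1 df) is used and
flagged. Genes detected in every cell contribute no detection deviance
and are likewise referred to 1 df via the fallback only when the
continuous part is unfittable. Fold change is log2 of the ratio of group
means of normalized expression (ε = 1e-9 guard); BH adjusts across the
genes tested per target. On permuted labels the statistic follows its
reference χ² closely (QQ slope within 1 ± 0.1 in the suite).

**Cis windows.** Genes are reported when their body intersects the TAD
containing the region's midpoint, or the ±1 Mb window when no TAD
annotation covers the region (with a warning), ordered by position.

## Synthetic data

The generators are first-class, deterministic-by-seed code:

- *Design inputs*: per-region contigs (pad|flank|body|flank|pad) redrawn
  until each 200-bp flank carries the requested number of NGG candidates
  (planted-construction guarantee). Scores: efficacy ~ Uniform(0,1),
  off-target totals ~ scaled Beta(2,2) ("realistic", making the score
  filters bite), or uniformly passing ranges ("permissive", for
  abundant-candidate settings).
- *Screen counts*: day-0 ~ multinomial with Dirichlet(50) proportions;
  later samples scale expected abundance by 2^(effect × days) per region
  (renormalized to fixed sequencing depth) and draw gamma–Poisson
  (negative-binomial) counts at dispersion 0.05. Defaults: 400 reads per
  pair (the screens' ~300–500× coverage regime), 15-day window.
- *Amplicon reads*: each read pair embeds the exact cassette grammar
  (anchor + junction + protospacer + scaffold) behind a random stagger
  prefix of length 0–7 (eight staggered PCR primers), with per-base
  substitution errors. With probability `recomb_rate` the H1-side
  protospacer is swapped with that of a construct from a **different
  region**: within a region the Cartesian-product design shares guides
  across pairs, so a same-region swap can still resolve to a designed
  pair and would not be observable as recombinant — drawing cross-region
  keeps the planted rate identifiable.
- *Single cell*: negative-binomial baseline counts (lognormal gene
  means, lognormal per-cell depth, dispersion 0.3); perturbed cells
  scale their cis-target gene means by (1 − knockdown); capture places
  the cell's pair high (Poisson around 12 UMIs split over its two
  guides, +1 to guarantee detection) over Poisson(0.02) background;
  multiplets carry a second, different pair. Genes are laid out every
  100 kb on one synthetic chromosome so cis-window logic is exercised.

What the generators do **not** emulate: guide-specific efficacy
variation (every pair of an essential region carries the full effect),
PCR jackpotting and GC bias, base-quality structure (errors are uniform
substitutions), chimeric reads beyond the single recombination
mechanism, cell-cycle and batch structure in the single-cell data, and
ambient/background mRNA. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under their stated noise
models, not robustness to every artifact of real libraries.

## Problem sizes and numerical conventions

The test suite exercises the recovery claims at 2,000 regions × 8 pairs
(screen recovery), 5 × 10⁴ + 2 × 10⁴ read pairs (read processing), 300
regions (interaction calling), and 500 null genes / 20 power replicates
at 150 vs 4,000 cells (hurdle model) — sizes chosen to estimate each
rate with useful Monte-Carlo error while keeping the suite quick.
Permutation p-values use add-one smoothing, so their floor is
1/(n_perm + 1). Ties in ranking break lexically by pair id for full
determinism; all random draws flow through explicit seeds. Beta tail
probabilities come from `scipy.stats.beta`; BH from
`statsmodels.stats.multitest`.

## Known limitations

- The beta score is a median-LFC coefficient, not a likelihood fit; with
  very few pairs per region its s.d. across regions blends biological
  and counting noise, and the interaction caller inherits that.
- Adaptive α depends on a robust-z cut at −1.645; screens where most
  guides are depleted (e.g. dropout of a whole library) would inflate α
  toward a fixed-α regime.
- The unique-best matcher tolerates one mismatch per protospacer;
  libraries containing guide pairs at Hamming distance ≤ 2 from each
  other will shed reads as `ambiguous` rather than risk misassignment.
- The hurdle model assumes Gaussian errors on log-normalized expression
  among detected cells; heavy-tailed genes are better served by rank
  tests, which are out of scope here.
- Cell-cycle regression is not built in; users may pass additional
  covariate columns by extending the assignment table before testing.
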