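# Methods

This note documents the models, statistics and design choices behind `xsp`,
in the order the pipeline runs them, followed by an account of what the
synthetic-data generator does and does not emulate.

## Ortholog resolution

Input is a candidate table of `(gene_a, gene_b, weighted_score,
best_score_reverse)` rows — the shape of a DIOPT export, where the weighted
score aggregates evidence across orthology databases and the reverse flag
marks pairs that are also best in the reverse-direction lookup. Candidate
tables are many-to-many; every downstream stage needs a strict one-to-one
map.

Per-gene selection ranks each gene's candidates by (1) weighted score,
descending; (2) reverse flag, set first; (3) mean delogged expression of the
partner gene in its own dataset; (4) the partner's detection fraction;
(5) the partner's gene id, lexicographically. Levels 4–5 exist only to make
the output a pure function of the input — independent of row order and
byte-reproducible. "Expression level" is taken as the mean of delogged
expression over all cells; detection fraction is the natural secondary
reading and serves as the next tie-break.

Per-gene selection can leave collisions (two A genes electing the same B
gene). These are settled by a greedy fixpoint: all genes propose their
current best candidate; each contested partner keeps the proposer with the
highest (score, reverse flag, own mean expression, own detection fraction,
lexicographic id); losers discard that candidate and re-propose from their
remaining list, until no collisions remain. The procedure terminates because
every round with a collision deletes at least one candidate. Each retained
pair records which precedence level decided it (`unique`, `score`,
`reverse`, `expression`) or `global_greedy` when it was a fallback after a
lost collision.

The *expressed* map additionally requires each gene to be detected (nonzero
in at least `min_cells` cells, default 1) in its own dataset; the core set
across several maps sharing species A is a plain intersection of their
A-side genes.

## Quality control

Four per-library rules, in a fixed order, each cell attributed to the first
rule that fires:

1. a hard UMI cap (optional; dataset-specific);
2. UMI > mean + k·SD, with k = 2 by default, mean and SD computed over the
   cells that survived the cap; SD is the sample SD (ddof = 1, the R
   convention). This rule targets likely multiplets. It is deliberately
   **not** idempotent: re-applying it to survivors computes a tighter
   threshold and may remove more cells;
3. detected genes < `min_genes` (default 200);
4. mitochondrial fraction > `max_mito_fraction` (default 0.10), with
   mitochondrial genes identified by configurable id prefixes (`mt:`,
   `mt-`, `MT-`) since nomenclature is species-dependent.

Mean/SD are computed per sequencing library because depth distributions are
library-specific; a single-cell library skips rule 2 with a logged warning.

## Aggregation

Log-normalized expression is `log1p` of library-size-scaled counts;
delogging is `expm1`, clipped at zero to absorb rounding. All aggregation
happens on the delogged (raw) scale, by **mean**: pseudo-bulk averages all
cells of a type; pseudo-cells average disjoint random groups of
`group_size = 10` same-type cells, drawn without replacement with a seeded
generator. Grouping is stratified by (library, cell type) so profiles never
mix batches. The trailing remainder of a stratum is dropped, unless the
stratum is smaller than the group size, in which case one undersized group
keeps it — a cell type is never silently deleted. Averaging (rather than
summing) keeps pseudo-bulk and pseudo-cells on a common scale; downstream
statistics are rank-based, so any monotone choice gives identical results.

## Neighbor voting

Variable genes: per dataset, genes are binned into deciles of median
expression across profiles, and the top-variance quartile of each bin is
kept (constant genes never qualify); the final list is the intersection
across datasets. This explicit recipe replaces a library call so the
selection is reproducible from the definition alone; it is an approximation
of that library's behavior, not a re-implementation.

The merged pseudo-cell matrix over variable genes yields a profile×profile
Spearman matrix whose columns are converted to midranks scaled by 1/N — the
voting network. Votes for each test profile are the network mass it receives
from the training type divided by the total mass it receives from the
training dataset (degree normalization, so hub profiles cannot dominate).
AUROC uses the Mann–Whitney midrank identity `(R⁺ − P(P+1)/2)/(P·N)`, which
handles ties exactly (verified against brute-force concordant-pair counting
to 1e-12). Both orientations (A trains / B tests and vice versa) are
computed and averaged; a test type with fewer than two profiles is recorded
as missing. Top hits take each type's best-scoring partner at or above the
threshold (inclusive ≥, so exact-boundary values are kept); a pair is a
reciprocal best hit when each member is the other's best hit.

## Marker discovery and enrichment

Markers are one-vs-rest, two-sided Wilcoxon rank-sum tests on log-normalized
expression (normal approximation with tie correction), Bonferroni-corrected
across all genes per cell type. A gene is a marker when its effect
(mean difference, focal − rest) is positive, it is detected in ≥ `min_pct`
(0.25) of focal cells, and adjusted p ≤ 0.05. Genes passing in more than one
cell type are removed everywhere: in continuously differentiating tissue
such genes mark shared states, not identities. The rank-sum test substitutes
a hurdle-model DE test used in comparable pipelines; it is deterministic and
dependency-free, with the same filtering semantics, at the cost of somewhat
different marker lists on real data. Types with fewer than three cells are
excluded with a warning.

Translated sets (through the one-to-one map; untranslatable genes dropped,
set sizes recorded before/after) are scored on the partner species'
pseudo-bulk with a gene-set variation statistic:

1. per gene, a Gaussian-kernel CDF across samples, bandwidth = sample
   SD / 4; constant genes are dropped (zero bandwidth);
2. per sample, genes are ordered by this statistic (descending, stable) and
   given symmetric rank scores |p/2 − rank|;
3. a weighted KS random walk over the ordered genes, weight exponent 1:
   in-set steps add the gene's symmetric score (normalized by the set
   total), out-of-set steps subtract 1/(p − m);
4. the enrichment score is the maximum positive deviation plus the maximum
   negative deviation of the walk (signed sum), hence raw scores in [−1, 1].

Sets with fewer than 5 usable genes are dropped with a warning. The final
matrix is min–max scaled to [0, 1] **globally** (not per row): the fusion
step compares scores across sets, so per-row scaling would destroy exactly
the comparability it needs. Enrichment is computed in one direction — marker
sets from the simpler species scored on the more complex species' profiles —
because marker discovery is more reliable in the species with the cleaner
type structure.

## Conservation map

For every cell-type pair present in either matrix, the conservation score is
the arithmetic mean of its AUROC and scaled enrichment; pairs scored by one
arm only carry that value and are flagged `partial` so they stay
inspectable. A pair is retained when it is a reciprocal best hit **or** its
score is strictly greater than 0.80. No re-scaling happens at fusion time
(scaling happened once, in the enrichment stage). Retained pairs are emitted
in deterministic order (species, then score descending), optionally with a
heatmap.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, and
is the basis of every end-to-end claim:

- Two species share latent per-gene baseline programs (log-normal across
  genes) through a random one-to-one bijection over ortholog slots; each
  species also carries private genes with no ortholog.
- Five matched type pairs elevate disjoint marker blocks (default 40 genes,
  4-fold). Types 0 and 1 form a progenitor→differentiated continuum: the
  progenitor expresses half of the differentiated type's markers at
  intermediate (2-fold) level, mirrored in both species — so the multi-type
  marker exclusion and intermediate AUROCs are exercised exactly as in
  continuously differentiating tissue.
- One species-specific type per species combines unique ortholog-block and
  private-gene markers, a down-regulation of a dedicated per-species block
  of matched marker genes, and a mild tilt toward one matched program
  (sub-threshold: a quarter of the marker effect on log2 scale, on half that
  program's markers, a different program per species). This triad is what
  makes the unmatched types behave like real lineage-specific populations:
  residual types that are simply "flat" over the shared variable genes
  become each other's best match by elimination, whereas a signature that
  copies a matched program is indistinguishable from homology. The tilt
  stays below the marker-detection margin (the tilted genes are less
  elevated in the unique type than in the dataset-wide rest mean, so they
  are never claimed as its markers).
- Counts are negative binomial (dispersion α = 0.15; α = 0 degrades to
  Poisson) with per-cell log-normal depth (σ = 0.3) times a per-library
  multiplier (two libraries per species, 1.0–1.6), so the per-library QC
  rules and stratified grouping are load-bearing.
- The candidate table contains every true pair with the top score and the
  reverse flag set, plus decoys for 30 % of genes at strictly lower scores —
  or, with probability 0.1, a tied score with the reverse flag unset — so
  all three resolution rules fire.

Defaults (3000 orthologs, 200 private genes per species, 6 types and 300
cells per type per species) are the standing validation conditions; the
test-suite's small fixture scales everything down (600 orthologs, 100
cells/type, 16 markers/type) and raises dispersion to 0.4, because with so
few genes the profile similarity rankings become nearly deterministic and
overstate the separability of residual types.

What the generator does **not** emulate: doublets and ambient RNA (the UMI
cap and 2SD rule are exercised on depth outliers only), mitochondrial
content (QC rule 4 is tested on synthetic QC tables instead), non-linear
batch effects beyond scalar depth, and gene–gene correlation within
programs. Passing tests therefore demonstrate that the statistics and the
fusion rule behave as specified and recover planted structure under
realistic count noise — not that any particular biological dataset would
yield a specific map.

## Numerical choices and degenerate inputs

- All randomness flows through explicit integer seeds (`numpy` Generator);
  same config + seed ⇒ byte-identical outputs, independent of row order.
- Spearman/rank operations use midranks throughout; correlations of
  constant profiles are NaN with a warning in the pseudo-bulk comparison and
  a hard error in the voting network (a constant pseudo-cell profile
  indicates an upstream problem).
- The GSVA-style walk breaks ordering ties by gene position (stable sort);
  ties in the kernel statistic have measure zero for continuous input.
- Bonferroni p-values are clipped at 1; all-tied genes (NaN under the
  tie-corrected normal approximation) are assigned p = 1.
- A degenerate enrichment matrix (all scores equal) scales to 0.5 with a
  warning rather than dividing by zero.
- The retention threshold is strict (> 0.80) while the hit threshold is
  inclusive (≥): boundary behavior is pinned by tests at 0.79/0.80/0.81.

## Known limitations

- The rank-sum marker test will diverge from hurdle-model marker lists on
  data with strong detection-rate structure; only the filtering semantics
  are shared.
- The variable-gene recipe is a fixed, documented approximation; gene lists
  from other implementations will differ in the tails of each bin.
- One-directional enrichment means pairs can be `partial` when a marker set
  is lost in translation; such pairs rely on the AUROC arm alone.
- Multi-species comparisons are pairwise; no transitive chaining or joint
  training across more than two datasets.
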