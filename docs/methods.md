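# Methods

## Specificity scoring and selection

Per-region mean FPKM pools all samples of a region across experimental
groups: region specificity is treated as a property of the region, not of
the group contrast, and the selection deliberately is *not* a
differential-expression analysis — it asks where a gene's expression lives,
not whether it responds to treatment.

The tissue-specificity index of a gene is `x_max / Σ x_i` over the declared
regions; the combined-pair variant replaces `x_max` with the sum of two
designated regions' means. Exactly one combined pair is supported per run
(default MRN/VTA); a gene is scored by the single-region rule first and by
the pair rule only as a fallback, so a gene with one dominant region keeps
its single-region assignment even when its pair-summed share is larger.
Selection uses a strict inequality at the threshold τ (default 0.5, soft by
design — TSI 0.5 means half the gene's summed regional signal sits in one
region). Ties on the maximum are broken by declared region order and
flagged. All-zero genes have no defined TSI and are skipped with a log
entry rather than failing the run. No minimum-expression floor is applied
by default (`min_max_fpkm = 0`): genes with maxima of tens of FPKM are
legitimate markers; the floor exists for users who want one. Reported
tables round TSI to two decimals; all internal computation keeps full
precision.

The expression-tier breakdown counts, per region, the selected genes whose
mean in that region strictly exceeds each threshold (default 100 and
1000 FPKM). Combined-pair genes count toward **both** member regions, each
under its own regional mean — this is what makes the bundled worked
example's pair segment contribute 17 genes to both MRN and VTA totals.

## Network edge enrichment

Scored interaction networks are read in the protein-links TSV dialect
(`protein1 protein2 combined_score`), scores normalized to [0, 1]
(auto-detecting the 0–1000 integer convention), A–B/B–A duplicates merged
keeping the maximum, self-loops dropped. Confidence tiers keep edges with
score strictly above 0.150 / 0.4 / 0.7 / 0.9 (low/medium/high/highest), so
tiers are nested.

The enrichment null resamples `B` node sets of equal size uniformly without
replacement from the graph and reports the add-one permutation p-value
`p = (1 + #{perm ≥ obs}) / (B + 1)`, which is never below `1/(B+1)` and is
exact-level conservative. Genes absent from the graph are excluded from the
null's set size, matching how mapped-protein databases silently restrict
sets. Uniform sampling is the default; a degree-binned sampler (degree
deciles) is available as a sensitivity analysis for graphs with heavy-tailed
degree distributions, where dense sets of hubs would otherwise look
spuriously enriched. A density-based analytic expectation,
`C(k,2) × (edges above cutoff) / C(n,2)`, is reported alongside; the two
agree on degree-homogeneous graphs and diverge on hub-dominated ones, which
is informative in itself. Interaction databases publish p-values from their
own unpublished nulls; those numbers are context, not targets, and every
output row here is labelled with the null method actually used.

## Projection statistics

Biplots use correlation-mode PCA: samples are observations, genes are
variables standardized to zero mean and unit variance across samples. The
alternative (covariance mode, available via `standardize=False`) lets a
handful of 1000+ FPKM genes dominate the axes, which defeats the purpose of
comparing mixed-magnitude marker sets. Zero-variance genes are dropped with
a log entry. Components come from the SVD of the standardized matrix; sample
scores are `U·S` and gene coordinates `V·S`, placing both on the same axes.

Raw SVD signs are arbitrary, so PC1 is oriented to correlate non-negatively
with raw gene mean expression — "right" always reads as "elevated overall
expression" — and higher components are oriented so their largest-magnitude
gene coordinate is positive (first in input order on ties). This makes side
counts reproducible run to run.

Side-preference tests are exact binomial at p₀ = 0.5 by direct pmf
summation; the two-sided p sums all outcomes whose pmf does not exceed the
observed one (1e-12 relative tolerance for floating-point ties at symmetric
outcomes). Items with an exactly zero PC1 coordinate — a measure-zero event
on real data — are counted to the right and flagged rather than erroring.
Both the two-sided test (for gene-side asymmetry) and the one-sided
upper-tail test on the majority side (for all-k-of-n sample clustering
claims) are always reported.

Agglomerative clustering standardizes gene profiles, uses Euclidean distance
and Ward linkage by default (configurable to the other scipy linkages), and
cuts either at a cluster count or a height. scipy's implementation is
deterministic for a fixed input order, merging the lowest-index pair on
ties.

## Synthetic data

The generator emulates the targeted study design: 5 regions × 3 groups × 3
replicates (45 samples), 2000 genes, per-gene log-normal baseline FPKM
(meanlog 2, sdlog 1.5 — median ≈ 7 FPKM with a heavy right tail), and
multiplicative log-normal noise with unit mean and CV 0.3. Planted signal:
20 single-region genes per region and 17 shared-pair genes (elevated
tenfold), plus optional group-effect genes (default fold 2 in the affected
groups, optionally region-restricted so a hormone-like regional group
response can be emulated). Noise is multiplicative because FPKM are
non-negative and right-skewed; fold effects are multiplicative for the same
reason. The companion graph generator plants dense modules
(within-module edge probability 0.3 over background 0.02) and draws each
edge's confidence score uniformly within one of the four tier bands.

What the generator does **not** emulate: gene–gene correlation beyond the
planted structure, library-size or batch effects, count-level (Poisson/NB)
noise, region-specific gene numbers, or any real gene's magnitude. Passing
recovery tests therefore shows the selection machinery is correct and
well-calibrated under clean planted signal — not that real tissues yield
any particular marker count.

## Problem sizes and numerical choices

Recovery checks run at the defaults above (2000 genes, 45 samples);
null-calibration checks use a 300-node background graph (edge probability
0.05), 200 random sets of 40 genes and B = 199 permutations — sizes chosen
so the discrete permutation p-values resolve the 0.05 level with limited
tie-induced conservatism while each replicate stays a fast dense-matrix
count. Pipeline runs derive per-stage seeds from the single config seed via
`numpy.random.SeedSequence.spawn`, making the manifest (file checksums +
seed + config echo) a sufficient record to reproduce a run bit for bit.

## Known limitations

- The combined-pair rule supports one declared pair per run; discovering
  which pair (if any) a dataset warrants is out of scope.
- No identifier mapping: gene symbols must match between expression matrix,
  panels and network, case-sensitively.
- The permutation null treats the gene set as exchangeable with all graph
  nodes; for strongly hub-biased sets use the degree-binned option and
  compare.
- The bundled mitophagy panel is a documented partial seed (Prkcd, Pink1,
  Park2, Gak) of a larger curated set, and the myelin panel is the Mbp seed
  alone; both are data files meant to be extended by the user.
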