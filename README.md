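# brsgkit

Toolkit for selecting **brain-region-specific genes (BRSGs)** from bulk
RNA-seq FPKM matrices and characterizing what they do — aimed at
neuro-transcriptomics studies that profile several brain regions across
experimental groups (e.g. control vs. chronically aggressive vs. chronically
defeated mice in a social-stress model) and want region marker genes, their
network wiring, and group-wise expression trends from one reproducible
pipeline.

## The statistic at the core

For a gene with mean FPKM `x_1 … x_n` over `n` regions (default five: HPC,
HPT, STR, MRN, VTA), the **tissue-specificity index** is

```
TSI = x_max / Σᵢ xᵢ                       (single-region rule)
TSI = (x_a + x_b) / Σᵢ xᵢ                 (combined-pair rule)
```

TSI runs from `1/n` (uniform expression) to 1 (fully confined) and is
invariant to rescaling a gene's FPKM. The combined-pair rule serves gene
programs shared by two closely related regions — here the midbrain
monoaminergic pair VTA (dopaminergic) and MRN (serotonergic). A gene is a
BRSG when its TSI strictly exceeds a soft threshold τ (default 0.5); the
single-region rule takes precedence, the pair rule is a fallback.

Downstream, the toolkit

- breaks BRSG sets down by expression tier (>100, >1000 FPKM) per region;
- tests whether a BRSG set is more densely wired in a scored
  protein-interaction network than random same-size node sets, at the
  standard confidence tiers (score > 0.15 / 0.4 / 0.7 / 0.9), using a
  seeded permutation null (`p = (1 + #{perm ≥ obs}) / (B + 1)`);
- draws correlation-mode PCA biplots of samples against gene sets, with a
  deterministic axis orientation (right = elevated overall expression), and
  tests side preference on PC1 with an exact binomial test at p₀ = 0.5;
- profiles named gene panels (glycinergic/neurofilament, TCA cycle, …) by
  region × group and summarizes group contrasts;
- generates synthetic FPKM matrices and scored graphs with planted ground
  truth, so every stage is testable without any download.

## Worked example

```python
import pandas as pd
import brsgkit as bk

profile = pd.Series([0.29, 0.05, 0.01, 3.89, 16.42],
                    index=["HPC", "HPT", "STR", "MRN", "VTA"], name="Dbh")
tsi, region, tie = bk.tsi_single(profile)
print(f"Dbh: TSI = {tsi:.2f}, assigned region = {region}")

spec = bk.SyntheticExpressionSpec(seed=1)          # 2000 genes, 45 samples
matrix, metadata, truth = bk.generate_expression(spec)
table = bk.select_brsgs(matrix, metadata, pair=("MRN", "VTA"), tau=0.5)
print(f"selected {len(table)} of {spec.n_genes} genes")
print(bk.breakdown_by_expression(table))
```

prints

```
Dbh: TSI = 0.79, assigned region = VTA
selected 117 of 2000 genes
        total  >100 FPKM  >1000 FPKM
region
HPC        20         10           0
HPT        20          7           2
STR        20          6           0
MRN        37         13           0
VTA        37         15           1
```

Dbh (dopamine beta-hydroxylase) concentrates 79% of its summed regional mean
in VTA, so it passes τ = 0.5 as a VTA marker. On the synthetic data the 100
planted single-region genes (20 per region) are all recovered — each region's
total is its 20 planted genes, and MRN/VTA additionally absorb the 17 planted
shared-pair genes (counted in both member regions) — with only noise-level
extras; the tier columns count how many of each region's markers exceed 100
and 1000 FPKM there.

The same flows are available from the shell:

```bash
brsg-kit simulate --config sim.yaml      # expression/metadata/ppi/truth TSVs
brsg-kit tsi --expression expr.tsv --metadata meta.tsv \
         --pair MRN,VTA --out brsg_table.tsv
brsg-kit run --config run.yaml           # full pipeline + manifest.json
```

A bundled worked-example dataset (`brsgkit.load_midbrain_example()`) carries
published per-region mean FPKM for 25 midbrain-enriched genes together with
their reference TSI values; recomputing every row reproduces the reference
column at two decimals.

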