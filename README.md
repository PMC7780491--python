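# migmod

Co-expression network modules with an excess of rare, family-segregating
functional variants.

Complex neurological disorders such as migraine show strong heritability
that common variants only partly explain. One route to the missing
fraction is to look for *sets* of genes — modules of a tissue co-expression
network — that accumulate rare functional variants segregating with the
phenotype in multi-generation families. `migmod` implements that analysis
end to end:

1. **Network construction** (WGCNA-style): genes are ranked by whole-network
   connectivity `k_i = Σ_{j≠i} |cor(x_i, x_j)|` and the top *k* retained; an
   unsigned adjacency `a_ij = |cor(x_i, x_j)|^β` is built with the smallest
   power β whose scale-free topology fit reaches `R² ≥ 0.8`; the topological
   overlap dissimilarity

   `d_ij = 1 − (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, with
   `ℓ_ij = Σ_u a_iu a_uj`,

   is computed 100 times on random 90%-sample subsets and averaged into a
   consensus; modules (≥ 30 genes) are cut from the average-linkage
   dendrogram with an adaptive branch-pruning (dynamic tree cut) algorithm
   and named by the conventional colour sequence, "grey" collecting
   unassigned genes.
2. **Module validation**: each module's mean within-module topological
   overlap is compared against random same-size gene sets (permutation p
   with add-one smoothing).
3. **Mutated-gene calling**: a gene is *mutated* when it carries a variant
   that is functional (frameshift/non-frameshift indel, non-synonymous SNV,
   splice site, stop-gain/stop-loss), rare (population MAF < 5%, absent =
   rare), and segregates dominantly in at least one family — every
   genotyped affected member carries it and affected carriers / carriers
   ≥ 0.9. Genes with only non-qualifying variants are *non-mutated*; genes
   with no variants are *undetected* and excluded.
4. **Burden testing**: modules whose mutated genes are significantly more
   mutation-tolerant (higher mean RVIS, one-sided Welch t) are excluded;
   the rest are tested by one-tailed Fisher's exact test on
   (mutated, non-mutated) × (in module, rest of network), Bonferroni-
   corrected over tested modules.
5. **Replication**: the burden test is repeated on an independent sporadic
   case cohort and a population control cohort, separately; a module
   *replicates* when significant in cases but not in controls.
6. **Functional annotation**: expression-weighted cell-type enrichment
   (summed specificity vs. 10 000 bootstrap gene sets) and binomial pathway
   over-representation, both BH-FDR-adjusted.

A first-class synthetic-data module generates expression matrices with
planted co-expressed blocks, pedigrees with a gene-dropped causal allele
under incomplete penetrance, and variant tables with a configurable excess
of qualifying variants in one module — so every stage is testable against
known ground truth.

## Worked example

```python
import numpy as np
from migmod.synthetic import (simulate_modular_expression, simulate_families,
                              simulate_variant_table)
from migmod.pipeline import RunConfig, run_discovery

expr, truth = simulate_modular_expression(
    n_background=200, module_sizes=[50]*5, n_samples=100,
    within_module_cor=0.7, seed=1)
families, carriers = simulate_families(40, penetrance=0.9, seed=2)
variants, vtruth = simulate_variant_table(
    expr.gene_ids, truth.true_module_labels, enriched_module="block1",
    families=families, carrier_maps=carriers,
    qualifying_rate_base=0.05, qualifying_rate_enriched=0.30, seed=3)
scores = {g: float(s) for g, s in
          zip(expr.gene_ids, np.random.default_rng(4).normal(size=expr.n_genes))}

config = RunConfig(k_top_genes=450, seed=9)
result = run_discovery(config, expr, variants, families, scores)
print(f"chosen power: {result.chosen_power} (signed R^2 = {result.scale_free_r2:.3f})")
print(f"detectable genes: {result.summary['n_genes_detectable']}, "
      f"mutated: {result.summary['n_genes_mutated']}")
for r in result.burden:
    print(f"{r.module:>10}  a={r.mutated_in:<3} OR={r.odds_ratio:5.2f} "
          f"CI=({r.ci_low:.2f}, {r.ci_high:.2f})  p_adj={r.p_adjusted:.2e}"
          f"  {'*' if r.significant else ''}")
```

prints

```
chosen power: 14 (signed R^2 = 0.813)
detectable genes: 450, mutated: 36
     brown  a=12  OR= 4.95 CI=(2.29, 10.68)  p_adj=7.95e-04  *
 turquoise  a=2   OR= 0.38 CI=(0.09, 1.61)  p_adj=1.00e+00
    yellow  a=5   OR= 1.32 CI=(0.49, 3.57)  p_adj=1.00e+00
     green  a=3   OR= 0.71 CI=(0.21, 2.41)  p_adj=1.00e+00
      blue  a=0   OR= 0.09 CI=(0.01, 1.53)  p_adj=1.00e+00
```

The five planted 50-gene blocks are recovered as modules; the block given a
6× excess of qualifying segregating variants (here labelled *brown*) is the
only module with a significant mutated-gene burden after Bonferroni
correction: 12 of its 50 genes are called mutated against a background rate
of ~5%, odds ratio 4.95 with 95% CI (2.29, 10.68).

## Command line

`migmod` exposes each stage as a subcommand over the standard text formats
(expression TSV, VCF, 6-column PED, GMT, 2-column score TSV):

```sh
migmod simulate --config sim.yaml --out-dir data
migmod network --expression data/expression.tsv --k 5000 --out-dir net
migmod flag-mutations --vcf data/variants.vcf --mode familial \
    --ped data/families.ped --genes genes.txt --out status.tsv
migmod burden --modules net/modules.tsv --status status.tsv --out burden.tsv
migmod replicate --cases burden_cases.tsv --controls burden_controls.tsv --out rep.tsv
migmod enrich-celltype --cell-means cellmeans.tsv --genes module_genes.txt --out ewce.tsv
migmod enrich-pathway --gmt pathways.gmt --query query.txt --reference ref.txt --out pw.tsv
migmod run --config run.yaml --out-dir results
```

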