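# seednet

Seeded brain-region co-expression networks and guilt-by-association gene
prioritization.

## The problem

Established disease risk genes for a neurodegenerative disorder such as
Alzheimer disease (AD) tend to be *co-expressed* — and more strongly so in
the brain regions the disease hits hardest. `seednet` turns that observation
into a reusable analysis for anyone with (i) a gene × sample brain expression
matrix annotated by donor and region, (ii) GWAS summary statistics, and
(iii) a seed set of established risk genes:

1. **Region-level expression.** Probes are averaged into genes, then each
   gene's expression is reduced to one value per brain region with a
   mixed-effect model, `y = β_region + u_donor + ε`, `u ~ N(0, σ_u²)`, that
   accounts for repeated sampling of the same donors and regions.
2. **Seeded networks.** For any stated region subset (a structure such as
   the cerebellum, or the cerebral regions affected early vs late in
   disease), the co-expression network has edge weights `|r|`, the absolute
   Pearson correlation across regions. Every non-seed gene *g* gets a score
   `S(g) = Σ_{s∈seeds} |r(g, s)|`, normalized to a percentile rank
   `rank/(N+1)`, which is uniform on (0,1) and therefore comparable across
   networks.
3. **MRC.** Seed genes themselves are scored leave-one-out: each seed is
   ranked against all non-seed genes by its summed correlation to the
   *remaining* seeds. The median of these ranks — the **median ranking by
   correlation (MRC)** — summarizes how tightly the seed set clusters in one
   network; MRC ≈ 0.5 means the seeds are unremarkable.
4. **Prioritization.** Network percentiles become Z-scores via the
   upper-tail normal quantile and are combined with gene-level GWAS
   Z-scores (best-SNP p corrected as `p_gene = 1 − (1 − p_best)^((N+1)/2)`
   for a gene with N SNPs) using an equal-weight Stouffer sum,
   `Z = (Z_gwas + Z_net)/√2`. Candidates are filtered to genes whose
   model-organism knockout yields an AD-related phenotype (defective
   memory/aging, oxidative stress, premature aging) and Benjamini–Hochberg
   FDR is computed within that filtered set.

A synthetic-data module generates complete studies with a *planted*
seed-gene module whose strength varies by brain structure (plus matched
GWAS Z-scores and phenotype tables), so every stage is testable without any
data download. The package also ships the published 52-gene seed list and
per-seed ranking tables as fixtures.

## Worked example

`examples/02_simulate_and_score.py` simulates 300 genes across 85 regions in
6 donor brains, with the 52 seed genes loading on a region-level latent
factor at a strength that differs by structure, then runs the pipeline:

```
structure group    planted loading   pipeline MRC
  cerebrum_early        0.45       0.934
  cerebrum_late         0.65       0.988
  cerebellum            0.00       0.390
  brain_stem            0.35       0.852
```

The recovered MRC is ordered exactly as the planted loadings; in the
structure with no planted module the seeds rank like any other gene.
`examples/03_prioritize_candidates.py` plants 10 signal genes among 2000 and
recovers 9 of them in the top 10 of the combined ranking
(`precision@10 = 0.9`); `examples/01_reproduce_published_rankings.py`
recomputes the published summary numbers from the packaged tables
(cerebrum MRC 0.748, brain stem 0.649, cerebellum 0.575; early 0.615 vs
late 0.733, one-sided rank-sum p = 0.0524; top candidate combined Z 4.20,
FDR q 8.7×10⁻³ over 654 filtered genes).

There is also a thin CLI mirroring the stages:

```sh
seednet simulate --seed 7 --out-dir sim1
seednet prep     --expression sim1/expression.tsv --annotations sim1/annotations.tsv --out region_expr.tsv
seednet network  --expression sim1/expression.tsv --annotations sim1/annotations.tsv \
                 --seeds sim1/seeds.txt --subset sim1/regions_cerebrum_late.txt --out scores.tsv
seednet rank     --expression sim1/expression.tsv --annotations sim1/annotations.tsv \
                 --seeds sim1/seeds.txt --gwas sim1/gwas.tsv --phenotypes sim1/phenotypes.tsv --out ranked.tsv
```

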