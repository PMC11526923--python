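# metaboage

Kinship-aware analysis of aging signatures in targeted plasma metabolomics
panels, exercised end-to-end on a synthetic cohort generator with known
ground truth.

The package implements, as reusable tested components:

- **`metaboage.simulate`** — synthetic cohorts: block-structured (breed-like)
  genotypes with admixture, per-metabolite heritability via a kinship-drawn
  polygenic term, a linear age → creatinine → metabolite mediator chain,
  injected batch/run-order drift, hemolysis grades and missingness.
- **`metaboage.preprocess`** — the LC-MS technical-normalization ledger:
  missingness filter (>10%), hemolysis filter (grade 4), log transform with
  per-sample centering, batch x run-order residualization, per-batch unit
  variance scaling, 10-NN mean imputation, technical-covariate regression.
  A state machine enforces the stage order.
- **`metaboage.kinship`** — variance-standardized GRM
  (`K_ij = mean_k z_ik z_jk`), SNP MAF/call-rate filters, PLINK-style
  `.rel`/`.rel.id` I/O, and breed classification from ancestry proportions
  (>= 85% threshold, minimum group size, both-sexes rule).
- **`metaboage.lmm`** — the numeric core: exact REML/ML fits of
  `y ~ N(Xb, sg2*K + se2*I)` by one eigendecomposition of K plus a 1-D
  profile-likelihood search; GLS fixed effects with t-tests, BLUPs,
  SNP-heritability, Benjamini-Hochberg FDR across metabolites, the two-stage
  age x weight interaction rule, covariate contrasts (diet, urinalysis) and
  subset refits.
- **`metaboage.multivariate`** — PCA with per-metabolite scaling, sequential
  Tracy-Widom (beta=1) selection of non-random components, Type III ANCOVA
  variance partitioning with sum-to-zero contrasts, per-PC SNP-heritability.
- **`metaboage.covariation`** — fully adjusted residuals
  (`y' = y - Xb - u`), pairwise Pearson correlation with exact-t p-values
  and FDR, deterministic UPGMA clustering with newick export.
- **`metaboage.mediation`** — linear causal mediation (ACME = a*b, proportion
  mediated = ACME / total), case-resampling bootstrap CIs (permutation null
  optional), and closed-form sensitivity to residual mediator-outcome
  confounding (ACME(rho) with root rho0).
- **`metaboage.pipeline`** — orchestration with plain-TSV intermediates and a
  deterministic JSON manifest (timings go to the log so fixed-seed runs are
  byte-identical).

## CLI

The console script is `mwas`; stages exchange plain TSV files, so every stage
can be re-run from saved intermediates:

```sh
mwas simulate --seed 1 --out runs/bundle
mwas grm --genotypes runs/bundle/genotypes.tsv --out runs/k.rel
mwas preprocess --metabolites runs/bundle/metabolites.tsv \
    --sample-meta runs/bundle/sample_meta.tsv --out runs/norm
mwas mwas --metabolites runs/norm/normalized.tsv \
    --cohort runs/bundle/cohort.tsv --grm runs/k.rel --out runs/mwas.tsv
mwas mediate --metabolites runs/norm/normalized.tsv \
    --cohort runs/bundle/cohort.tsv --n-boot 10000 --seed 17 --out runs/med.tsv

# or everything at once, with a deterministic manifest:
mwas run-all --synthetic --seed 1 --out runs/full
mwas report --rundir runs/full
```

`run-all` also accepts user tables (`--metabolites/--sample-meta/--cohort`
plus `--grm` or `--genotypes`) and a YAML config (`--config`) whose keys
mirror `metaboage.pipeline.PipelineConfig` (filters, FDR alpha, mediation
settings, and a `simulation:` block).

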