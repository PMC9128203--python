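# hlafine

Statistical fine-mapping of the human HLA region for disease and expression
traits, over a genotype matrix that mixes three variant classes: ordinary
SNP dosages, classical (two-field) HLA allele dosages, and amino-acid
polymorphism dosages derived from the alleles.

The HLA locus is the strongest association signal for many immune-mediated
diseases (asthma, autoimmunity, infection), but its extreme polymorphism
and long-range LD defeat single-variant interpretation. This package
implements the analysis toolkit for resolving such a locus:

* **Encoding** (`hla_encode`): classical alleles determine protein
  sequence, so allele dosages linearly imply amino-acid dosages. Each
  residue R at protein position k of gene g becomes a biallelic indicator
  `AA_<g>_<k>_<R>` with dosage = Σ dosages of the g alleles carrying R at
  k. Standard imputation-era QC (call rate > 95% **or** info score > 80%,
  exact Hardy-Weinberg p > 1e-10, MAF > 0.1% for SNPs; frequency ≥ 1% for
  alleles and amino acids) with a full per-variant report.
* **Association** (`assoc`): per-variant covariate-adjusted logistic
  regression (additive or dominant coding), conditional scans, interaction
  tests, Cochran's Q heterogeneity between case groups, and
  direction-constrained one-sided inverse-variance meta-analysis for
  replication, with Bonferroni thresholds.
* **Fine-mapping** (`susie`): a from-scratch sum-of-single-effects (SuSiE)
  engine. The model y = Σ_l X b_l + ε places each effect b_l on exactly one
  variant; iterative Bayesian stepwise selection yields per-effect
  inclusion weights α_l, per-variant posterior inclusion probabilities
  PIP_j = 1 − Π_l (1 − α_lj), and minimal level-95% credible sets filtered
  by purity (minimum |r| among members). Exposed as a scikit-learn-style
  estimator, `SuSiE(L=10).fit(X, y)`.
* **eQTL mapping** (`eqtl`): nominal cis scans (±1 Mb around the TSS,
  inclusive) by OLS or by a kinship linear mixed model for related samples,
  Benjamini-Hochberg FDR, and per-gene eQTL fine-mapping with the same
  engine.
* **Integration** (`integrate`): exact-id overlap of disease and eQTL
  credible sets, and interval annotation (e.g. enhancer chromatin states
  from BED).
* **Synthetic cohorts** (`synthdata`) and **validation** (`simval`):
  haplotype pools with block LD, classical alleles deterministically
  implying residues, diploid dosages with optional imputation noise, binary
  and quantitative traits with known causal truth, covariate confounding
  and family relatedness — used to validate calibration of the fine-mapping
  engine (credible-set coverage, null behavior, top-PIP identification).

## Worked example

```python
import numpy as np
import hlafine as hf

# a synthetic high-LD cohort: 500 SNPs in 10 blocks + 2 HLA genes
pool = hf.build_haplotype_pool(hf.PoolConfig(n_haplotypes=2000), seed=7)
snps, alleles, _ = hf.simulate_genotypes(pool, 2000, seed=1)
aa = hf.translate_alleles_to_aa(alleles, pool.allele_aa_map)
G = hf.assemble_combined_matrix(snps, alleles, aa)

# a binary trait driven by one SNP (log-OR 0.8)
causal = pool.snp_ids()[120]
truth = hf.SimulationTruth([causal], [0.8], "binary", prevalence=0.2)
pheno = hf.simulate_binary_phenotype(snps, truth, seed=2)

fit = hf.SuSiE(L=10).fit(
    G.dosages, pheno.binary["case"],
    variant_ids=G.variant_ids,
    positions=np.array([v.pos for v in G.variants]),
)
print("credible sets:", [cs.variant_ids for cs in fit.credible_sets_])
print("PIP of causal:", round(fit.pip_[G.variant_ids.index(causal)], 3))
```

Output:

```
credible sets: [['snp_b2_46', 'snp_b2_20', 'snp_b2_6', 'snp_b2_4']]
PIP of causal: 0.317
```

One level-95% credible set is reported and it contains the true causal
variant (`snp_b2_20`, the 121st SNP) together with three of its LD-block
partners: the data cannot distinguish among four highly correlated
variants, so the posterior mass (the PIPs, summing to ~1 over the set) is
spread across them — exactly the honest answer a credible set is designed
to give in a high-LD region.

The same stages are scriptable from the shell via the `hlafine` CLI
(`simulate`, `encode`, `qc`, `assoc`, `het`, `meta`, `finemap`, `eqtl`,
`eqtl-finemap`, `overlap`, `simval`); each subcommand consumes and produces
the package's TSV dialects (see `hlafine --help`).

### Dosage TSV dialect

Variants are rows; the first six columns are
`id  kind  chrom  pos  ref  alt` (`kind` ∈ {SNP, HLA_ALLELE, AA_POLY}),
followed by one column per sample with dosages in [0, 2] (`.` = missing).
The allele→amino-acid dictionary is a flat 4-column TSV
(`gene  allele  residue_pos  residue`).

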