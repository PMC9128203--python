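# Methods

## The combined genotype matrix

Three variant classes share one samples × variants dosage matrix with
values in [0, 2] (NaN = missing): SNP dosages, classical two-field HLA
allele dosages, and amino-acid indicator dosages. Because a classical
allele fixes the protein sequence, translation is a linear map: the dosage
of residue R at protein position k of gene g is the sum of the dosages of
the g alleles carrying R at k. Every residue at every position present in
the dictionary becomes its own biallelic indicator, including both residues
of a strictly biallelic position; residues co-inherited on one allele group
therefore appear as perfectly correlated columns, which is intentional —
the fine-mapping engine, not the encoding, decides what is resolvable.
Positions missing from some alleles (sequence gaps) contribute zero to
every indicator at that position; no explicit absence indicator is emitted.
Per-individual conservation (Σ residue dosages at a position = Σ dosages of
the alleles defining that position) holds exactly for noiseless input and
is enforced up to a ploidy tolerance (`ploidy_tol`, default 1e-6) that must
be disabled for noisy imputed dosages, whose per-gene sums drift from 2.

## QC

SNPs are retained when (call rate > `min_call_rate` OR imputation info
score > `min_info`) AND exact-test HWE p > `min_hwe_p` AND MAF >
`min_maf`; defaults 0.95 / 0.80 / 1e-10 / 0.001. The call-rate/info clause
is deliberately a disjunction: a variant may be either well genotyped or
well imputed. HWE is computed on dosages rounded to hard calls, using the
exact conditional test (total probability of heterozygote configurations
no more probable than the observed one, given the allele counts);
monomorphic columns return p = 1. The info score is the MaCH-style ratio
var(dosage) / (2p(1−p)) clipped to [0, 1], with monomorphic columns defined
as 1. Classical alleles and amino-acid indicators are filtered only on
allele frequency (≥ `min_hla_freq`, default 0.01), optionally within every
level of a sample-group column (the per-ancestry variant of the filter).
QC is idempotent: a filtered matrix passes unchanged.

## Association, heterogeneity, replication

Case/control association is maximum-likelihood logistic regression of the
0/1 trait on dosage plus covariates, Wald z test, listwise deletion of
missing values. Dominant coding maps dosage d to min(d, 1). Perfect
separation is flagged (`converged=False`, infinite-beta sentinel) rather
than reported as an estimate; Firth correction is out of scope. Conditional
scans append the conditioning variants' dosages to the covariates and skip
re-testing them. Effect-sharing between two case groups uses Cochran's
Q = Σ w_i (β_i − β̄_w)², w_i = 1/se_i², χ²(k−1); when the groups share
controls the estimates are positively correlated and Q is anti-conservative
— kept as-is because that is the standard GWAS-tooling behavior being
reproduced, and flagged here as a fidelity-over-correctness choice.
Replication meta-analysis is fixed-effect inverse-variance on the log-odds
scale; the one-sided p constrains the direction to the discovery sign
(p_two/2 on agreement, 1 − p_two/2 otherwise). Sample-size-weighted z
meta-analysis is not implemented.

## The sum-of-single-effects engine

Model: y = Σ_{l=1..L} X b_l + ε, ε ~ N(0, σ²I); each b_l has one nonzero
coordinate with uniform selection prior and N(0, σ0l²) coefficient prior.
Columns are centered and scaled to unit variance before fitting and the
prior variance is interpreted on that standardized scale; y is centered
(binary traits enter as 0/1 — the linear treatment standard for
fine-mapping large cohorts). Fitting is coordinate-ascent variational
inference (IBSS): each effect is refit by exact single-effect regression on
the residual left by the others. Per variant j: β̂_j = x_j'r / (x_j'x_j),
s_j² = σ²/(x_j'x_j), log Bayes factor
lbf_j = ½log(s_j²/(σ0²+s_j²)) + ½β̂_j²σ0²/(s_j²(σ0²+s_j²)), α_j ∝
exp(lbf_j), posterior mean μ_j = σ0²/(σ0²+s_j²)·β̂_j.

Defaults and numerical choices:

* `L = 10` effects; an upper bound, not an estimate — switched-off effects
  are harmless.
* Per-effect prior variance re-estimated each sweep by bounded
  maximization of the single-effect log marginal likelihood over log σ0²
  in [−30, 15]; if no positive value beats σ0² = 0 the effect is switched
  off (α uniform, μ = 0) — this is what makes the null case report nothing.
  Initial value 0.2·var(y).
* Residual variance updated from the expected residual sum of squares.
* Convergence: |ΔELBO| < 1e-3, max 100 sweeps; the ELBO is monotone
  non-decreasing by construction (asserted in tests to 1e-6 slack).
  Non-converged fits are returned with `converged_=False`.
* Zero-variance columns get α = 0 with a warning; missing dosages must be
  mean-imputed upstream (`mean_impute`), or the analysis restricted to
  well-genotyped samples — both modes are the caller's choice.
* Exactly duplicated columns split an effect's α evenly by symmetry and
  are reported together in one credible set.

Credible sets: per effect, sort α descending (ties broken by genomic
position then id, so extraction is deterministic), take the minimal prefix
reaching the coverage level (default 0.95); purity = minimum absolute
pairwise correlation of member genotype columns (singletons = 1); sets with
purity < 0.5 and duplicate sets are dropped. PIPs use effects with positive
prior variance by default (`effects="nonnull"`); "all" and "cs" selectors
exist. The engine is a scikit-learn estimator (`fit`/`predict`/
`get_params`, fitted attributes with trailing underscores) so it composes
with sklearn tooling; `susie_fit` is the functional wrapper.

## eQTL mapping

The nominal cis pass tests every variant with |pos − TSS| ≤ 1 Mb
(boundary inclusive, strand ignored) by OLS of expression on dosage +
covariates, two-sided t test with n − q − 1 dof. For related samples the
single-random-effect LMM y = Wγ + xβ + u + ε, u ~ N(0, σg²K), is fitted by
eigendecomposing K once, profiling the variance ratio λ = σg²/σe² per gene
under the covariate-only model by a REML grid search (41 log-spaced points
in [1e-5, 1e5]) refined by golden section, then testing each variant by GLS
in the rotated coordinates with the gene's λ reused across variants (the
usual population-parameters approximation). With K = I the LMM reduces
exactly to the OLS scan. Columns inside the covariate span are reported as
NaN rather than tested. FDR is Benjamini-Hochberg across all gene ×
variant tests of a scan; genes with any q < 0.05 are fine-mapped by
residualizing covariates out of expression and running the engine over the
cis window. Expression is assumed pre-normalized. Permutation-pass
empirical p-values are out of scope.

## Synthetic cohorts

The generator reproduces the structural features the analyses depend on,
not any particular population's LD. SNP haplotypes come from a
template-copying process: each LD block holds `n_templates` (default 4)
random template haplotypes; a haplotype copies one template, resampling
each site independently from the block's frequencies with probability
1 − `sharing_rate` (default 0.9). Within-block correlation rises
monotonically with the sharing rate; cross-block correlation is ~0. Each
haplotype carries one classical allele per HLA gene, drawn from configured
frequencies; a generated allele→residue dictionary (1-3 residues per
position) makes residues deterministic given alleles. Individuals are two
haplotypes drawn uniformly with replacement; imputation noise is additive
truncated Gaussian on dosage (the real error process is unknown; this
merely perturbs dosages plausibly). Optional two-subpopulation structure
tilts template weights by ancestry and loads PC1 on the ancestry label, so
covariate adjustment is actually exercised. Binary traits are Bernoulli
under a logistic model whose intercept is solved by bisection (tolerance
1e-4) to hit the target prevalence; quantitative traits get residual
variance set so the causal variants explain the requested variance
fraction. Relatedness is block-diagonal expected kinship (full-sib families,
0.5 off-diagonal).

What passing tests on these cohorts do **not** show: performance under real
HLA LD (orders of magnitude denser and longer-ranged), under realistic
allele-frequency spectra, or under imputation error correlated with LD.
They do show that the machinery is calibrated when its assumptions hold and
that the encodings, conditioning logic and credible-set rules behave as
specified.

## Validation studies

`run_simulation_study` builds one haplotype pool per study (a fixed
reference panel), then per replicate draws individuals, causal variants and
the trait. Causal variants are restricted to distinct LD blocks (so "number
of signals" is well defined; a same-block stress mode exists) and to common
SNPs (pool MAF ≥ 0.1), since a near-monomorphic causal variant carries
almost no trait variance and would conflate power with calibration.
Scored per replicate: the number of purity-filtered level-95% credible
sets, whether each contains a true causal variant, and whether a true
causal attains the global top PIP. The acceptance-scale study uses 200
replicates of n = 2,000 individuals over 500 SNPs in 10 blocks
(quantitative trait, 3% trait variance per causal variant) plus 100 null
replicates — sizes chosen so a full run completes in minutes on one CPU
while leaving ~400 credible sets for the coverage estimate. The top-PIP
rate is reported descriptively only: it depends strongly on the LD panel,
so no particular value is claimed for it beyond lying in (0, 1] and
increasing with effect size.

## Known limitations

* The engine fits a linear likelihood to binary traits; at extreme
  case/control imbalance or huge effects the Gaussian approximation
  degrades (rankings remain accurate in the regimes tested).
* Cochran's Q between case groups sharing controls is anti-conservative
  (see above).
* The LMM shares one variance ratio across a gene's variants; an exact
  per-variant refit is not implemented.
* Summary-statistic fine-mapping, logistic-likelihood single effects, and
  colocalization posteriors are out of scope.
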