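"""Synthetic HLA-like cohorts with known ground truth.

Real HLA genotype panels (biobank dosages, classical-allele imputations,
expression cohorts) are access controlled, so validation and simulation
studies here run on generated cohorts that reproduce the *structural*
features the analyses depend on:

* a haplotype pool over one high-LD region, organised into LD blocks — each
  block holds a few template haplotypes that individual haplotypes copy with
  a configurable per-site fidelity, so within-block r^2 is high and tunable
  while cross-block r^2 is ~0;
* multiallelic classical HLA genes: each haplotype carries exactly one
  two-field allele per gene, and alleles deterministically imply amino-acid
  residues through an :class:`~hlafine.io_formats.AlleleAAMap`;
* diploid dosages formed by drawing two haplotypes per individual, with
  optional truncated-Gaussian noise emulating imputation uncertainty;
* binary case/control traits from a logistic model (intercept solved by
  bisection to hit a target prevalence), quantitative cis-regulated
  expression traits with a requested heritable variance fraction, covariates
  (sex, ancestry PCs tied to a latent ancestry label that can also shift
  allele frequencies), and optional sib-pair family relatedness.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import (
    AlleleAAMap,
    GeneModel,
    GenotypeMatrix,
    PhenotypeTable,
    VariantKind,
    VariantRecord,
)

_AA_ALPHABET = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
]


class ConfigError(ValueError):
    pass


@dataclass
class PoolConfig:
    """Configuration for the haplotype pool.

    ``sharing_rate`` is the per-site probability that a haplotype copies its
    block template faithfully; the complement is an independent resample, so
    1.0 gives perfect within-block LD and 0.0 gives free recombination.
    ``hla_genes`` maps gene name -> {two-field allele -> frequency}.
    """

    n_haplotypes: int = 2000
    n_blocks: int = 10
    block_size: int = 50
    sharing_rate: float = 0.9
    n_templates: int = 4
    hla_genes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "C": {"01:02": 0.25, "04:01": 0.25, "07:02": 0.3, "03:04": 0.2},
            "DQA1": {"01:02": 0.3, "03:01": 0.3, "05:01": 0.4},
        }
    )
    aa_positions_per_gene: int = 8
    chrom: str = "6"
    start_pos: int = 29_900_000
    spacing: int = 2_000
    n_subpops: int = 1
    subpop_divergence: float = 0.3  # template-weight tilt between subpops


@dataclass
class HaplotypePool:
    """Phased haplotypes over SNP blocks plus per-gene classical alleles."""

    snp_alleles: np.ndarray  # (n_haplotypes, n_snps) in {0,1}
    hla_alleles: dict[str, np.ndarray]  # gene -> array of allele labels
    block_structure: list[range]
    positions: np.ndarray
    gene_positions: dict[str, int]
    allele_aa_map: AlleleAAMap
    config: PoolConfig
    ancestry: np.ndarray  # latent subpop label per haplotype

    @property
    def n_haplotypes(self) -> int:
        return self.snp_alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.snp_alleles.shape[1]

    def snp_ids(self) -> list[str]:
        out = []
        for b, block in enumerate(self.block_structure):
            out.extend(f"snp_b{b}_{j - block.start}" for j in block)
        return out


@dataclass
class SimulationTruth:
    """Ground truth for one simulated trait."""

    causal_ids: list[str]
    effect_sizes: list[float]
    trait_type: str  # "binary" | "quantitative"
    prevalence: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ConfigError(f"unknown trait_type {self.trait_type!r}")
        if len(self.causal_ids) != len(self.effect_sizes):
            raise ConfigError("causal_ids and effect_sizes differ in length")
        if not np.all(np.isfinite(self.effect_sizes)):
            raise ConfigError("effect sizes must be finite")


def generate_allele_aa_map(
    hla_genes: Mapping[str, Mapping[str, float]],
    positions_per_gene: int,
    seed: int,
) -> AlleleAAMap:
    """Random but deterministic allele -> residue dictionary.

    Each gene gets ``positions_per_gene`` numbered protein positions; at each
    position alleles are split among 1-3 residues, so some positions are
    monomorphic, some biallelic, some carry three residues, and allele
    groups (e.g. all *03 alleles) can share residues in perfect LD.
    """
    rng = np.random.default_rng(seed)
    entries: dict[str, dict[str, dict[int, str]]] = {}
    for gene, alleles in hla_genes.items():
        names = sorted(alleles)
        gene_map: dict[str, dict[int, str]] = {a: {} for a in names}
        for k in range(positions_per_gene):
            pos = 9 + 2 * k  # arbitrary protein coordinates
            n_res = int(rng.integers(1, 4))
            residues = list(rng.choice(_AA_ALPHABET, size=n_res, replace=False))
            assignment = rng.integers(0, n_res, size=len(names))
            if n_res > 1:  # ensure the position is actually polymorphic
                assignment[0], assignment[-1] = 0, n_res - 1
            for a, idx in zip(names, assignment):
                gene_map[a][pos] = residues[int(idx)]
        entries[gene] = gene_map
    return AlleleAAMap(entries)


def build_haplotype_pool(config: PoolConfig, seed: int) -> HaplotypePool:
    """Build the haplotype pool: block-LD SNPs and per-gene classical alleles."""
    cfg = config
    if cfg.n_haplotypes < 2:
        raise ConfigError("need at least 2 haplotypes")
    for gene, freqs in cfg.hla_genes.items():
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(
                f"allele frequencies for gene {gene} sum to {total}, expected 1"
            )
    if not 0.0 <= cfg.sharing_rate <= 1.0:
        raise ConfigError("sharing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_snps = cfg.n_blocks * cfg.block_size
    ancestry = (
        rng.integers(0, cfg.n_subpops, size=cfg.n_haplotypes)
        if cfg.n_subpops > 1
        else np.zeros(cfg.n_haplotypes, dtype=int)
    )
    snp = np.empty((cfg.n_haplotypes, n_snps), dtype=np.int8)
    blocks: list[range] = []
    for b in range(cfg.n_blocks):
        lo = b * cfg.block_size
        blocks.append(range(lo, lo + cfg.block_size))
        site_freq = rng.uniform(0.1, 0.9, size=cfg.block_size)
        templates = (rng.random((cfg.n_templates, cfg.block_size)) < site_freq).astype(
            np.int8
        )
        # subpop-specific template weights induce ancestry-frequency shifts
        base = rng.dirichlet(np.ones(cfg.n_templates))
        weights = np.tile(base, (max(cfg.n_subpops, 1), 1))
        if cfg.n_subpops > 1:
            for s in range(cfg.n_subpops):
                tilt = rng.dirichlet(np.ones(cfg.n_templates))
                weights[s] = (1 - cfg.subpop_divergence) * base + cfg.subpop_divergence * tilt
        choice = np.empty(cfg.n_haplotypes, dtype=int)
        for s in range(max(cfg.n_subpops, 1)):
            mask = ancestry == s
            choice[mask] = rng.choice(cfg.n_templates, size=mask.sum(), p=weights[s])
        copied = templates[choice]
        resample = rng.random((cfg.n_haplotypes, cfg.block_size)) >= cfg.sharing_rate
        fresh = (rng.random((cfg.n_haplotypes, cfg.block_size)) < site_freq).astype(np.int8)
        snp[:, lo: lo + cfg.block_size] = np.where(resample, fresh, copied)
    positions = cfg.start_pos + cfg.spacing * np.arange(n_snps)
    hla_alleles: dict[str, np.ndarray] = {}
    gene_positions: dict[str, int] = {}
    for g, (gene, freqs) in enumerate(sorted(cfg.hla_genes.items())):
        names = sorted(freqs)
        p = np.array([freqs[a] for a in names])
        hla_alleles[gene] = np.array(names, dtype=object)[
            rng.choice(len(names), size=cfg.n_haplotypes, p=p / p.sum())
        ]
        gene_positions[gene] = int(positions[-1] + (g + 1) * 10 * cfg.spacing)
    aa_map = generate_allele_aa_map(cfg.hla_genes, cfg.aa_positions_per_gene, seed + 101)
    return HaplotypePool(
        snp_alleles=snp,
        hla_alleles=hla_alleles,
        block_structure=blocks,
        positions=positions,
        gene_positions=gene_positions,
        allele_aa_map=aa_map,
        config=cfg,
        ancestry=ancestry,
    )


def simulate_genotypes(
    pool: HaplotypePool,
    n_individuals: int,
    seed: int,
    dosage_noise_sd: float = 0.0,
) -> tuple[GenotypeMatrix, GenotypeMatrix, np.ndarray]:
    """Draw diploid individuals from the pool.

    Each individual is two haplotypes drawn uniformly with replacement (from
    their own subpopulation when the pool has more than one).  Returns the
    SNP dosage matrix, the classical-allele dosage matrix (per gene, allele
    dosages sum to exactly 2 before noise), and the per-individual ancestry
    label.  ``dosage_noise_sd`` adds N(0, sd^2) truncated to [0, 2] to every
    dosage, emulating imputation.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    rng = np.random.default_rng(seed)
    n_sub = max(pool.config.n_subpops, 1)
    ind_ancestry = (
        rng.integers(0, n_sub, size=n_individuals)
        if n_sub > 1
        else np.zeros(n_individuals, dtype=int)
    )
    hap_a = np.empty(n_individuals, dtype=int)
    hap_b = np.empty(n_individuals, dtype=int)
    for s in range(n_sub):
        mask = ind_ancestry == s
        idx = np.flatnonzero(pool.ancestry == s) if n_sub > 1 else np.arange(pool.n_haplotypes)
        hap_a[mask] = rng.choice(idx, size=mask.sum(), replace=True)
        hap_b[mask] = rng.choice(idx, size=mask.sum(), replace=True)
    snp_dos = (pool.snp_alleles[hap_a] + pool.snp_alleles[hap_b]).astype(float)
    sample_ids = [f"ind{i:05d}" for i in range(n_individuals)]
    snp_variants = [
        VariantRecord(
            id=vid,
            kind=VariantKind.SNP,
            chrom=pool.config.chrom,
            pos=int(pool.positions[j]),
            ref="A",
            alt="G",
        )
        for j, vid in enumerate(pool.snp_ids())
    ]
    allele_cols: list[np.ndarray] = []
    allele_variants: list[VariantRecord] = []
    for gene in sorted(pool.hla_alleles):
        labels = pool.hla_alleles[gene]
        for allele in sorted(set(labels)):
            dos = (labels[hap_a] == allele).astype(float) + (
                labels[hap_b] == allele
            ).astype(float)
            allele_cols.append(dos)
            allele_variants.append(
                VariantRecord(
                    id=f"{gene}*{allele}",
                    kind=VariantKind.HLA_ALLELE,
                    chrom=pool.config.chrom,
                    pos=pool.gene_positions[gene],
                    ref=".",
                    alt=allele,
                    gene=gene,
                )
            )
    allele_dos = (
        np.column_stack(allele_cols) if allele_cols else np.empty((n_individuals, 0))
    )
    if dosage_noise_sd > 0:
        snp_dos = np.clip(
            snp_dos + rng.normal(0.0, dosage_noise_sd, snp_dos.shape), 0.0, 2.0
        )
        allele_dos = np.clip(
            allele_dos + rng.normal(0.0, dosage_noise_sd, allele_dos.shape), 0.0, 2.0
        )
    snp_G = GenotypeMatrix(sample_ids, snp_variants, snp_dos).with_frequencies()
    allele_G = GenotypeMatrix(sample_ids, allele_variants, allele_dos).with_frequencies()
    return snp_G, allele_G, ind_ancestry


def _covariate_block(
    n: int, rng: np.random.Generator, ancestry: np.ndarray | None, n_pcs: int
) -> dict[str, np.ndarray]:
    """Sex plus PCs; PC1 loads on the latent ancestry label when present."""
    sex = rng.integers(0, 2, size=n).astype(float)
    covs = {"sex": sex}
    anc = (
        np.zeros(n) if ancestry is None else np.asarray(ancestry, dtype=float)
    )
    anc_c = anc - anc.mean() if anc.std() > 0 else anc
    for k in range(n_pcs):
        loading = 1.5 if k == 0 else 0.0
        covs[f"PC{k + 1}"] = loading * anc_c + rng.normal(0.0, 1.0, size=n)
    return covs


def _solve_intercept(eta: np.ndarray, target: float, tol: float = 1e-4) -> float:
    """Bisection for b0 so that mean(expit(b0 + eta)) == target."""
    from scipy.special import expit

    if not 0.0 < target < 1.0:
        raise ValueError(f"prevalence target {target} must lie in (0, 1)")
    lo, hi = -40.0, 40.0
    f = lambda b0: float(np.mean(expit(b0 + eta))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError("prevalence target unattainable for given effects")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_binary_phenotype(
    G: GenotypeMatrix,
    truth: SimulationTruth,
    covariate_effects: Mapping[str, float] | None = None,
    seed: int = 0,
    n_pcs: int = 4,
    ancestry: np.ndarray | None = None,
    phenotype_name: str = "case",
) -> PhenotypeTable:
    """Case/control labels from a logistic model over the causal dosages.

    The intercept is solved by bisection so the population prevalence matches
    ``truth.prevalence``; sex and ``n_pcs`` ancestry PCs are generated and
    stored as covariates (with optional nonzero effects on the trait).
    """
    if truth.trait_type != "binary":
        raise ConfigError("truth.trait_type must be 'binary'")
    if truth.prevalence is None:
        raise ConfigError("binary truth requires a prevalence target")
    rng = np.random.default_rng(seed)
    n = G.n_samples
    covs = _covariate_block(n, rng, ancestry, n_pcs)
    eta = np.zeros(n)
    for vid, beta in zip(truth.causal_ids, truth.effect_sizes):
        eta += beta * np.nan_to_num(G.column(vid))
    for name, gamma in (covariate_effects or {}).items():
        eta += gamma * covs[name]
    b0 = _solve_intercept(eta, truth.prevalence)
    from scipy.special import expit

    y = (rng.random(n) < expit(b0 + eta)).astype(float)
    return PhenotypeTable(
        sample_ids=list(G.sample_ids),
        binary={phenotype_name: y},
        covariates=covs,
    )


def simulate_expression(
    G: GenotypeMatrix,
    gene_model: GeneModel,
    truth: SimulationTruth,
    heritable_fraction: float = 0.1,
    seed: int = 0,
    n_pcs: int = 4,
    ancestry: np.ndarray | None = None,
) -> PhenotypeTable:
    """Quantitative cis-regulated expression trait.

    The genetic component is the causal-dosage linear predictor; residual
    noise variance is set so the causal variants explain
    ``heritable_fraction`` of the trait variance.  With zero causal effects
    the trait is pure standard-normal noise.
    """
    if truth.trait_type != "quantitative":
        raise ConfigError("truth.trait_type must be 'quantitative'")
    rng = np.random.default_rng(seed)
    n = G.n_samples
    genetic = np.zeros(n)
    for vid, beta in zip(truth.causal_ids, truth.effect_sizes):
        genetic += beta * np.nan_to_num(G.column(vid))
    var_g = float(np.var(genetic))
    if var_g > 0:
        if not 0.0 < heritable_fraction < 1.0:
            raise ValueError("heritable_fraction must be in (0, 1) with causal effects")
        sigma2 = var_g * (1.0 - heritable_fraction) / heritable_fraction
    else:
        sigma2 = 1.0
    y = genetic + rng.normal(0.0, np.sqrt(sigma2), size=n)
    covs = _covariate_block(n, rng, ancestry, n_pcs)
    return PhenotypeTable(
        sample_ids=list(G.sample_ids),
        quantitative={gene_model.gene_id: y},
        covariates=covs,
    )


def simulate_kinship(
    n: int, family_size: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Block-diagonal expected kinship: full-sib families of ``family_size``.

    Diagonal 1, within-family off-diagonal 0.5, unrelateds 0.  Returns the
    matrix and the family assignment vector.  The layout is deterministic;
    ``seed`` is accepted for interface uniformity.
    """
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    family = np.arange(n) // family_size
    K = np.eye(n)
    if family_size > 1:
        same = family[:, None] == family[None, :]
        K = np.where(same, 0.5, 0.0)
        np.fill_diagonal(K, 1.0)
    return K, family


def truth_to_dict(truth: SimulationTruth) -> dict:
    return dataclasses.asdict(truth)
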