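"""Amino-acid encoding of classical HLA alleles and genotype QC.

Classical two-field alleles determine the protein sequence, so allele
dosages linearly imply amino-acid dosages: the dosage of residue R at
protein position k of gene g is the sum of the dosages of the g alleles
that carry R at k.  Every residue at every polymorphic position becomes its
own biallelic indicator column (``AA_<GENE>_<pos>_<RESIDUE>``), including
both residues of a strictly biallelic position.

QC follows common imputation-era filters: SNPs are retained when
(call rate > 0.95 OR imputation info score > 0.80) AND exact
Hardy-Weinberg p > 1e-10 AND MAF > 0.001; classical alleles and amino-acid
indicators are filtered on allele frequency alone (>= 1% by default,
optionally within every sample group).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import (
    AlleleAAMap,
    GenotypeMatrix,
    IntegrityError,
    ValidationError,
    VariantKind,
    VariantRecord,
    alt_frequencies,
)


class LookupError_(KeyError):
    """An allele column has no entry in the allele->AA dictionary."""


@dataclass(frozen=True)
class QCThresholds:
    min_call_rate: float = 0.95
    min_info: float = 0.80
    min_hwe_p: float = 1e-10
    min_maf: float = 0.001
    min_hla_freq: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_info", "min_hwe_p", "min_maf", "min_hla_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCVariantReport:
    variant_id: str
    kind: str
    call_rate: float
    info: float
    hwe_p: float
    maf: float
    frequency: float
    pass_call_rate: bool
    pass_info: bool
    pass_hwe: bool
    pass_maf: bool
    pass_hla_freq: bool
    retained: bool


@dataclass
class QCReport:
    variants: list[QCVariantReport]
    counts: dict[str, int] = field(default_factory=dict)

    def retained_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants if v.retained]


# ---------------------------------------------------------------------------
# Allele -> amino-acid translation
# ---------------------------------------------------------------------------

def translate_alleles_to_aa(
    allele_G: GenotypeMatrix,
    aa_map: AlleleAAMap,
    ploidy_tol: float | None = 1e-6,
) -> GenotypeMatrix:
    """Translate classical-allele dosages into amino-acid indicator dosages.

    For each (gene, residue position, residue) observed among the alleles
    present in ``allele_G``, emits one AA_POLY column whose per-individual
    dosage is the sum of the dosages of alleles carrying that residue there.
    By construction the residue dosages at a position sum to the total
    dosage of the alleles that define the position (translation is linear in
    allele dosages).

    ``ploidy_tol``: if not None, a per-position dosage sum exceeding
    2 + ploidy_tol raises :class:`IntegrityError` (pass ``None`` for noisy
    imputed dosages, whose per-gene sums need not be exactly 2).
    """
    by_gene: dict[str, list[int]] = {}
    for j, v in enumerate(allele_G.variants):
        if v.kind != VariantKind.HLA_ALLELE:
            raise ValidationError(f"variant {v.id!r} is not an HLA allele column")
        allele = v.id.split("*", 1)[1]
        if allele not in aa_map.entries.get(v.gene or "", {}):
            raise LookupError_(
                f"allele {v.id!r} absent from the allele->amino-acid dictionary"
            )
        by_gene.setdefault(v.gene, []).append(j)

    cols: list[np.ndarray] = []
    variants: list[VariantRecord] = []
    for gene in sorted(by_gene):
        col_idx = by_gene[gene]
        alleles = [allele_G.variants[j].id.split("*", 1)[1] for j in col_idx]
        gene_pos = min(allele_G.variants[j].pos for j in col_idx)
        positions = sorted(
            {
                p
                for a in alleles
                for p in aa_map.entries[gene][a]
            }
        )
        for pos in positions:
            residues = sorted(
                {
                    aa_map.residue(gene, a, pos)
                    for a in alleles
                    if aa_map.residue(gene, a, pos) is not None
                }
            )
            pos_total = np.zeros(allele_G.n_samples)
            for res in residues:
                dos = np.zeros(allele_G.n_samples)
                for a, j in zip(alleles, col_idx):
                    if aa_map.residue(gene, a, pos) == res:
                        dos = dos + np.nan_to_num(allele_G.dosages[:, j])
                pos_total += dos
                cols.append(dos)
                variants.append(
                    VariantRecord(
                        id=f"AA_{gene}_{pos}_{res.upper()}",
                        kind=VariantKind.AA_POLY,
                        chrom=allele_G.variants[col_idx[0]].chrom,
                        pos=gene_pos,
                        ref=".",
                        alt=res,
                        gene=gene,
                        residue_pos=pos,
                        residue=res,
                    )
                )
            if ploidy_tol is not None and np.any(pos_total > 2.0 + ploidy_tol):
                i = int(np.argmax(pos_total))
                raise IntegrityError(
                    f"residue dosages at {gene} position {pos} sum to "
                    f"{pos_total[i]:.6f} > 2 for sample {allele_G.sample_ids[i]!r}"
                )
    dosages = (
        np.column_stack(cols) if cols else np.empty((allele_G.n_samples, 0))
    )
    if ploidy_tol is None:
        # imputation-noise mode: residue sums may drift past ploidy; clip
        # like any imputed dosage
        dosages = np.clip(dosages, 0.0, 2.0)
    else:
        # absorb accumulation noise at the boundary without hiding real excess
        near_two = (dosages > 2.0) & (dosages <= 2.0 + 1e-9)
        dosages[near_two] = 2.0
    return GenotypeMatrix(allele_G.sample_ids, variants, dosages).with_frequencies()


# ---------------------------------------------------------------------------
# Per-variant QC statistics
# ---------------------------------------------------------------------------

def hwe_test(dosages: np.ndarray) -> float:
    """Exact Hardy-Weinberg test p-value on hard-called genotypes.

    Dosages are rounded to the nearest integer genotype before the exact
    (mid-less) test of Wigginton, Cutler & Abecasis: the p-value is the
    total probability, under the hypergeometric distribution of heterozygote
    counts conditional on the allele counts, of all genotype configurations
    no more probable than the observed one.  Monomorphic columns return 1.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all dosages missing; HWE undefined")
    g = np.clip(np.rint(d), 0, 2).astype(int)
    n_aa = int(np.sum(g == 0))
    n_ab = int(np.sum(g == 1))
    n_bb = int(np.sum(g == 2))
    return hwe_exact_p(n_ab, n_aa, n_bb)


def hwe_exact_p(obs_hets: int, obs_hom1: int, obs_hom2: int) -> float:
    """Exact HWE p-value from genotype counts (order of homozygotes immaterial)."""
    obs_homr = min(obs_hom1, obs_hom2)
    obs_homc = max(obs_hom1, obs_hom2)
    rare = 2 * obs_homr + obs_hets
    n = obs_hets + obs_homr + obs_homc
    if n == 0:
        raise ValueError("no genotypes")
    if rare == 0 or rare == 2 * n:
        return 1.0
    # recurrence over heterozygote counts of matching parity
    het_probs = np.zeros(rare + 1)
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    het_probs[mid] = 1.0
    total = 1.0
    curr_hets, curr_homr, curr_homc = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while curr_hets > 1:
        het_probs[curr_hets - 2] = (
            het_probs[curr_hets]
            * curr_hets
            * (curr_hets - 1.0)
            / (4.0 * (curr_homr + 1.0) * (curr_homc + 1.0))
        )
        total += het_probs[curr_hets - 2]
        curr_hets -= 2
        curr_homr += 1
        curr_homc += 1
    curr_hets, curr_homr, curr_homc = mid, (rare - mid) // 2, n - mid - (rare - mid) // 2
    while curr_hets <= rare - 2:
        het_probs[curr_hets + 2] = (
            het_probs[curr_hets]
            * 4.0
            * curr_homr
            * curr_homc
            / ((curr_hets + 2.0) * (curr_hets + 1.0))
        )
        total += het_probs[curr_hets + 2]
        curr_hets += 2
        curr_homr -= 1
        curr_homc -= 1
    het_probs /= total
    p = float(np.sum(het_probs[het_probs <= het_probs[obs_hets] * (1.0 + 1e-12)]))
    return min(p, 1.0)


def info_score(dosages: np.ndarray) -> float:
    """MaCH/minimac-style imputation quality r-hat^2.

    var(dosage) / (2 p (1-p)) with p the dosage-based allele frequency,
    clipped to [0, 1]; monomorphic columns are defined as 1 (a perfectly
    confident constant imputation).
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("all dosages missing; info score undefined")
    p = float(np.mean(d)) / 2.0
    denom = 2.0 * p * (1.0 - p)
    if denom <= 0.0:
        return 1.0
    return float(np.clip(np.var(d) / denom, 0.0, 1.0))


def call_rate(dosages: np.ndarray) -> float:
    d = np.asarray(dosages, dtype=float)
    return float(np.mean(~np.isnan(d)))


# ---------------------------------------------------------------------------
# QC filter
# ---------------------------------------------------------------------------

def qc_filter(
    G: GenotypeMatrix,
    thresholds: QCThresholds = QCThresholds(),
    sample_groups: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply per-variant QC; returns the filtered matrix and a full report.

    SNPs: retained iff (call_rate > min_call_rate OR info > min_info) AND
    hwe_p > min_hwe_p AND maf > min_maf.  The call-rate/info clause is a
    disjunction: either a well-genotyped or a well-imputed variant passes.
    HLA alleles and amino-acid indicators: retained iff allele frequency
    >= min_hla_freq — within every group of ``sample_groups`` when given
    (the per-ancestry variant of the frequency filter).
    """
    if G.n_variants == 0:
        raise ValueError("empty genotype matrix")
    groups = None
    if sample_groups is not None:
        sample_groups = np.asarray(sample_groups)
        if sample_groups.shape != (G.n_samples,):
            raise ValueError("sample_groups length must match samples")
        groups = [sample_groups == g for g in np.unique(sample_groups)]
    reports: list[QCVariantReport] = []
    keep: list[int] = []
    freqs = alt_frequencies(G.dosages)
    for j, v in enumerate(G.variants):
        col = G.dosages[:, j]
        cr = call_rate(col)
        info = info_score(col) if cr > 0 else 0.0
        freq = float(freqs[j]) if np.isfinite(freqs[j]) else 0.0
        maf = min(freq, 1.0 - freq)
        hwe_p = hwe_test(col) if cr > 0 else 0.0
        if v.kind == VariantKind.SNP:
            p_cr = cr > thresholds.min_call_rate
            p_info = info > thresholds.min_info
            p_hwe = hwe_p > thresholds.min_hwe_p
            p_maf = maf > thresholds.min_maf
            p_freq = True
            retained = (p_cr or p_info) and p_hwe and p_maf
        else:
            if groups is None:
                p_freq = freq >= thresholds.min_hla_freq
            else:
                p_freq = all(
                    float(alt_frequencies(col[g][:, None])[0]) >= thresholds.min_hla_freq
                    for g in groups
                )
            p_cr = p_info = p_hwe = p_maf = True
            retained = p_freq
        reports.append(
            QCVariantReport(
                variant_id=v.id,
                kind=v.kind.value,
                call_rate=cr,
                info=info,
                hwe_p=hwe_p,
                maf=maf,
                frequency=freq,
                pass_call_rate=p_cr,
                pass_info=p_info,
                pass_hwe=p_hwe,
                pass_maf=p_maf,
                pass_hla_freq=p_freq,
                retained=retained,
            )
        )
        if retained:
            keep.append(j)
    counts = {
        "n_input": G.n_variants,
        "n_retained": len(keep),
        "n_removed": G.n_variants - len(keep),
        "n_fail_call_rate_and_info": sum(
            1 for r in reports if not (r.pass_call_rate or r.pass_info)
        ),
        "n_fail_hwe": sum(1 for r in reports if not r.pass_hwe),
        "n_fail_maf": sum(1 for r in reports if not r.pass_maf),
        "n_fail_hla_freq": sum(1 for r in reports if not r.pass_hla_freq),
    }
    filtered = GenotypeMatrix(
        G.sample_ids,
        [G.variants[j] for j in keep],
        G.dosages[:, keep],
    )
    return filtered, QCReport(variants=reports, counts=counts)


def assemble_combined_matrix(
    snps: GenotypeMatrix,
    alleles: GenotypeMatrix,
    aas: GenotypeMatrix,
) -> GenotypeMatrix:
    """Column-concatenate the three variant classes into one genotype matrix.

    Inputs must share identical sample ids in identical order; duplicate
    variant ids across inputs are rejected.
    """
    parts = [snps, alleles, aas]
    ref = parts[0].sample_ids
    for part in parts[1:]:
        if part.sample_ids != ref:
            bad = sorted(
                set(part.sample_ids).symmetric_difference(ref)
            ) or ["<order differs>"]
            raise ValidationError(
                f"sample ids mismatched or reordered across inputs: {bad[:5]}"
            )
    variants = [v for p in parts for v in p.variants]
    dosages = np.hstack([p.dosages for p in parts])
    return GenotypeMatrix(ref, variants, dosages)
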