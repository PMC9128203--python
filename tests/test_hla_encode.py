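"""Allele -> amino-acid translation, HWE/info statistics, QC filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hlafine as hf
from hlafine.hla_encode import (
    LookupError_,
    hwe_exact_p,
    hwe_test,
    info_score,
    qc_filter,
    translate_alleles_to_aa,
)
from hlafine.io_formats import (
    GenotypeMatrix,
    IntegrityError,
    ValidationError,
    VariantKind,
    VariantRecord,
)


def _allele_matrix(sample_ids, gene_alleles, dosages):
    variants = [
        VariantRecord(
            id=f"{g}*{a}", kind=VariantKind.HLA_ALLELE, chrom="6", pos=100 + i,
            alt=a, gene=g,
        )
        for i, (g, a) in enumerate(gene_alleles)
    ]
    return GenotypeMatrix(sample_ids, variants, np.asarray(dosages, float))


class TestTranslation:
    def test_heterozygote_gets_both_residues(self, tiny_aa_map):
        # C*07:02 carries Ala11, C*01:02 carries Ser11
        G = _allele_matrix(["s1"], [("C", "07:02"), ("C", "01:02")], [[1.0, 1.0]])
        aa = translate_alleles_to_aa(G, tiny_aa_map)
        assert aa.column("AA_C_11_ALA")[0] == 1.0
        assert aa.column("AA_C_11_SER")[0] == 1.0
        # position 45 is monomorphic Gly: one column carrying total dosage
        assert aa.column("AA_C_45_GLY")[0] == 2.0

    def test_three_residues_make_three_indicator_columns(self):
        m = hf.AlleleAAMap(
            {"B": {"07:02": {9: "Tyr"}, "08:01": {9: "Asp"}, "44:02": {9: "His"}}}
        )
        G = _allele_matrix(
            ["s1", "s2"],
            [("B", "07:02"), ("B", "08:01"), ("B", "44:02")],
            [[2, 0, 0], [0, 1, 1]],
        )
        aa = translate_alleles_to_aa(G, m)
        names = {v.id for v in aa.variants}
        assert names == {"AA_B_9_TYR", "AA_B_9_ASP", "AA_B_9_HIS"}
        assert aa.column("AA_B_9_TYR").tolist() == [2.0, 0.0]
        assert aa.column("AA_B_9_ASP").tolist() == [0.0, 1.0]

    def test_residues_carried_by_one_allele_group_are_perfectly_correlated(self):
        # five positions where the *03 allele alone carries the minor residue
        positions = {p: None for p in (11, 13, 26, 47, 56)}
        m = hf.AlleleAAMap(
            {
                "DQA1": {
                    "03:01": {p: "Val" for p in positions},
                    "01:02": {p: "Leu" for p in positions},
                }
            }
        )
        rng = np.random.default_rng(0)
        d03 = rng.integers(0, 3, size=200).astype(float)
        G = _allele_matrix(
            [f"s{i}" for i in range(200)],
            [("DQA1", "03:01"), ("DQA1", "01:02")],
            np.column_stack([d03, 2 - d03]),
        )
        aa = translate_alleles_to_aa(G, m)
        val_cols = [j for j, v in enumerate(aa.variants) if v.residue == "Val"]
        assert len(val_cols) == 5
        corr = np.corrcoef(aa.dosages[:, val_cols].T)
        assert np.allclose(corr, 1.0)

    def test_conservation_per_position(self, small_cohort, small_pool):
        _, allele_G, _ = small_cohort
        aa = translate_alleles_to_aa(allele_G, small_pool.allele_aa_map)
        for gene in ("C", "DQA1"):
            total = allele_G.dosages[
                :, [j for j, v in enumerate(allele_G.variants) if v.gene == gene]
            ].sum(axis=1)
            for pos in small_pool.allele_aa_map.positions(gene):
                cols = [
                    j
                    for j, v in enumerate(aa.variants)
                    if v.gene == gene and v.residue_pos == pos
                ]
                assert np.allclose(aa.dosages[:, cols].sum(axis=1), total)

    def test_translation_linear_in_allele_dosages(self, tiny_aa_map):
        ga = [("C", "07:02"), ("C", "01:02")]
        A = _allele_matrix(["s1", "s2"], ga, [[0.5, 0.0], [0.0, 0.25]])
        B = _allele_matrix(["s1", "s2"], ga, [[0.25, 0.5], [0.5, 0.25]])
        S = _allele_matrix(["s1", "s2"], ga, np.asarray(A.dosages) + np.asarray(B.dosages))
        ta = translate_alleles_to_aa(A, tiny_aa_map, ploidy_tol=None)
        tb = translate_alleles_to_aa(B, tiny_aa_map, ploidy_tol=None)
        ts = translate_alleles_to_aa(S, tiny_aa_map, ploidy_tol=None)
        assert np.allclose(ts.dosages, ta.dosages + tb.dosages)

    def test_unknown_allele_named_in_error(self, tiny_aa_map):
        G = _allele_matrix(["s1"], [("C", "99:99")], [[2.0]])
        with pytest.raises(LookupError_, match="99:99"):
            translate_alleles_to_aa(G, tiny_aa_map)

    def test_ploidy_violation_detected(self, tiny_aa_map):
        G = _allele_matrix(["s1"], [("C", "07:02"), ("C", "01:02")], [[2.0, 1.0]])
        with pytest.raises(IntegrityError):
            translate_alleles_to_aa(G, tiny_aa_map)
        # tolerance disabled for noisy dosages
        aa = translate_alleles_to_aa(G, tiny_aa_map, ploidy_tol=None)
        assert aa.n_variants > 0


class TestHWE:
    def test_all_heterozygotes_strongly_rejected(self):
        assert hwe_test(np.ones(100)) < 1e-10

    def test_conforming_counts_give_p_one(self):
        # 25 / 50 / 25 is the most probable configuration given allele counts
        d = np.repeat([0.0, 1.0, 2.0], [25, 50, 25])
        assert hwe_test(d) == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_returns_one(self):
        assert hwe_test(np.zeros(50)) == 1.0
        assert hwe_test(np.full(50, 2.0)) == 1.0

    def test_matches_enumeration_oracle(self):
        # brute-force: enumerate heterozygote counts of matching parity,
        # probability from the conditional (hypergeometric-type) pmf
        from math import comb

        def oracle(n_ab, n_aa, n_bb):
            n = n_aa + n_ab + n_bb
            na = 2 * n_aa + n_ab

            def pmf(h):
                hom_a = (na - h) // 2
                hom_b = n - h - hom_a
                if hom_a < 0 or hom_b < 0:
                    return 0.0
                # P(h | n, na) ∝ n! / (hom_a! h! hom_b!) * 2^h
                from math import lgamma, exp

                return exp(
                    lgamma(n + 1)
                    - lgamma(hom_a + 1)
                    - lgamma(h + 1)
                    - lgamma(hom_b + 1)
                    + h * np.log(2)
                )

            hs = [h for h in range(0, min(na, 2 * n - na) + 1) if h % 2 == na % 2]
            probs = {h: pmf(h) for h in hs}
            z = sum(probs.values())
            p_obs = probs[n_ab] / z
            return sum(p / z for p in probs.values() if p / z <= p_obs * (1 + 1e-12))

        for counts in [(5, 10, 5), (2, 14, 4), (9, 1, 10), (0, 10, 10)]:
            n_ab, n_aa, n_bb = counts
            assert hwe_exact_p(n_ab, n_aa, n_bb) == pytest.approx(
                oracle(n_ab, n_aa, n_bb), rel=1e-9
            )

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            hwe_test(np.full(5, np.nan))


class TestInfoScore:
    def test_hard_calls_in_hwe_score_near_one(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.5, size=5000).astype(float)
        assert 0.9 <= info_score(d) <= 1.0

    def test_constant_dosage_scores_zero(self):
        assert info_score(np.full(100, 0.8)) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_scores_one(self):
        assert info_score(np.zeros(100)) == 1.0


class TestQCFilter:
    def _snp_matrix(self, cols):
        variants = [
            VariantRecord(id=f"rs{j}", kind=VariantKind.SNP, chrom="6", pos=100 + j,
                          ref="A", alt="G")
            for j in range(cols.shape[1])
        ]
        return GenotypeMatrix(
            [f"s{i}" for i in range(cols.shape[0])], variants, cols
        )

    def test_call_rate_or_info_is_disjunctive(self):
        rng = np.random.default_rng(2)
        n = 1000
        # fully called but shrunken dosages: call rate 1.0, info < 0.8, and the
        # shrinkage is mild enough that rounding recovers the HWE-conforming calls
        hard = rng.binomial(2, 0.5, n).astype(float)
        noisy = 0.6 * hard + 0.4
        G = self._snp_matrix(noisy[:, None])
        filtered, rep = qc_filter(G)
        assert rep.variants[0].pass_call_rate and not rep.variants[0].pass_info
        assert rep.variants[0].retained

    def test_low_maf_snp_removed(self):
        d = np.zeros(2000)
        d[0] = 1.0  # MAF 0.00025
        G = self._snp_matrix(d[:, None])
        filtered, rep = qc_filter(G)
        assert not rep.variants[0].pass_maf and not rep.variants[0].retained

    def test_low_frequency_hla_allele_removed(self):
        d = np.zeros(1000)
        d[:8] = 2.0  # frequency 0.008 < 0.01
        v = VariantRecord(id="C*15:02", kind=VariantKind.HLA_ALLELE, chrom="6",
                          pos=100, alt="15:02", gene="C")
        G = GenotypeMatrix([f"s{i}" for i in range(1000)], [v], d[:, None])
        filtered, rep = qc_filter(G)
        assert filtered.n_variants == 0
        assert not rep.variants[0].pass_hla_freq

    def test_per_group_frequency_filter(self):
        # common overall but absent in group B -> removed under group rule
        d = np.concatenate([np.ones(100), np.zeros(100)])
        v = VariantRecord(id="C*07:02", kind=VariantKind.HLA_ALLELE, chrom="6",
                          pos=100, alt="07:02", gene="C")
        G = GenotypeMatrix([f"s{i}" for i in range(200)], [v], d[:, None])
        groups = ["A"] * 100 + ["B"] * 100
        kept_all, _ = qc_filter(G)
        assert kept_all.n_variants == 1
        kept_grouped, _ = qc_filter(G, sample_groups=groups)
        assert kept_grouped.n_variants == 0

    def test_qc_idempotent(self, small_cohort):
        snp_G, allele_G, _ = small_cohort
        once, _ = qc_filter(snp_G)
        twice, rep = qc_filter(once)
        assert twice.variant_ids == once.variant_ids
        assert rep.counts["n_removed"] == 0

    def test_empty_matrix_rejected(self):
        G = GenotypeMatrix(["s1"], [], np.empty((1, 0)))
        with pytest.raises(ValueError):
            qc_filter(G)


class TestAssemble:
    def test_kinds_preserved_in_order(self, small_cohort, small_pool):
        snp_G, allele_G, _ = small_cohort
        aa = translate_alleles_to_aa(allele_G, small_pool.allele_aa_map)
        combined = hf.assemble_combined_matrix(snp_G, allele_G, aa)
        kinds = [v.kind for v in combined.variants]
        assert kinds[: snp_G.n_variants] == [VariantKind.SNP] * snp_G.n_variants
        assert combined.n_variants == snp_G.n_variants + allele_G.n_variants + aa.n_variants

    def test_sample_mismatch_rejected(self, small_cohort, small_pool):
        snp_G, allele_G, _ = small_cohort
        aa = translate_alleles_to_aa(allele_G, small_pool.allele_aa_map)
        shuffled = GenotypeMatrix(
            list(reversed(allele_G.sample_ids)), allele_G.variants, allele_G.dosages
        )
        with pytest.raises(ValidationError):
            hf.assemble_combined_matrix(snp_G, shuffled, aa)

    def test_empty_middle_input_ok(self, small_cohort):
        snp_G, allele_G, _ = small_cohort
        empty = GenotypeMatrix(snp_G.sample_ids, [], np.empty((snp_G.n_samples, 0)))
        combined = hf.assemble_combined_matrix(snp_G, empty, empty)
        assert combined.n_variants == snp_G.n_variants


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    d1=st.lists(st.floats(0, 1), min_size=3, max_size=3),
    d2=st.lists(st.floats(0, 1), min_size=3, max_size=3),
)
def test_translation_additivity_property(d1, d2, ):
    m = hf.AlleleAAMap({"C": {"07:02": {11: "Ala"}, "01:02": {11: "Ser"}}})
    ga = [("C", "07:02"), ("C", "01:02")]
    A = _allele_matrix(["a", "b", "c"], ga, np.column_stack([d1, d2]) / 2)
    B = _allele_matrix(["a", "b", "c"], ga, np.column_stack([d2, d1]) / 2)
    S = _allele_matrix(["a", "b", "c"], ga,
                       (np.column_stack([d1, d2]) + np.column_stack([d2, d1])) / 2)
    ta = translate_alleles_to_aa(A, m, ploidy_tol=None)
    tb = translate_alleles_to_aa(B, m, ploidy_tol=None)
    ts = translate_alleles_to_aa(S, m, ploidy_tol=None)
    assert np.allclose(ts.dosages, ta.dosages + tb.dosages, atol=1e-12)
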