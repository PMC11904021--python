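import itertools

import numpy as np
import pandas as pd
import pytest

import mrmediate as mm
from mrmediate.instruments import HarmonizedSet, InstrumentSet
from tests.conftest import make_variant


class TestStrengthFormulas:
    def test_variance_explained_symmetric_case(self):
        assert mm.variance_explained(0.5, 1.0) == pytest.approx(0.5)

    def test_zero_beta_explains_nothing(self):
        assert mm.variance_explained(0.3, 0.0) == 0.0

    def test_hand_arithmetic(self):
        assert mm.variance_explained(0.3, 0.1) == pytest.approx(2 * 0.7 * 0.3 * 0.01)

    def test_major_allele_frequency_rejected(self):
        with pytest.raises(ValueError):
            mm.variance_explained(0.7, 0.1)

    def test_unstandardized_beta_capped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            r2 = mm.variance_explained(0.5, 3.0)
        assert r2 < 1.0

    def test_f_statistic_values(self):
        assert mm.f_statistic(0.0, 100) == 0.0
        assert mm.f_statistic(0.5, 4) == pytest.approx(2.0)
        # metabolite-GWAS-scale sample size
        assert mm.f_statistic(0.0042, 8299) == pytest.approx(0.0042 * 8297 / 0.9958, rel=1e-12)
        assert mm.f_statistic(0.0042, 8299) == pytest.approx(34.99, abs=0.01)

    def test_f_statistic_domain_errors(self):
        with pytest.raises(ValueError):
            mm.f_statistic(1.0, 100)
        with pytest.raises(ValueError):
            mm.f_statistic(0.1, 2)


class TestPalindromeRule:
    @pytest.mark.parametrize("ea,oa,eaf,expected", [
        ("A", "T", 0.45, True),     # palindromic, MAF above 0.42
        ("A", "T", 0.56, True),     # MAF = 0.44 via the major side
        ("A", "G", 0.45, False),    # not palindromic
        ("C", "G", 0.10, False),    # palindromic but orientable by frequency
        ("C", "G", 0.42, True),     # boundary is inclusive
        ("G", "C", 0.5, True),
    ])
    def test_rule(self, ea, oa, eaf, expected):
        assert mm.is_ambiguous_palindrome(ea, oa, eaf) is expected


class TestClump:
    def test_stronger_snp_dominates_linked_pair(self):
        a = make_variant("rsA", pos=1000, pval=1e-8)
        b = make_variant("rsB", pos=2000, pval=1e-7)
        ld = mm.LDMatrix(["rsA", "rsB"], np.array([[1, 0.5], [0.5, 1]]))
        kept = mm.clump([a, b], ld)
        assert [v.snp_id for v in kept] == ["rsA"]

    def test_unlinked_pair_both_kept(self):
        a = make_variant("rsA", pos=1000, pval=1e-8)
        b = make_variant("rsB", pos=2000, pval=1e-7)
        kept = mm.clump([a, b], mm.LDMatrix.identity(["rsA", "rsB"]))
        assert len(kept) == 2

    def test_cross_chromosome_never_clumped(self):
        a = make_variant("rsA", chrom="1", pos=1000, pval=1e-8)
        b = make_variant("rsB", chrom="2", pos=1000, pval=1e-7)
        ld = mm.LDMatrix(["rsA", "rsB"], np.array([[1, 0.9], [0.9, 1]]))
        assert len(mm.clump([a, b], ld)) == 2

    def test_window_limits_clumping(self):
        a = make_variant("rsA", pos=1_000, pval=1e-8)
        b = make_variant("rsB", pos=1_000 + 10_000_001, pval=1e-7)
        ld = mm.LDMatrix(["rsA", "rsB"], np.array([[1, 0.9], [0.9, 1]]))
        assert len(mm.clump([a, b], ld, window_kb=10_000)) == 2
        assert len(mm.clump([a, b], ld, window_kb=20_000)) == 1

    def test_block_matches_exhaustive_oracle(self):
        """5 mutually linked SNPs plus one independent: the greedy result must
        equal the p-value-greedy maximal valid subset found by brute force."""
        block = [make_variant(f"rsB{i}", pos=1000 + i, pval=10.0 ** -(8 - i)) for i in range(5)]
        indep = make_variant("rsI", pos=5_000_000, pval=1e-6)
        ids = [v.snp_id for v in block + [indep]]
        r2 = np.eye(6)
        r2[:5, :5] = 0.9
        np.fill_diagonal(r2, 1.0)
        ld = mm.LDMatrix(ids, r2)
        kept = {v.snp_id for v in mm.clump(block + [indep], ld)}
        assert len(kept) == 2

        def valid(subset):
            return all(ld.r2_between(a, b) <= 0.001
                       for a, b in itertools.combinations(subset, 2))

        # brute-force: walk candidates by ascending p, keep if still valid
        oracle = []
        for v in sorted(block + [indep], key=lambda v: (v.pval, v.snp_id)):
            if valid([*oracle, v.snp_id]):
                oracle.append(v.snp_id)
        assert kept == set(oracle)

    def test_output_invariant_to_input_order(self):
        variants = [make_variant(f"rs{i}", pos=1000 + 100 * i, pval=p)
                    for i, p in enumerate([1e-8, 1e-7, 1e-9, 1e-6, 1e-7])]
        r2 = np.full((5, 5), 0.4)
        np.fill_diagonal(r2, 1.0)
        ld = mm.LDMatrix([v.snp_id for v in variants], r2)
        baseline = [v.snp_id for v in mm.clump(variants, ld)]
        for perm in itertools.permutations(variants):
            assert [v.snp_id for v in mm.clump(list(perm), ld)] == baseline

    def test_empty_input_empty_output(self):
        assert mm.clump([], mm.LDMatrix.identity([])) == []


class TestSelectInstruments:
    def _dataset(self, variants):
        return mm.SummaryDataset.from_variants("exp", "continuous", variants)

    def test_nothing_significant_all_logged_pvalue(self):
        ds = self._dataset([make_variant(f"rs{i}", pos=1000 * i + 1, pval=1e-3) for i in range(4)])
        inst = mm.select_instruments(ds, mm.LDMatrix.identity(ds.table.SNP.tolist()))
        assert len(inst) == 0
        assert {r for _, r in inst.selection_log} == {"pvalue"}

    def test_selected_set_satisfies_invariants(self, clean_panel):
        inst = mm.select_instruments(clean_panel.exposure, clean_panel.ld)
        assert len(inst) > 0
        assert (inst.table["F"] > 10).all()
        assert (inst.table["P"] < 5e-6).all()
        for a, b in itertools.combinations(inst.snp_ids, 2):
            assert clean_panel.ld.r2_between(a, b) <= 0.001

    def test_tighter_threshold_gives_subset(self, clean_panel):
        lenient = mm.select_instruments(clean_panel.exposure, clean_panel.ld, p_threshold=5e-6)
        strict = mm.select_instruments(clean_panel.exposure, clean_panel.ld, p_threshold=5e-8)
        assert set(strict.snp_ids) <= set(lenient.snp_ids)

    def test_ambiguous_palindromes_excluded(self):
        ds = self._dataset([
            make_variant("rs_pal", ea="A", oa="T", eaf=0.45, pval=1e-9),
            make_variant("rs_ok", pos=5_000_000, pval=1e-9),
        ])
        inst = mm.select_instruments(ds, mm.LDMatrix.identity(ds.table.SNP.tolist()))
        assert inst.snp_ids == ["rs_ok"]
        assert ("rs_pal", "palindrome") in inst.selection_log

    def test_weak_instruments_excluded(self):
        # tiny beta at modest n: F far below 10 despite strong p
        weak = make_variant("rs_weak", beta=0.01, se=0.001, n=1000, pval=1e-10)
        strong = make_variant("rs_strong", pos=5_000_000, beta=0.3, se=0.01, n=50_000, pval=1e-10)
        ds = self._dataset([weak, strong])
        inst = mm.select_instruments(ds, mm.LDMatrix.identity(ds.table.SNP.tolist()))
        assert inst.snp_ids == ["rs_strong"]
        assert ("rs_weak", "weak") in inst.selection_log

    def test_permissive_settings_return_input_unchanged(self):
        variants = [make_variant(f"rs{i}", pos=1000 * i + 1, pval=0.5) for i in range(5)]
        ds = self._dataset(variants)
        inst = mm.select_instruments(ds, mm.LDMatrix.identity(ds.table.SNP.tolist()),
                                     p_threshold=1.0, clump_r2=1.0, f_min=None)
        assert set(inst.snp_ids) == {v.snp_id for v in variants}

    def test_binary_exposure_warns_about_scale(self):
        ds = mm.SummaryDataset.from_variants(
            "disease", "binary", [make_variant("rs1", beta=0.2, n=100_000, pval=1e-10)])
        with pytest.warns(RuntimeWarning, match="log-odds"):
            mm.select_instruments(ds, mm.LDMatrix.identity(["rs1"]), p_threshold=5e-8)


def _instrument_set(variants):
    rows = [(v.snp_id, v.chrom, v.pos, v.effect_allele, v.other_allele,
             v.eaf, v.beta, v.se, v.pval, v.n, 0.01, 50.0) for v in variants]
    table = pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "EA", "OA", "EAF",
                                        "BETA", "SE", "P", "N", "R2", "F"])
    return InstrumentSet("exp", table, [], 5e-6)


class TestHarmonize:
    def test_matching_alleles_copied_verbatim(self):
        inst = _instrument_set([make_variant("rs1", ea="A", oa="G", beta=0.1)])
        outcome = mm.SummaryDataset.from_variants("out", "binary",
            [make_variant("rs1", ea="A", oa="G", beta=0.2)])
        harm = mm.harmonize(inst, outcome)
        row = harm.table.iloc[0]
        assert row.beta_out == 0.2 and not row.flipped

    def test_swapped_alleles_flip_sign(self):
        inst = _instrument_set([make_variant("rs1", ea="A", oa="G", eaf=0.3)])
        outcome = mm.SummaryDataset.from_variants("out", "binary",
            [make_variant("rs1", ea="G", oa="A", eaf=0.7, beta=0.2)])
        harm = mm.harmonize(inst, outcome)
        row = harm.table.iloc[0]
        assert row.beta_out == pytest.approx(-0.2)
        assert row.eaf_out == pytest.approx(0.3)
        assert row.flipped

    def test_strand_complement_resolved(self):
        inst = _instrument_set([make_variant("rs1", ea="A", oa="G", eaf=0.3)])
        outcome = mm.SummaryDataset.from_variants("out", "binary",
            [make_variant("rs1", ea="T", oa="C", eaf=0.3, beta=0.2)])
        harm = mm.harmonize(inst, outcome)
        assert harm.table.iloc[0].beta_out == 0.2

    def test_palindrome_oriented_by_frequency(self):
        inst = _instrument_set([make_variant("rs1", ea="A", oa="T", eaf=0.10)])
        outcome = mm.SummaryDataset.from_variants("out", "binary",
            [make_variant("rs1", ea="A", oa="T", eaf=0.88, beta=0.2)])
        harm = mm.harmonize(inst, outcome)
        row = harm.table.iloc[0]
        assert row.beta_out == pytest.approx(-0.2)
        assert row.eaf_out == pytest.approx(0.12)
        assert row.flipped

    def test_palindrome_concordant_frequency_untouched(self):
        inst = _instrument_set([make_variant("rs1", ea="A", oa="T", eaf=0.10)])
        outcome = mm.SummaryDataset.from_variants("out", "binary",
            [make_variant("rs1", ea="A", oa="T", eaf=0.12, beta=0.2)])
        harm = mm.harmonize(inst, outcome)
        assert harm.table.iloc[0].beta_out == 0.2
        assert not harm.table.iloc[0].flipped

    def test_mismatched_alleles_dropped(self):
        inst = _instrument_set([make_variant("rs1", ea="A", oa="G")])
        outcome = mm.SummaryDataset.from_variants("out", "binary",
            [make_variant("rs1", ea="A", oa="C")])
        harm = mm.harmonize(inst, outcome)
        assert harm.n_snp == 0
        assert ("rs1", "allele_mismatch") in harm.dropped

    def test_missing_in_outcome_dropped(self):
        inst = _instrument_set([make_variant("rs1"), make_variant("rs2", pos=5_000_000)])
        outcome = mm.SummaryDataset.from_variants("out", "binary", [make_variant("rs1")])
        harm = mm.harmonize(inst, outcome)
        assert harm.n_snp == 1
        assert ("rs2", "missing_in_outcome") in harm.dropped

    def test_idempotent_on_aligned_pair(self, clean_panel):
        """Re-harmonizing an outcome rebuilt from harmonized rows changes nothing."""
        inst = mm.select_instruments(clean_panel.exposure, clean_panel.ld)
        harm1 = mm.harmonize(inst, clean_panel.outcome)
        inst_tab = inst.table.set_index("SNP")
        aligned = [
            mm.VariantAssociation(r.snp_id, "1", 1, inst_tab.loc[r.snp_id, "EA"],
                                  inst_tab.loc[r.snp_id, "OA"], r.eaf_out,
                                  r.beta_out, r.se_out, 0.5, 100_000)
            for r in harm1.table.itertuples()
        ]
        outcome2 = mm.SummaryDataset.from_variants("outcome", "binary", aligned)
        harm2 = mm.harmonize(inst, outcome2)
        np.testing.assert_allclose(harm2.table.beta_out, harm1.table.beta_out)
        assert not harm2.table.flipped.any()
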