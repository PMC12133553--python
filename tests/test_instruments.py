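import itertools
import random

import numpy as np
import pytest

from mrmediate.instruments import (
    FilterLedger,
    clump,
    f_statistic,
    filter_by_pvalue,
    filter_weak,
    harmonize,
    pairs_to_records,
    remove_blacklisted,
    remove_outcome_associated,
)
from mrmediate.summary_io import FormatError, LDMatrix

from conftest import make_pair, make_record


class TestPvalueFilter:
    def test_strict_less_than(self):
        recs = [make_record("rs1", pval=1e-9), make_record("rs2", pval=1e-7)]
        assert [r.snp_id for r in filter_by_pvalue(recs, 5e-8)] == ["rs1"]

    def test_boundary_below_threshold_kept(self):
        recs = [make_record("rs1", pval=4.9e-8), make_record("rs2", pval=5e-8)]
        assert [r.snp_id for r in filter_by_pvalue(recs, 5e-8)] == ["rs1"]

    def test_simulated_null_count_matches_enumeration(self):
        rng = np.random.default_rng(7)
        pvals = rng.uniform(size=1000)
        recs = [make_record(f"rs{i}", pval=float(p)) for i, p in enumerate(pvals)]
        kept = filter_by_pvalue(recs, 1e-5)
        assert len(kept) == int(np.sum(pvals < 1e-5))  # direct enumeration


class TestClump:
    def test_window_pair_keeps_lower_p(self):
        a = make_record("rs1", pos=1000, pval=1e-10)
        b = make_record("rs2", pos=6000, pval=1e-9)
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert [r.snp_id for r in clump([a, b], ld=ld)] == ["rs1"]

    def test_different_chromosomes_both_kept(self):
        a = make_record("rs1", chrom="1", pos=1000, pval=1e-10)
        b = make_record("rs2", chrom="2", pos=1000, pval=1e-9)
        ld = LDMatrix(["rs1", "rs2"], np.eye(2))
        assert len(clump([a, b], ld=ld)) == 2

    def test_full_ld_window_single_survivor_matches_bruteforce(self):
        # 10 SNPs, pairwise r2 = 1: greedy must keep exactly the min-p SNP.
        # brute force: any accepting order that respects the blocking rule
        # yields a single survivor; the p-ordered greedy picks the smallest.
        rng = np.random.default_rng(1)
        pvals = rng.uniform(1e-12, 1e-8, size=10)
        recs = [
            make_record(f"rs{i}", pos=1000 + i * 100, pval=float(p))
            for i, p in enumerate(pvals)
        ]
        ld = LDMatrix([r.snp_id for r in recs], np.ones((10, 10)))
        survivors = clump(recs, ld=ld)
        assert len(survivors) == 1
        assert survivors[0].snp_id == recs[int(np.argmin(pvals))].snp_id

    def test_distance_only_fallback_blocks_within_window(self):
        a = make_record("rs1", pos=1_000, pval=1e-10)
        b = make_record("rs2", pos=5_000_000, pval=1e-9)
        c = make_record("rs3", pos=20_000_000, pval=1e-9)
        kept = clump([a, b, c], ld=None)
        assert [r.snp_id for r in kept] == ["rs1", "rs3"]

    def test_output_independent_of_input_order(self):
        rng = np.random.default_rng(3)
        recs = [
            make_record(
                f"rs{i}", chrom=str(i % 3 + 1), pos=int(rng.integers(1, 3_000_000)),
                pval=float(rng.uniform(1e-12, 1e-6)),
            )
            for i in range(12)
        ]
        baseline = [r.snp_id for r in clump(recs)]
        for perm_seed in range(5):
            shuffled = recs.copy()
            random.Random(perm_seed).shuffle(shuffled)
            assert [r.snp_id for r in clump(shuffled)] == baseline


class TestFStatistic:
    @pytest.mark.parametrize(
        "beta,se,f,kept",
        [(0.1, 0.02, 25.0, True), (0.02, 0.01, 4.0, False)],
    )
    def test_f_value_and_filter(self, beta, se, f, kept):
        pair = make_pair(beta_exp=beta, se_exp=se)
        assert f_statistic(pair) == pytest.approx(f)
        assert (pair in filter_weak([pair])) is kept

    def test_boundary_f_exactly_ten_kept(self):
        pair = make_pair(beta_exp=0.1, se_exp=0.1 / np.sqrt(10))
        assert f_statistic(pair) == pytest.approx(10.0)
        assert filter_weak([pair]) == [pair]


class TestHarmonize:
    def test_effect_allele_flip_negates_beta(self):
        exp = make_record("rs1", ea="A", oa="G", beta=0.1)
        out = make_record("rs1", ea="G", oa="A", beta=0.05, eaf=0.3, trait_id="out")
        pairs, _ = harmonize([exp], [out])
        assert pairs[0].beta_out == pytest.approx(-0.05)
        assert pairs[0].eaf_out == pytest.approx(0.7)
        assert pairs[0].effect_allele == "A"

    def test_palindromic_removed_unconditionally(self):
        exp = make_record("rs1", ea="A", oa="T")
        out = make_record("rs1", ea="A", oa="T")
        pairs, ledger = harmonize([exp], [out])
        assert pairs == []
        assert ledger.removed("palindromic") == 1

    def test_mismatched_allele_sets_removed_as_ambiguous(self):
        exp = make_record("rs1", ea="A", oa="G")
        out = make_record("rs1", ea="A", oa="C")
        pairs, ledger = harmonize([exp], [out])
        assert pairs == []
        assert ledger.removed("ambiguous") == 1

    def test_strand_complement_resolved(self):
        # T/C on the other strand is A/G: beta should align without flip
        exp = make_record("rs1", ea="A", oa="G", beta=0.1)
        out = make_record("rs1", ea="T", oa="C", beta=0.05)
        pairs, _ = harmonize([exp], [out])
        assert pairs[0].beta_out == pytest.approx(0.05)

    def test_duplicate_snp_id_is_error(self):
        exp = [make_record("rs1"), make_record("rs1")]
        with pytest.raises(FormatError, match="rs1"):
            harmonize(exp, [make_record("rs1")])

    def test_idempotent_on_own_output(self):
        exp = [
            make_record("rs1", ea="A", oa="G", beta=0.1),
            make_record("rs2", ea="T", oa="G", beta=0.2, pos=2000),
        ]
        out = [
            make_record("rs1", ea="G", oa="A", beta=0.05),
            make_record("rs2", ea="T", oa="G", beta=-0.01, pos=2000),
        ]
        pairs, _ = harmonize(exp, out)
        exp2, out2 = pairs_to_records(pairs)
        pairs2, _ = harmonize(exp2, out2)
        assert [(p.snp_id, p.beta_out, p.effect_allele) for p in pairs] == [
            (p.snp_id, p.beta_out, p.effect_allele) for p in pairs2
        ]

    def test_ledger_telescopes(self):
        exp = [
            make_record("rs1"),
            make_record("rs2", ea="A", oa="T"),
            make_record("rs3"),
        ]
        out = [make_record("rs1"), make_record("rs2", ea="A", oa="T")]
        _, ledger = harmonize(exp, out)
        assert ledger.telescopes()


class TestBlacklist:
    def test_substring_match_removes(self):
        pairs = [make_pair("rs1"), make_pair("rs2")]
        bl = {"rs1": ["Body Mass Index"]}
        kept, ledger = remove_blacklisted(pairs, bl, ["body mass"])
        assert [p.snp_id for p in kept] == ["rs2"]
        assert ledger.removed("confounder_blacklist") == 1

    def test_empty_blacklist_is_identity(self):
        pairs = [make_pair("rs1"), make_pair("rs2")]
        kept, _ = remove_blacklisted(pairs, {}, ["body mass"])
        assert kept == pairs

    def test_counts_match_annotation(self):
        pairs = [make_pair(f"rs{i}") for i in range(21)]
        bl = {"rs0": ["smoking status"], "rs5": ["alcohol intake"], "rs9": ["smoking"]}
        kept, ledger = remove_blacklisted(pairs, bl, ["smoking", "alcohol"])
        assert len(kept) == 18
        assert ledger.removed("confounder_blacklist") == 3


class TestOutcomeBonferroni:
    def test_threshold_is_alpha_over_k(self):
        pairs = [make_pair(f"rs{i}", pval_out=0.5) for i in range(9)]
        pairs.append(make_pair("rs9", pval_out=0.004))
        kept, _ = remove_outcome_associated(pairs, alpha=0.05)
        assert "rs9" not in [p.snp_id for p in kept]  # 0.004 < 0.05/10

    def test_above_threshold_kept(self):
        pairs = [make_pair(f"rs{i}", pval_out=0.5) for i in range(9)]
        pairs.append(make_pair("rs9", pval_out=0.006))
        kept, _ = remove_outcome_associated(pairs, alpha=0.05)
        assert len(kept) == 10  # 0.006 >= 0.005

    def test_implanted_outcome_hits_all_removed(self):
        rng = np.random.default_rng(11)
        pairs = [
            make_pair(f"rs{i}", pval_out=float(rng.uniform(0.1, 1.0)))
            for i in range(95)
        ] + [make_pair(f"bad{i}", pval_out=1e-6) for i in range(5)]
        kept, ledger = remove_outcome_associated(pairs, alpha=0.05)
        assert ledger.removed("outcome_bonferroni") == 5
        assert all(not p.snp_id.startswith("bad") for p in kept)


def test_ledger_rejects_non_telescoping_entry():
    ledger = FilterLedger()
    ledger.add("a", 10, 8)
    with pytest.raises(ValueError):
        ledger.add("b", 9, 9)
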