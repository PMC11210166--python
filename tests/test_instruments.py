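import io
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmr.instruments import (
    LDTable,
    NoInstrumentsError,
    clump,
    f_from_pvalue,
    instrument_strength,
    read_annotations,
    screen_confounders,
    select_instruments,
    strength_summary,
)

from .conftest import PRINTED_F, make_record


class TestSelect:
    def test_prostatitis_all_kept(self, prostatitis_records):
        out = select_instruments(prostatitis_records, 5e-6)
        assert out.k == 10
        assert out.provenance[-1].n_removed == 0

    def test_boundary_is_strict(self):
        with pytest.raises(NoInstrumentsError):
            select_instruments([make_record(pvalue=6e-6)], 5e-6)

    def test_threshold_one_is_identity(self, bph_records):
        out = select_instruments(bph_records, 1.0)
        assert list(out.records) == bph_records

    def test_provenance_counts(self, bph_records):
        out = select_instruments(bph_records, 1e-8)
        ev = out.provenance[-1]
        assert ev.n_in == 23 and ev.n_out == out.k
        assert out.k == sum(1 for r in bph_records if r.pvalue < 1e-8)

    def test_bad_threshold(self, bph_records):
        with pytest.raises(ValueError):
            select_instruments(bph_records, 0.0)


def brute_force_clump(records, ld, r2_threshold):
    """Independent restatement of the greedy rule (no windows)."""
    ranked = sorted(records, key=lambda r: (r.pvalue, r.snp_id))
    kept = []
    for cand in ranked:
        if all(ld.r2(cand.snp_id, k.snp_id) < r2_threshold for k in kept):
            kept.append(cand)
    return [r.snp_id for r in kept]


class TestClump:
    def test_two_snp_hand_trace(self):
        a = make_record(snp_id="rsA", pvalue=1e-8)
        b = make_record(snp_id="rsB", pvalue=1e-6)
        ld = LDTable({("rsA", "rsB"): 0.5})
        out = clump([a, b], ld, r2_threshold=0.001)
        assert [r.snp_id for r in out.records] == ["rsA"]
        assert out.provenance[-1].n_removed == 1

    def test_singleton_unchanged(self):
        r = make_record()
        out = clump([r], LDTable())
        assert list(out.records) == [r]

    def test_five_snp_vs_brute_force(self):
        recs = [make_record(snp_id=f"rs{i}", pvalue=p)
                for i, p in enumerate([1e-9, 5e-9, 1e-8, 2e-7, 1e-6])]
        ld = LDTable()
        ld.set("rs0", "rs1", 0.9)
        ld.set("rs0", "rs2", 0.0005)
        ld.set("rs2", "rs3", 0.3)
        ld.set("rs3", "rs4", 0.002)
        out = clump(recs, ld, r2_threshold=0.001)
        assert [r.snp_id for r in out.records] == brute_force_clump(recs, ld, 0.001)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_six_snp_instances_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        recs = [make_record(snp_id=f"rs{i}", pvalue=float(rng.uniform(1e-10, 1e-5)))
                for i in range(6)]
        ld = LDTable()
        for a, b in itertools.combinations(range(6), 2):
            ld.set(f"rs{a}", f"rs{b}", float(rng.uniform(0, 0.01)))
        out = clump(recs, ld, r2_threshold=0.001)
        assert [r.snp_id for r in out.records] == brute_force_clump(recs, ld, 0.001)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        recs = [make_record(snp_id=f"rs{i}", pvalue=float(rng.uniform(1e-9, 1e-5)))
                for i in range(8)]
        ld = LDTable()
        for a, b in itertools.combinations(range(8), 2):
            ld.set(f"rs{a}", f"rs{b}", float(rng.uniform(0, 0.005)))
        base = clump(recs, ld, 0.001).records
        for perm_seed in range(5):
            shuffled = list(recs)
            np.random.default_rng(perm_seed).shuffle(shuffled)
            assert clump(shuffled, ld, 0.001).records == base

    def test_window_limits_conflicts(self):
        a = make_record(snp_id="rsA", pvalue=1e-9, chrom="1", pos=1000)
        b = make_record(snp_id="rsB", pvalue=1e-6, chrom="1", pos=50_000_000)
        ld = LDTable({("rsA", "rsB"): 0.9})
        out = clump([a, b], ld, r2_threshold=0.001, window_bp=10_000_000)
        assert out.k == 2  # out of window: high r2 ignored
        out2 = clump([a, b], ld, r2_threshold=0.001, window_bp=float("inf"))
        assert out2.k == 1

    def test_different_chromosomes_never_conflict(self):
        a = make_record(snp_id="rsA", pvalue=1e-9, chrom="1", pos=1000)
        b = make_record(snp_id="rsB", pvalue=1e-6, chrom="2", pos=1000)
        ld = LDTable({("rsA", "rsB"): 1.0})
        assert clump([a, b], ld, 0.001, window_bp=10_000_000).k == 2

    def test_strict_policy_missing_pair(self):
        a = make_record(snp_id="rsA", pvalue=1e-9)
        b = make_record(snp_id="rsB", pvalue=1e-6)
        with pytest.raises(KeyError):
            clump([a, b], LDTable(policy="strict"), 0.001)


class TestLDTable:
    def test_symmetry_and_self(self):
        ld = LDTable({("a", "b"): 0.4})
        assert ld.r2("b", "a") == 0.4
        assert ld.r2("a", "a") == 1.0

    def test_from_tsv_pairs(self):
        ld = LDTable.from_tsv(io.StringIO("snp_a\tsnp_b\tr2\nrs1\trs2\t0.25\n"))
        assert ld.r2("rs2", "rs1") == 0.25

    def test_from_tsv_matrix(self):
        text = "id\trs1\trs2\nrs1\t1.0\t0.3\nrs2\t0.3\t1.0\n"
        ld = LDTable.from_tsv(io.StringIO(text))
        assert ld.r2("rs1", "rs2") == 0.3

    def test_invalid_r2(self):
        with pytest.raises(ValueError):
            LDTable({("a", "b"): 1.5})


class TestScreenConfounders:
    def test_empty_annotations_identity(self, prostatitis_records):
        out = screen_confounders(prostatitis_records, [], ["body mass"])
        assert list(out.records) == prostatitis_records

    def test_blocklisted_trait_removed(self):
        recs = [make_record(snp_id="rs1"), make_record(snp_id="rs2")]
        out = screen_confounders(recs, [("rs1", "Body mass index")], ["body mass"])
        assert [r.snp_id for r in out.records] == ["rs2"]
        assert out.provenance[-1].detail == (("rs1", "Body mass index"),)

    def test_case_insensitive_substring(self):
        recs = [make_record(snp_id=f"rs{i}") for i in (1, 2, 3)]
        annotations = [
            ("rs1", "BODY MASS INDEX"),
            ("rs2", "height"),
            ("rs3", "smoking status"),
        ]
        out = screen_confounders(recs, annotations, ["body mass", "SMOK"])
        assert [r.snp_id for r in out.records] == ["rs2"]

    def test_read_annotations(self):
        table = read_annotations(io.StringIO("snp_id\ttrait\nrs1\tbmi\n"))
        assert table == [("rs1", "bmi")]


class TestStrength:
    def test_printed_formula_hand_example(self):
        rec = make_record(snp_id="rs380286", eaf=0.437, beta=-0.002,
                          se=2.08e-4, pvalue=4.90e-19)
        s = instrument_strength(rec, n=463_010, k=1)
        assert s.r2_paper == pytest.approx(9.83e-5, rel=5e-3)
        assert s.f_persnp == pytest.approx(45.5, rel=5e-3)
        assert s.f_paper == pytest.approx(s.f_persnp, rel=1e-4)  # k=1

    def test_f_from_p_unit_z(self):
        assert f_from_pvalue(0.3173) == pytest.approx(1.0, abs=1e-3)

    def test_f_from_p_matches_printed_value(self):
        assert f_from_pvalue(4.90e-19) == pytest.approx(79.461, rel=0.01)

    def test_all_33_rows_within_one_percent(self, bph_records, prostatitis_records):
        for rec in bph_records + prostatitis_records:
            p, f_printed = PRINTED_F[rec.snp_id]
            assert rec.pvalue == pytest.approx(p)
            assert f_from_pvalue(rec.pvalue) == pytest.approx(f_printed, rel=0.01)

    def test_small_n_domain_error(self):
        with pytest.raises(ValueError):
            instrument_strength(make_record(), n=3, k=5)

    @given(st.floats(1e-280, 0.999))
    @settings(max_examples=100, deadline=None)
    def test_f_from_p_monotone(self, p):
        assert f_from_pvalue(p) >= f_from_pvalue(min(1.0, p * 1.5)) - 1e-12

    def test_f_paper_monotone_in_beta_over_se(self):
        fs = [
            instrument_strength(make_record(beta=b), n=10_000, k=1).f_paper
            for b in (0.01, 0.02, 0.05, 0.1)
        ]
        assert fs == sorted(fs)


class TestStrengthSummary:
    def test_pooled_fixture_range(self, bph_records, prostatitis_records):
        fmin, fmax, n10 = strength_summary(bph_records + prostatitis_records)
        assert fmin == pytest.approx(21.06, rel=0.01)
        assert fmax == pytest.approx(79.46, rel=0.01)
        assert n10 == 33

    def test_single_snp(self):
        fmin, fmax, _ = strength_summary([make_record()])
        assert fmin == fmax

    def test_equal_pvalues(self):
        recs = [make_record(snp_id=f"rs{i}", pvalue=1e-8) for i in range(4)]
        fmin, fmax, _ = strength_summary(recs)
        assert fmin == pytest.approx(fmax, rel=1e-12)

    def test_empty_set_error(self):
        with pytest.raises(NoInstrumentsError):
            strength_summary([])
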