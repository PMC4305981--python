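import math
from fractions import Fraction
from math import comb

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfcoop.data import DataError, NucleosomeTrack, RegulationTable, TFBSRecord
from tfcoop.scoring import (
    ContingencyTable,
    build_contingency,
    codepletion_pvalue,
    cooperativity_score,
    export_network,
    occupancy_state,
    overlap_pvalue,
    predict,
    score_all_pairs,
    score_pair,
)
from tfcoop.targets import build_best_site_index, define_targets

from oracles import fisher_tail_exact, hyper_tail_exact, overlap_tail_by_enumeration


def _log10_fraction(x: Fraction) -> float:
    """Exact-arithmetic log10 of a positive Fraction of any magnitude."""

    def log10_int(n: int) -> float:
        k = len(str(n)) - 1
        return k + math.log10(n / 10 ** k)

    return log10_int(x.numerator) - log10_int(x.denominator)


def site(tf, gene, start, posterior=0.9, chrom="chr1"):
    return TFBSRecord(
        tf=tf, chrom=chrom, start=start, end=start + 10,
        strand="+", posterior=posterior, gene=gene,
    )


class TestOverlapPvalue:
    def test_m_zero_sums_whole_distribution(self):
        p, log10_p = overlap_pvalue(5, 7, 0, 20)
        assert p == pytest.approx(1.0)
        assert log10_p == 0.0

    def test_full_overlap_small_universe(self):
        # frozen from brute-force enumeration of all C(4,2) placements
        expected = overlap_tail_by_enumeration(2, 2, 2, 4)
        assert expected == Fraction(1, 6)
        p, _ = overlap_pvalue(2, 2, 2, 4)
        assert p == pytest.approx(float(expected), rel=1e-12)

    def test_single_term_tail_against_big_integers(self):
        # m = n1 = n2 = 50: the tail is the single term 1 / C(6576, 50)
        exact = Fraction(1, comb(6576, 50))
        p, log10_p = overlap_pvalue(50, 50, 50, 6576)
        assert log10_p == pytest.approx(_log10_fraction(exact), rel=1e-9)
        assert p == pytest.approx(float(exact), rel=1e-9)

    def test_underflowing_tail_stays_finite_in_log_space(self):
        # 1 / C(6576, 200) is far below float underflow
        exact = Fraction(1, comb(6576, 200))
        assert float(exact) == 0.0
        p, log10_p = overlap_pvalue(200, 200, 200, 6576)
        assert p == 0.0
        assert log10_p == pytest.approx(_log10_fraction(exact), rel=1e-9)

    def test_matches_exact_oracle_spot_checks(self):
        for n1, n2, m, total in [(3, 4, 2, 10), (6, 6, 3, 12), (1, 1, 1, 2)]:
            p, log10_p = overlap_pvalue(n1, n2, m, total)
            exact = hyper_tail_exact(n1, n2, m, total)
            assert p == pytest.approx(float(exact), rel=1e-10)

    def test_domain_errors(self):
        with pytest.raises(DataError):
            overlap_pvalue(3, 4, 4, 10)  # m > min(n1, n2)
        with pytest.raises(DataError):
            overlap_pvalue(11, 4, 2, 10)  # n1 > total
        with pytest.raises(DataError):
            overlap_pvalue(-1, 4, 0, 10)

    @given(
        st.integers(min_value=1, max_value=40),
        st.integers(min_value=1, max_value=40),
        st.integers(min_value=41, max_value=120),
    )
    def test_monotone_nonincreasing_in_m(self, n1, n2, total):
        values = [
            overlap_pvalue(n1, n2, m, total)[1] for m in range(min(n1, n2) + 1)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    @given(
        st.integers(min_value=0, max_value=8),
        st.integers(min_value=0, max_value=8),
        st.integers(min_value=8, max_value=14),
    )
    def test_symmetric_in_n1_n2(self, n1, n2, total):
        m = min(n1, n2)
        assert overlap_pvalue(n1, n2, m, total)[1] == pytest.approx(
            overlap_pvalue(n2, n1, m, total)[1], abs=1e-10
        )


class TestCodepletionPvalue:
    def test_a_zero_gives_one(self):
        for b, c, d in [(0, 0, 0), (3, 2, 5), (1, 0, 7)]:
            p, log10_p = codepletion_pvalue(ContingencyTable(0, b, c, d))
            assert p == pytest.approx(1.0)
            assert log10_p == 0.0

    def test_3_1_1_3_is_17_over_70(self):
        # frozen from margin enumeration: tables (3,1,1,3) and (4,0,0,4)
        expected = fisher_tail_exact(3, 1, 1, 3)
        assert expected == Fraction(17, 70)
        p, _ = codepletion_pvalue(ContingencyTable(3, 1, 1, 3))
        assert p == pytest.approx(float(expected), rel=1e-12)

    def test_empty_table_returns_one(self):
        assert codepletion_pvalue(ContingencyTable(0, 0, 0, 0)) == (1.0, 0.0)

    def test_negative_cell_rejected(self):
        with pytest.raises(DataError):
            ContingencyTable(-1, 0, 0, 0)

    @given(
        st.integers(min_value=0, max_value=8),
        st.integers(min_value=0, max_value=8),
        st.integers(min_value=0, max_value=8),
        st.integers(min_value=0, max_value=8),
    )
    def test_transpose_symmetry(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        p1 = codepletion_pvalue(t)[1]
        p2 = codepletion_pvalue(t.transpose)[1]
        assert p1 == pytest.approx(p2, abs=1e-10)

    @given(
        st.integers(min_value=0, max_value=10),
        st.integers(min_value=0, max_value=10),
        st.integers(min_value=0, max_value=10),
        st.integers(min_value=0, max_value=10),
    )
    def test_matches_exact_oracle(self, a, b, c, d):
        p, _ = codepletion_pvalue(ContingencyTable(a, b, c, d))
        assert p == pytest.approx(float(fisher_tail_exact(a, b, c, d)), rel=1e-9)

    @given(
        st.integers(min_value=1, max_value=10),
        st.integers(min_value=0, max_value=10),
        st.integers(min_value=0, max_value=10),
        st.integers(min_value=0, max_value=10),
    )
    def test_full_support_sums_to_one(self, a, b, c, d):
        # the tail at the support minimum spans the whole distribution:
        # rebuild a table with the same margins whose a-cell is minimal
        lo = max(0, (a + c) - (c + d))
        p, _ = codepletion_pvalue(ContingencyTable(lo, a + b - lo, a + c - lo,
                                                   (c + d) - (a + c - lo)))
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_monotone_nonincreasing_in_a_with_fixed_margins(self):
        # margins (6, 6; 6, 6): slide mass along the diagonal
        values = [
            codepletion_pvalue(ContingencyTable(a, 6 - a, 6 - a, a))[1]
            for a in range(7)
        ]
        assert all(x >= y for x, y in zip(values, values[1:]))


class TestOccupancyState:
    track = NucleosomeTrack({"chr1": [(105, 250)]})

    def test_overlapping_site_occupied(self):
        assert occupancy_state(site("T", "G", 100), self.track) == 1

    def test_adjacent_site_depleted(self):
        track = NucleosomeTrack({"chr1": [(110, 250)]})
        assert occupancy_state(site("T", "G", 100), track) == 0

    def test_unknown_chromosome_depleted(self):
        assert occupancy_state(site("T", "G", 100, chrom="chrX"), self.track) == 0


def _pipeline_inputs(genes_states, track_intervals):
    """Build a two-TF scenario: genes_states maps gene -> (s1, s2) or None."""
    reg_records = set()
    sites = []
    pos = 0
    intervals = []
    for gene, states in genes_states.items():
        for j, tf in enumerate(("TF1", "TF2")):
            if states is None and tf == "TF1":
                reg_records.add((tf, gene))  # documented-only for TF1
                continue
            start = pos + j * 20
            sites.append(site(tf, gene, start))
            reg_records.add((tf, gene))
            if states is not None and states[j] == 1:
                intervals.append(("chr1", start, start + 10))
        pos += 100
    track = NucleosomeTrack.from_intervals(intervals + track_intervals)
    reg = RegulationTable(records=frozenset(reg_records))
    best = build_best_site_index(sites)
    targets = define_targets(reg, best, total_genes=50)
    return targets, best, track


class TestBuildContingency:
    def test_single_gene_both_depleted(self):
        targets, best, track = _pipeline_inputs({"G1": (0, 0)}, [])
        set_a, table = build_contingency("TF1", "TF2", targets, best, track)
        assert set_a == {"G1"}
        assert (table.a, table.b, table.c, table.d) == (1, 0, 0, 0)

    def test_documented_only_gene_excluded_from_set_a(self):
        targets, best, track = _pipeline_inputs({"G1": (0, 0), "G2": None}, [])
        assert "G2" in targets["TF1"] & targets["TF2"]
        set_a, _ = build_contingency("TF1", "TF2", targets, best, track)
        assert set_a == {"G1"}

    def test_one_gene_per_cell(self):
        targets, best, track = _pipeline_inputs(
            {"G1": (0, 0), "G2": (1, 0), "G3": (0, 1), "G4": (1, 1)}, []
        )
        set_a, table = build_contingency("TF1", "TF2", targets, best, track)
        assert len(set_a) == 4
        assert (table.a, table.b, table.c, table.d) == (1, 1, 1, 1)

    def test_self_pair_rejected(self):
        targets, best, track = _pipeline_inputs({"G1": (0, 0)}, [])
        with pytest.raises(DataError):
            build_contingency("TF1", "TF1", targets, best, track)

    def test_conservation(self):
        targets, best, track = _pipeline_inputs(
            {"G1": (0, 0), "G2": (1, 1), "G3": (1, 0)}, []
        )
        set_a, table = build_contingency("TF1", "TF2", targets, best, track)
        assert table.total == len(set_a)


class TestCooperativityScore:
    def test_log10_arithmetic(self):
        assert cooperativity_score(-100.0, -30.0) == pytest.approx(130.0)

    def test_both_one_gives_zero(self):
        assert cooperativity_score(0.0, 0.0) == 0.0

    def test_commutative(self):
        assert cooperativity_score(-3.0, -7.0) == cooperativity_score(-7.0, -3.0)

    def test_positive_log_rejected(self):
        with pytest.raises(DataError):
            cooperativity_score(0.1, 0.0)


class TestScoreAllPairs:
    def test_synthetic_default_has_190_results(self, default_results):
        assert len(default_results) == 190

    def test_sorted_by_score_descending(self, default_results):
        scores = [r.score for r in default_results]
        assert scores == sorted(scores, reverse=True)

    def test_scores_nonnegative_and_conserved(self, default_results):
        for r in default_results:
            assert r.score >= 0.0
            assert r.m <= min(r.n1, r.n2)
            assert r.set_a_size <= r.m

    def test_ablation_equals_overlap_term_only(self, default_dataset):
        from tfcoop import score_files

        cfg = default_dataset.config
        ablated = score_files(
            default_dataset.regulation_path,
            default_dataset.tfbs_path,
            default_dataset.nucleosome_path,
            total_genes=cfg.n_genes,
            disable_nucleosome=True,
        )
        for r in ablated:
            assert r.p_nu == 1.0
            assert r.score == pytest.approx(-r.log10_p_overlap)

    def test_pair_symmetry(self):
        targets, best, track = _pipeline_inputs(
            {"G1": (0, 0), "G2": (1, 0), "G3": (0, 1)}, []
        )
        r12 = score_pair("TF1", "TF2", targets, best, track)
        r21 = score_pair("TF2", "TF1", targets, best, track)
        assert r12 == r21  # canonical ordering makes them identical

    def test_row_order_permutation_invariance(self, default_dataset, tmp_path,
                                              default_results):
        import random

        from tfcoop import score_files

        lines = default_dataset.tfbs_path.read_text().splitlines()
        random.Random(7).shuffle(lines)
        shuffled = tmp_path / "tfbs_shuffled.bed"
        shuffled.write_text("\n".join(lines) + "\n")
        cfg = default_dataset.config
        res = score_files(
            default_dataset.regulation_path, shuffled,
            default_dataset.nucleosome_path, total_genes=cfg.n_genes,
        )
        assert res == default_results


class TestPredict:
    def test_threshold_zero_keeps_all_positive(self, default_results):
        positive = [r for r in default_results if r.score > 0]
        assert predict(default_results, 0.0) == positive

    def test_threshold_above_max_empty(self, default_results):
        top = default_results[0].score
        assert predict(default_results, top + 1.0) == []

    def test_strict_inequality(self):
        results = [_dummy(s) for s in (130.0, 120.0, 119.0)]
        assert [r.score for r in predict(results, 120.0)] == [130.0]


def _dummy(score):
    from tfcoop.data import PairResult

    return PairResult(
        tf1="A", tf2=f"B{score}", n1=1, n2=1, m=1,
        p_overlap=1.0, log10_p_overlap=0.0, a=0, b=0, c=0, d=0,
        p_nu=1.0, log10_p_nu=0.0, score=score,
    )


class TestExportNetwork:
    def test_edge_count(self, tmp_path):
        out = tmp_path / "net.tsv"
        export_network([("A", "B"), ("C", "D")], out)
        assert len(out.read_text().splitlines()) == 3

    def test_empty_prediction(self, tmp_path):
        out = tmp_path / "net.tsv"
        export_network([], out)
        assert out.read_text().splitlines() == ["tf1\ttf2\tshared_categories"]

    def test_shared_category_attribute(self, tmp_path):
        out = tmp_path / "net.tsv"
        export_network(
            [("A", "B"), ("C", "D")], out,
            annotations={"A": ["cycle"], "B": ["cycle", "meta"], "C": ["x"]},
        )
        lines = out.read_text().splitlines()[1:]
        assert lines[0].split("\t")[2] == "cycle"
        assert lines[1].split("\t")[2] == ""
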