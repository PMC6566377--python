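"""Binomial enrichment: exact tail values, adjustments, and reporting."""

import io
import math

import numpy as np
import pytest
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from ogclust import (
    GOAnnotationMap,
    TermCountTable,
    adjust_pvalues,
    binomial_test,
    count_terms,
    enrich_group,
    make_obo,
    parse_obo,
    top_report,
)


class TestCountTerms:
    def _dag(self):
        return parse_obo(io.StringIO(make_obo(3, 2)))

    def test_level_restriction_and_n(self):
        dag = self._dag()
        level3 = dag.terms_at_level(3)
        level2 = dag.terms_at_level(2)
        ann = GOAnnotationMap(
            terms={
                "p1": {level3[0], level2[0]},
                "p2": {level3[0]},
                "p3": {level2[0]},
            },
            provenance={},
        )
        table = count_terms(ann, ["p1", "p2", "p3", "p_unannotated"], dag, level=3)
        assert table.n == 3
        assert table.counts == {level3[0]: 2}

    def test_no_annotated_proteins(self):
        table = count_terms(GOAnnotationMap({}, {}), ["p1"], self._dag(), level=3)
        assert table.n == 0 and table.counts == {}


class TestBinomialTest:
    def test_zero_successes_gives_one(self):
        assert binomial_test(0, 10, 0.3) == 1.0

    def test_exact_upper_tail(self):
        # C(10,8)+C(10,9)+C(10,10) = 56 outcomes of 1024 at p0 = 1/2
        assert binomial_test(8, 10, 0.5) == pytest.approx(56 / 1024, rel=1e-12)

    def test_exact_two_sided_point_probability(self):
        assert binomial_test(8, 10, 0.5, "two-sided") == pytest.approx(
            112 / 1024, rel=1e-12
        )

    def test_impossible_under_null(self):
        assert binomial_test(3, 10, 0.0) == 0.0
        assert binomial_test(0, 10, 0.0) == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binomial_test(11, 10, 0.5)
        with pytest.raises(ValueError):
            binomial_test(1, 10, 1.5)

    def test_upper_tail_monotone_in_k(self):
        for p0 in (0.1, 0.5, 0.9):
            ps = [binomial_test(k, 20, p0) for k in range(21)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("alternative", ["greater", "two-sided"])
    def test_matches_scipy_reference(self, alternative):
        for n in (1, 5, 17):
            for p0 in (0.1, 0.5, 0.9):
                for k in range(n + 1):
                    ours = binomial_test(k, n, p0, alternative)
                    ref = binomtest(k, n, p0, alternative=alternative).pvalue
                    assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)


class TestAdjust:
    def test_holm_step_down_example(self):
        assert adjust_pvalues([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_single_and_unit(self):
        assert adjust_pvalues([0.2]) == [pytest.approx(0.2)]
        assert adjust_pvalues([1.0, 1.0]) == [1.0, 1.0]

    def test_empty(self):
        assert adjust_pvalues([]) == []

    def test_against_statsmodels(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        for ours, theirs in (
            (adjust_pvalues(p, "holm"), multipletests(p, method="holm")[1]),
            (adjust_pvalues(p, "bh"), multipletests(p, method="fdr_bh")[1]),
        ):
            assert np.allclose(ours, theirs)

    def test_holm_dominates_bh_and_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        holm = np.array(adjust_pvalues(p, "holm"))
        bh = np.array(adjust_pvalues(p, "bh"))
        assert np.all(holm >= bh - 1e-15)
        assert np.all(holm >= p) and np.all(holm <= 1.0)


class TestEnrichGroup:
    def _table(self, group, n, counts):
        return TermCountTable(group=group, n=n, counts=counts)

    def test_identical_counts_never_significant(self):
        tested = self._table("Cha+Emb", 100, {"T1": 30, "T2": 5})
        control = self._table("Chl+Cha+Emb", 100, {"T1": 30, "T2": 5})
        results = enrich_group(tested, control)
        assert not any(r.significant for r in results)
        assert all(r.p_raw >= 0.5 for r in results)

    def test_direction_filter_blocks_depletion(self):
        tested = self._table("Emb", 200, {"T1": 1})
        control = self._table("Chl+Cha+Emb", 200, {"T1": 150})
        (result,) = enrich_group(tested, control, alternative="two-sided")
        assert result.direction == "under" and not result.significant

    def test_term_absent_from_control_is_degenerate(self):
        tested = self._table("Emb", 50, {"T1": 25})
        control = self._table("Chl+Cha+Emb", 80, {})
        (result,) = enrich_group(tested, control)
        assert result.degenerate and result.k_C == 0

    def test_empty_control_is_error(self):
        with pytest.raises(ValueError):
            enrich_group(self._table("Emb", 5, {}), self._table("C", 0, {}))


class TestTopReport:
    def _result(self, term, p_adj, k=10, n=100):
        from ogclust import EnrichmentResult

        return EnrichmentResult(
            term_id=term, group="Cha+Emb", k_T=k, n_T=n, k_C=1, n_C=100,
            p0=0.01, p_raw=p_adj, p_adj=p_adj, direction="over", significant=True,
        )

    def test_empty(self):
        assert top_report([]).rows == []

    def test_truncation(self):
        results = [self._result(f"T{i:02d}", 1e-5 * (i + 1)) for i in range(25)]
        assert len(top_report(results, top_n=20).rows) == 20

    def test_tie_break_by_fraction_then_term(self):
        a = self._result("T2", 1e-4, k=30)
        b = self._result("T1", 1e-4, k=30)
        c = self._result("T3", 1e-4, k=50)
        report = top_report([a, b, c])
        assert [r.term_id for r in report.rows] == ["T3", "T1", "T2"]

    def test_minus_log10_column(self):
        report = top_report([self._result("T1", 1e-4)])
        assert report.minus_log10_padj() == [pytest.approx(4.0)]
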